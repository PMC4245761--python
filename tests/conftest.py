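import random

import pytest

from kmernorm.io import ReadSet, SequenceRecord


def make_record(read_id, bases, quals=None, library="lib", partner=None, role="fragment"):
    return SequenceRecord(
        read_id=read_id,
        bases=bases,
        quals=quals,
        library=library,
        mate_role=role,
        partner_id=partner,
        original_id=read_id.split("|")[-1],
    )


def make_readset(seqs, fmt="fasta"):
    """ReadSet of fragment records from {id: bases}."""
    rs = ReadSet()
    rs.format = fmt
    for rid, bases in seqs.items():
        rs.add(make_record(rid, bases))
    return rs


def make_paired_readset(pairs):
    """ReadSet from {stem: (fwd_bases, rev_bases)} with symmetric links."""
    rs = ReadSet()
    rs.format = "fasta"
    for stem, (fwd, rev) in pairs.items():
        fid, rid = f"{stem}/1", f"{stem}/2"
        rs.add(make_record(fid, fwd, partner=rid, role="forward"))
        rs.add(make_record(rid, rev, partner=fid, role="reverse"))
    return rs


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture
def fastq_pair(tmp_path):
    """Two tiny positionally paired FASTQ files with /1 and /2 suffixes."""
    r1 = tmp_path / "r1.fastq"
    r2 = tmp_path / "r2.fastq"
    r1.write_text("@a/1\nACGTACGT\n+\nIIIIIIII\n@b/1\nTTTTCCCC\n+\nFFFFFFFF\n")
    r2.write_text("@a/2\nCCGGAATT\n+\nHHHHHHHH\n@b/2\nGGGGAAAA\n+\nEEEEEEEE\n")
    return r1, r2
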