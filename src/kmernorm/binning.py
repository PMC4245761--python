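"""Input filtering and retention-bin assignment.

Each surviving read is placed into one of Z retention bins (default 100)
labelled by the percentage of the bin's reads to keep.  Reads at or below
the user's RMKF cutoff land in bin Z (the 100% retention bin); more
abundant reads get bin ``ceil((cutoff / RMKF) * Z)``, clamped to bin 1, so
retention falls inversely with estimated depth.  The bin boundary
arithmetic is done on exact rationals to avoid float edge cases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Union

from kmernorm.io import ReadSet
from kmernorm.kmer import DEFAULT_K

log = logging.getLogger(__name__)

DEFAULT_NUM_BINS = 100

REASON_SHORT = "short"
REASON_ZERO_RMKF = "zero-rmkf"


@dataclass
class SelectionConfig:
    """Run parameters for a normalization pass.

    ``cutoff`` is the RMKF at (or below) which reads are always kept; it
    has no default because it encodes the desired output coverage.  Because
    strands are not merged during counting, the cutoff corresponds
    empirically to roughly half the expected output sequence coverage.
    """

    cutoff: float
    num_bins: int = DEFAULT_NUM_BINS
    k: int = DEFAULT_K
    seed: int = 0
    method: str = "random"
    track_mates: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be > 0, got {self.cutoff}")
        if self.num_bins < 1:
            raise ValueError(f"num_bins must be >= 1, got {self.num_bins}")
        if self.method not in ("random", "targeted"):
            raise ValueError(f"method must be random|targeted, got {self.method!r}")
        log.info(
            "RMKF cutoff %s: expect output coverage near 2x the cutoff "
            "(strands are counted separately)",
            self.cutoff,
        )


@dataclass
class RetentionBinSet:
    """Bin index (1..Z) -> read ids, plus the filtered-out ids with reasons."""

    num_bins: int
    bins: dict[int, list[str]] = field(default_factory=dict)
    removed: dict[str, str] = field(default_factory=dict)

    def bin_of(self) -> dict[str, int]:
        return {rid: b for b, ids in self.bins.items() for rid in ids}

    def n_binned(self) -> int:
        return sum(len(ids) for ids in self.bins.values())

    def size(self, b: int) -> int:
        return len(self.bins.get(b, []))


def filter_reads(
    readset: ReadSet,
    profile: dict[str, int],
    k: int = DEFAULT_K,
) -> tuple[list[str], dict[str, str]]:
    """Drop unusable reads before binning.

    A read is removed iff its RMKF is 0 or it has fewer than k
    non-ambiguous bases (it then cannot carry a full valid k-mer).  Removed
    reads are tombstoned in the read set's pairing table so that surviving
    mates compete at fragment priority later.
    """
    kept: list[str] = []
    removed: dict[str, str] = {}
    for rec in list(readset):
        if rec.n_unambiguous < k:
            removed[rec.read_id] = REASON_SHORT
        elif profile[rec.read_id] == 0:
            removed[rec.read_id] = REASON_ZERO_RMKF
        else:
            kept.append(rec.read_id)
    for rid in removed:
        readset.tombstone(rid)
    return kept, removed


def assign_bin(rmkf: float, cutoff: float, num_bins: int = DEFAULT_NUM_BINS) -> int:
    """Retention bin for one read.

    rmkf <= cutoff -> bin Z; otherwise ceil((cutoff/rmkf) * Z) on exact
    rational arithmetic, clamped to bin 1 when the retention value falls
    below 1.
    """
    if rmkf <= 0:
        raise ValueError("assign_bin requires rmkf > 0; filter reads first")
    if rmkf <= cutoff:
        return num_bins
    value = Fraction(cutoff) * num_bins / Fraction(rmkf)
    return max(1, math.ceil(value))


def build_bins(
    kept_ids: list[str],
    profile: dict[str, int],
    cfg: SelectionConfig,
    removed: Union[dict[str, str], None] = None,
) -> RetentionBinSet:
    """Assign every kept read to its retention bin."""
    binset = RetentionBinSet(num_bins=cfg.num_bins, removed=dict(removed or {}))
    for rid in kept_ids:
        b = assign_bin(profile[rid], cfg.cutoff, cfg.num_bins)
        binset.bins.setdefault(b, []).append(rid)
    return binset


def write_bin_report(
    binset: RetentionBinSet,
    profile: dict[str, int],
    path: Union[str, Path],
) -> None:
    """TSV summary: bin_index, n_reads, min_rmkf, max_rmkf."""
    with open(path, "w") as fh:
        fh.write("bin_index\tn_reads\tmin_rmkf\tmax_rmkf\n")
        for b in sorted(binset.bins):
            vals = [profile[rid] for rid in binset.bins[b]]
            fh.write(f"{b}\t{len(vals)}\t{min(vals)}\t{max(vals)}\n")
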