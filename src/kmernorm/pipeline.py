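"""End-to-end orchestration: count -> filter -> bin -> (cluster) -> select -> write.

``run_reduce`` executes the whole normalization chain on real input files
and writes the selection outputs, per-bin report, id sidecar and a JSON
run manifest whose stage counts must reconcile (kept + removed = input).
``run_simulate`` / ``run_evaluate`` wrap the synthetic-data generator and
the coverage metrics for benchmarking on data with known truth.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from kmernorm import __version__
from kmernorm.binning import SelectionConfig, build_bins, filter_reads, write_bin_report
from kmernorm.clustering import cluster_bin, write_clstr
from kmernorm.io import ReadSet, load_reads, merge_readsets, write_id_map, write_selection
from kmernorm.kmer import KmerCountTable, count_kmers, rmkf_profile
from kmernorm.metrics import fivefold_fraction, two_sided_rate, window_depth
from kmernorm.selection import plan_quotas, select_random, select_targeted
from kmernorm.simulate import (
    CoverageProfile,
    SimulatedReadSet,
    make_genome,
    simulate_reads,
    write_fasta,
)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance for one reduction run."""

    version: str
    config: dict
    inputs: list[str]
    n_input: int = 0
    n_removed: int = 0
    n_kept: int = 0
    n_selected: int = 0
    two_sided_pairs: int = 0
    seed: int = 0
    elapsed_s: float = 0.0
    outputs: dict = field(default_factory=dict)

    def check(self) -> None:
        if self.n_kept + self.n_removed != self.n_input:
            raise RuntimeError(
                f"stage counts do not reconcile: kept {self.n_kept} + "
                f"removed {self.n_removed} != input {self.n_input}"
            )

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def _load_inputs(
    paired: Optional[Sequence[Union[str, Path]]],
    interleaved: Optional[Union[str, Path]],
    fragments: Sequence[Union[str, Path]],
) -> ReadSet:
    sets = []
    if paired:
        sets.append(load_reads(list(paired), "paired_two_file", library="paired"))
    if interleaved:
        sets.append(load_reads([interleaved], "paired_interleaved", library="paired"))
    for i, frag in enumerate(fragments or []):
        sets.append(load_reads([frag], "fragment", library=f"frag{i}"))
    if not sets:
        raise ValueError("no input files given")
    return merge_readsets(sets) if len(sets) > 1 else sets[0]


def run_reduce(
    cfg: SelectionConfig,
    out_prefix: Union[str, Path],
    paired: Optional[Sequence[Union[str, Path]]] = None,
    interleaved: Optional[Union[str, Path]] = None,
    fragments: Sequence[Union[str, Path]] = (),
    kmer_table: Optional[Union[str, Path]] = None,
    debug_dumps: bool = False,
) -> RunManifest:
    """Run the full normalization chain and write all outputs.

    ``kmer_table`` switches to standalone mode: user-supplied k-mer
    frequencies are loaded from TSV instead of being counted here.
    """
    t0 = time.monotonic()
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    readset = _load_inputs(paired, interleaved, fragments)
    has_pairs = bool(readset.pairing)
    if cfg.track_mates and not has_pairs:
        log.warning("track_mates requested on fragment-only input; proceeding as fragments")

    manifest = RunManifest(
        version=__version__,
        config=asdict(cfg),
        inputs=[str(p) for p in (list(paired or []) + ([interleaved] if interleaved else []) + list(fragments or []))],
        n_input=len(readset),
        seed=cfg.seed,
    )

    if kmer_table:
        table = KmerCountTable.from_tsv(kmer_table)
        if table.k != cfg.k:
            log.warning("k-mer table has k=%d; overriding configured k=%d", table.k, cfg.k)
            cfg.k = table.k
    else:
        table = count_kmers(readset, cfg.k)
    profile = rmkf_profile(readset, table)

    kept, removed = filter_reads(readset, profile, cfg.k)
    manifest.n_removed = len(removed)
    manifest.n_kept = len(kept)
    bins = build_bins(kept, profile, cfg, removed)
    plan = plan_quotas(bins, cfg)

    if cfg.method == "targeted":
        clusters = {
            b: cluster_bin([readset[rid] for rid in ids])
            for b, ids in bins.bins.items()
            if b != cfg.num_bins
        }
        result = select_targeted(
            bins,
            clusters,
            plan,
            pairing=readset.pairing,
            track_mates=cfg.track_mates and has_pairs,
            seed=cfg.seed,
            tombstones=readset.tombstones,
        )
        if debug_dumps:
            write_clstr(clusters, out_prefix.with_name(out_prefix.name + ".clstr"))
            result.ledger.dump(out_prefix.with_name(out_prefix.name + ".ledger.tsv"))
    else:
        result = select_random(bins, plan, cfg.seed, pairing=readset.pairing)

    outputs = write_selection(readset, result.selected, out_prefix)
    manifest.n_selected = len(result.selected)
    manifest.two_sided_pairs = result.two_sided_pairs

    bin_report = out_prefix.with_name(out_prefix.name + ".bins.tsv")
    write_bin_report(bins, profile, bin_report)
    sel_report = out_prefix.with_name(out_prefix.name + ".selection.tsv")
    result.write_report(bins, plan, sel_report)
    id_map = out_prefix.with_name(out_prefix.name + ".idmap.tsv")
    write_id_map(readset, id_map)
    ids_path = out_prefix.with_name(out_prefix.name + ".selected_ids.txt")
    with open(ids_path, "w") as fh:
        for rid in sorted(result.selected):
            fh.write(rid + "\n")

    manifest.outputs = {k: str(v) for k, v in outputs.items()}
    manifest.outputs.update(
        bins=str(bin_report), selection=str(sel_report), idmap=str(id_map), ids=str(ids_path)
    )
    manifest.elapsed_s = round(time.monotonic() - t0, 3)
    manifest.check()
    manifest.write(out_prefix.with_name(out_prefix.name + ".manifest.json"))
    return manifest


def run_simulate(
    out_prefix: Union[str, Path],
    genome_len: int = 50_000,
    window_len: int = 1_000,
    base_depth: float = 20.0,
    sigma: float = 0.0,
    spikes: Sequence[tuple[int, int, float]] = (),
    read_len: int = 100,
    paired: bool = False,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    err_rate: float = 0.0,
    gc: float = 0.5,
    seed: int = 0,
) -> SimulatedReadSet:
    """Generate a biased read set and write reads + truth + profile."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    genome = make_genome(genome_len, gc=gc, seed=seed)
    if sigma > 0 or spikes:
        profile = CoverageProfile.lognormal(
            genome_len, window_len, base_depth, sigma, seed + 1, spikes
        )
    else:
        profile = CoverageProfile.uniform(genome_len, window_len, base_depth)
    sim = simulate_reads(
        genome,
        profile,
        read_len=read_len,
        paired=paired,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        err_rate=err_rate,
        seed=seed + 2,
    )
    write_fasta(sim, out_prefix.with_name(out_prefix.name + ".reads.fasta"))
    sim.truth_to_tsv(out_prefix.with_name(out_prefix.name + ".truth.tsv"))
    profile.to_tsv(out_prefix.with_name(out_prefix.name + ".profile.tsv"))
    return sim


def run_evaluate(
    truth_tsv: Union[str, Path],
    profile_tsv: Union[str, Path],
    ids_file: Optional[Union[str, Path]] = None,
    out_json: Optional[Union[str, Path]] = None,
    depth_floor: float = 5.0,
) -> dict:
    """Coverage metrics for a selection (or the full set if no ids given)."""
    truth = SimulatedReadSet.truth_from_tsv(truth_tsv)
    profile = CoverageProfile.from_tsv(profile_tsv)
    selected = None
    if ids_file is not None:
        with open(ids_file) as fh:
            selected = [line.strip() for line in fh if line.strip()]
        # ids written by run_reduce carry a "<library>|<ordinal>|" prefix on
        # top of the simulator's ids; strip it when needed to match truth
        resolved = []
        for rid in selected:
            if rid in truth:
                resolved.append(rid)
            else:
                parts = rid.split("|", 2)
                if len(parts) == 3 and parts[2] in truth:
                    resolved.append(parts[2])
                else:
                    raise KeyError(f"selected id {rid!r} not found in truth table")
        selected = resolved
    depths = window_depth(truth, profile, selected)
    pairing: dict[str, str] = {}
    metrics = {
        "n_reads": len(truth) if selected is None else len(selected),
        "mean_depth": float(depths.mean()) if depths.size else 0.0,
        "max_depth": float(depths.max()) if depths.size else 0.0,
        "fivefold_fraction": fivefold_fraction(depths, depth_floor),
    }
    if selected is not None and pairing:
        metrics["two_sided_rate"] = two_sided_rate(selected, pairing)
    if out_json:
        with open(out_json, "w") as fh:
            json.dump(metrics, fh, indent=2)
            fh.write("\n")
    return metrics
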