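"""Per-bin quota planning and the random / targeted selection methods.

The quota for bin b is ``round_half_up(|bin b| * b / Z)`` — bin Z keeps
everything — so retention falls linearly with the bin index.  Random
selection shuffles each bin and takes the quota.  Targeted selection walks
bins most-selective first and, inside each bin, its similarity clusters
smallest (most unique) first, recomputing the per-cluster ideal
``ceil(S_remaining / clusters_remaining)`` after every cluster; with mate
tracking on, reads inside a cluster are taken by priority tier:

  (a) two-sided pairs both present in the cluster,
  (b) one-sided mates whose partner is already selected,
  (c) one-sided mates whose partner is not yet evaluated,
  (d) fragments and one-sided mates whose partner was discarded.

A single seeded random generator drives all shuffles, with a documented
draw order (bin Z first, then bins ascending; clusters in sorted order),
so a run is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

from kmernorm.binning import RetentionBinSet, SelectionConfig
from kmernorm.clustering import Cluster, sort_clusters_unique_first

UNEVALUATED = "unevaluated"
SELECTED = "selected"
DISCARDED = "discarded"


@dataclass
class SelectionPlan:
    """Ideal extraction count S_b per bin."""

    quotas: dict[int, int] = field(default_factory=dict)

    def quota(self, b: int) -> int:
        return self.quotas.get(b, 0)


class MateStatusLedger:
    """Monotone per-read status: unevaluated -> selected | discarded."""

    def __init__(self) -> None:
        self._status: dict[str, str] = {}

    def status(self, read_id: str) -> str:
        return self._status.get(read_id, UNEVALUATED)

    def _set(self, read_id: str, status: str) -> None:
        cur = self.status(read_id)
        if cur != UNEVALUATED and cur != status:
            raise ValueError(
                f"ledger status of {read_id} is {cur}; cannot change to {status}"
            )
        self._status[read_id] = status

    def mark_selected(self, read_id: str) -> None:
        self._set(read_id, SELECTED)

    def mark_discarded(self, read_id: str) -> None:
        self._set(read_id, DISCARDED)

    def partner_selected(self, read_id: str, pairing: dict[str, str]) -> bool:
        mate = pairing.get(read_id)
        return mate is not None and self.status(mate) == SELECTED

    def dump(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tstatus\n")
            for rid in sorted(self._status):
                fh.write(f"{rid}\t{self._status[rid]}\n")


@dataclass
class SelectionResult:
    selected: list[str]
    per_bin: dict[int, int]
    seed: int
    per_cluster: Optional[dict[tuple[int, int], int]] = None
    two_sided_pairs: int = 0
    ledger: Optional[MateStatusLedger] = None

    @property
    def selected_set(self) -> set[str]:
        return set(self.selected)

    def write_report(
        self, bins: RetentionBinSet, plan: SelectionPlan, path: Union[str, Path]
    ) -> None:
        with open(path, "w") as fh:
            fh.write("bin\tbin_size\tquota\tselected\n")
            for b in sorted(bins.bins):
                fh.write(
                    f"{b}\t{bins.size(b)}\t{plan.quota(b)}\t"
                    f"{self.per_bin.get(b, 0)}\n"
                )


def _round_half_up(x: Fraction) -> int:
    return math.floor(x + Fraction(1, 2))


def plan_quotas(bins: RetentionBinSet, cfg: SelectionConfig) -> SelectionPlan:
    """S_b = round_half_up(|bin b| * b / Z), capped at the bin size;
    bin Z's quota is its full size."""
    z = cfg.num_bins
    quotas: dict[int, int] = {}
    for b, ids in bins.bins.items():
        n = len(ids)
        if b == z:
            quotas[b] = n
        else:
            quotas[b] = min(n, _round_half_up(Fraction(n * b, z)))
    return SelectionPlan(quotas=quotas)


def _count_two_sided(selected: Sequence[str], pairing: dict[str, str]) -> int:
    sel = set(selected)
    return sum(1 for rid in sel if pairing.get(rid) in sel and rid < pairing[rid])


def select_random(
    bins: RetentionBinSet,
    plan: SelectionPlan,
    seed: int,
    pairing: Optional[dict[str, str]] = None,
) -> SelectionResult:
    """Take all of bin Z, then a seeded random quota from each other bin."""
    rng = random.Random(seed)
    z = bins.num_bins
    selected: list[str] = []
    per_bin: dict[int, int] = {}

    zi = list(bins.bins.get(z, []))
    selected.extend(zi)
    if zi:
        per_bin[z] = len(zi)
    for b in sorted(bins.bins):
        if b == z:
            continue
        ids = sorted(bins.bins[b])
        rng.shuffle(ids)
        take = ids[: plan.quota(b)]
        selected.extend(take)
        per_bin[b] = len(take)
    return SelectionResult(
        selected=selected,
        per_bin=per_bin,
        seed=seed,
        two_sided_pairs=_count_two_sided(selected, pairing or {}),
    )


def _tiered_cluster_pick(
    members: Sequence[str],
    budget: int,
    ledger: MateStatusLedger,
    pairing: dict[str, str],
    tombstones: set[str],
    rng: random.Random,
) -> list[str]:
    """Pick up to ``budget`` reads from one cluster by mate-priority tier."""
    mset = set(members)
    picked: list[str] = []

    # tier (a): two-sided pairs inside the cluster, taken as units
    pairs = sorted(
        (rid, pairing[rid])
        for rid in mset
        if pairing.get(rid) in mset and rid < pairing[rid]
    )
    rng.shuffle(pairs)
    leftover_pair_members: list[str] = []
    for a, b in pairs:
        if budget - len(picked) >= 2:
            picked.extend((a, b))
        else:
            leftover_pair_members.extend((a, b))

    rest = sorted(mset - set(picked) - set(leftover_pair_members))
    tier_b: list[str] = []
    tier_c: list[str] = list(leftover_pair_members)  # partner unevaluated
    tier_d: list[str] = []
    for rid in rest:
        mate = pairing.get(rid)
        if mate is None:
            tier_d.append(rid)
        elif ledger.status(mate) == SELECTED:
            tier_b.append(rid)
        elif ledger.status(mate) == DISCARDED or mate in tombstones:
            tier_d.append(rid)
        else:
            tier_c.append(rid)
    for tier in (tier_b, tier_c, tier_d):
        rng.shuffle(tier)
        for rid in tier:
            if len(picked) >= budget:
                break
            picked.append(rid)
    return picked


def select_targeted(
    bins: RetentionBinSet,
    clusters_per_bin: dict[int, Sequence[Cluster]],
    plan: SelectionPlan,
    pairing: Optional[dict[str, str]] = None,
    track_mates: bool = False,
    seed: int = 0,
    tombstones: Optional[set[str]] = None,
) -> SelectionResult:
    """Targeted selection: unique clusters first, optional mate priority.

    Bin Z is recruited wholesale first (toggling its members' mate status
    when tracking), then bins run from most selective (1) upward.  Within a
    bin, clusters go smallest-first and the per-cluster ideal is
    recomputed after every cluster from the remaining quota and remaining
    cluster count, so unfilled clusters roll their share forward.
    """
    pairing = pairing or {}
    tombstones = set(tombstones or ())
    rng = random.Random(seed)
    z = bins.num_bins
    ledger = MateStatusLedger()
    selected: list[str] = []
    per_bin: dict[int, int] = {}
    per_cluster: dict[tuple[int, int], int] = {}

    # validate that clusters partition each sub-Z bin
    for b, ids in bins.bins.items():
        if b == z:
            continue
        clustered = [rid for cl in clusters_per_bin.get(b, []) for rid in cl.member_ids]
        if sorted(clustered) != sorted(ids):
            raise ValueError(f"clusters for bin {b} do not partition the bin")

    zi = list(bins.bins.get(z, []))
    for rid in zi:
        ledger.mark_selected(rid)
    selected.extend(zi)
    if zi:
        per_bin[z] = len(zi)

    for b in sorted(bins.bins):
        if b == z:
            continue
        ordered = sort_clusters_unique_first(clusters_per_bin.get(b, []))
        quota = plan.quota(b)
        taken = 0
        for i, cl in enumerate(ordered):
            remaining = quota - taken
            if remaining <= 0:
                for rid in cl.member_ids:
                    ledger.mark_discarded(rid)
                continue
            ideal = math.ceil(remaining / (len(ordered) - i))
            budget = min(ideal, remaining, cl.size)
            if track_mates:
                picked = _tiered_cluster_pick(
                    cl.member_ids, budget, ledger, pairing, tombstones, rng
                )
            else:
                ids = sorted(cl.member_ids)
                rng.shuffle(ids)
                picked = ids[:budget]
            for rid in picked:
                ledger.mark_selected(rid)
            for rid in set(cl.member_ids) - set(picked):
                ledger.mark_discarded(rid)
            selected.extend(picked)
            taken += len(picked)
            per_cluster[(b, i)] = len(picked)
        per_bin[b] = taken

    return SelectionResult(
        selected=selected,
        per_bin=per_bin,
        seed=seed,
        per_cluster=per_cluster,
        two_sided_pairs=_count_two_sided(selected, pairing),
        ledger=ledger,
    )
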