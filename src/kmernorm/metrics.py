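"""Coverage and mate-pair metrics for evaluating a normalization run.

All depth metrics use the simulator's per-read truth positions rather than
an aligner, so they are exact and deterministic: window depth is total
overlapping read bases divided by window length.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np

from kmernorm.simulate import CoverageProfile, ReadTruth


def window_depth(
    truth: Mapping[str, ReadTruth],
    profile: CoverageProfile,
    selected_ids: Optional[Iterable[str]] = None,
) -> np.ndarray:
    """Per-window mean depth from truth positions.

    Depth of a window is the summed overlap (in bases) of all reads with
    the window, divided by the window length.  ``selected_ids`` restricts
    the computation to a selection; None means all reads.
    """
    glen = profile.genome_len
    cov = np.zeros(glen + 1)
    ids = truth.keys() if selected_ids is None else selected_ids
    for rid in ids:
        t = truth[rid]
        s, e = max(0, t.start), min(glen, t.end)
        if s < e:
            cov[s] += 1
            cov[e] -= 1
    cov = np.cumsum(cov[:-1])
    w = profile.window_len
    n = len(profile.depths)
    return cov[: n * w].reshape(n, w).mean(axis=1)


def fivefold_fraction(depths: np.ndarray, threshold: float = 5.0) -> float:
    """Fraction of windows at or above ``threshold``-fold coverage.

    The headline uniformity metric: after normalization, formerly starved
    windows should clear the 5-fold floor an assembler needs.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        return 0.0
    return float(np.mean(depths >= threshold))


def two_sided_rate(
    selected_ids: Iterable[str], pairing: Mapping[str, str]
) -> float:
    """Fraction of selected pair-member reads whose mate was also selected.

    Denominator: selected reads that belong to any original pair (so the
    rate compares selection strategies at equal read budget); numerator:
    2 x the number of pairs with both mates selected.
    """
    sel = set(selected_ids)
    paired_sel = [rid for rid in sel if rid in pairing]
    if not paired_sel:
        return 0.0
    both = sum(1 for rid in paired_sel if pairing[rid] in sel)
    return both / len(paired_sel)


def depth_ratio(
    depths: np.ndarray, high_windows: Iterable[int], low_windows: Iterable[int]
) -> float:
    """Mean depth over the high-tier windows divided by mean over the low
    tier — the spike-to-trough contrast a normalizer should shrink."""
    depths = np.asarray(depths, dtype=float)
    hi = depths[list(high_windows)].mean()
    lo = depths[list(low_windows)].mean()
    if lo == 0:
        return float("inf")
    return float(hi / lo)
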