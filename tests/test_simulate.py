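"""Synthetic genome/read generation and the coverage metrics."""

import math

import numpy as np
import pytest

from kmernorm.clustering import revcomp
from kmernorm.metrics import depth_ratio, fivefold_fraction, two_sided_rate, window_depth
from kmernorm.simulate import (
    CoverageProfile,
    RepeatSpec,
    ReadTruth,
    make_genome,
    simulate_reads,
)


class TestMakeGenome:
    def test_gc_within_binomial_bound(self):
        n, gc = 50_000, 0.5
        genome = make_genome(n, gc=gc, seed=1)
        assert len(genome) == n
        observed = (genome.count("G") + genome.count("C")) / n
        sigma = math.sqrt(gc * (1 - gc) / n)
        assert abs(observed - gc) < 3 * sigma

    def test_repeat_spec_copies_segment(self):
        spec = RepeatSpec(source_start=1000, length=5000, target_start=20_000)
        genome = make_genome(30_000, repeat_spec=spec, seed=2)
        assert genome[1000:6000] == genome[20_000:25_000]

    def test_same_seed_same_genome(self):
        assert make_genome(2000, seed=7) == make_genome(2000, seed=7)
        assert make_genome(2000, seed=7) != make_genome(2000, seed=8)

    def test_skewed_gc(self):
        genome = make_genome(20_000, gc=0.7, seed=3)
        observed = (genome.count("G") + genome.count("C")) / len(genome)
        assert abs(observed - 0.7) < 3 * math.sqrt(0.21 / 20_000)


class TestSimulateReads:
    def test_uniform_depth_within_poisson_bands(self):
        genome = make_genome(50_000, seed=4)
        profile = CoverageProfile.uniform(50_000, 1000, 20.0)
        sim = simulate_reads(genome, profile, read_len=100, seed=5)
        depths = window_depth(sim.truth, profile)
        # per-window depth ~ 20 with sd ~ sqrt(20 * read_len / window_len)
        sigma = math.sqrt(20 * 100 / 1000)
        ok = np.mean(np.abs(depths - 20) < 4 * sigma)
        assert ok >= 0.95

    def test_error_free_reads_are_genomic_substrings(self):
        genome = make_genome(5_000, seed=6)
        profile = CoverageProfile.uniform(5_000, 500, 10.0)
        sim = simulate_reads(genome, profile, read_len=80, err_rate=0.0, seed=7)
        for rec in sim.reads:
            t = sim.truth[rec.read_id]
            frag = genome[t.start : t.end]
            assert rec.bases == (frag if t.strand == "+" else revcomp(frag))

    def test_two_tier_ratio_near_target(self):
        genome = make_genome(50_000, seed=8)
        profile = CoverageProfile.two_tier(50_000, 1000, 500.0, 10.0, 0.1)
        sim = simulate_reads(genome, profile, read_len=100, seed=9)
        depths = window_depth(sim.truth, profile)
        hi = [i for i, d in enumerate(profile.depths) if d == 500.0]
        lo = [i for i, d in enumerate(profile.depths) if d == 10.0]
        ratio = depth_ratio(depths, hi, lo)
        assert abs(ratio - 50) / 50 < 0.2

    def test_paired_mode_emits_symmetric_mates(self):
        genome = make_genome(10_000, seed=10)
        profile = CoverageProfile.uniform(10_000, 1000, 20.0)
        sim = simulate_reads(
            genome, profile, read_len=100, paired=True,
            insert_mean=300, insert_sd=20, seed=11,
        )
        sim.reads.check_pairing()
        assert len(sim.reads) % 2 == 0
        for rec in sim.reads:
            if rec.mate_role == "forward":
                mate = sim.reads[rec.partner_id]
                tf, tr = sim.truth[rec.read_id], sim.truth[mate.read_id]
                assert tf.strand == "+" and tr.strand == "-"
                assert tr.end - tf.start >= 100  # insert >= read length

    def test_insert_shorter_than_read_rejected(self):
        genome = make_genome(2_000, seed=1)
        profile = CoverageProfile.uniform(2_000, 500, 5.0)
        with pytest.raises(ValueError):
            simulate_reads(genome, profile, read_len=100, paired=True, insert_mean=50)

    def test_errors_change_bases_at_expected_rate(self):
        genome = make_genome(20_000, seed=12)
        profile = CoverageProfile.uniform(20_000, 1000, 10.0)
        sim = simulate_reads(genome, profile, read_len=100, err_rate=0.02, seed=13)
        mismatches = total = 0
        for rec in sim.reads:
            t = sim.truth[rec.read_id]
            frag = genome[t.start : t.end]
            ref = frag if t.strand == "+" else revcomp(frag)
            mismatches += sum(a != b for a, b in zip(rec.bases, ref))
            total += len(ref)
        rate = mismatches / total
        assert abs(rate - 0.02) < 4 * math.sqrt(0.02 / total)

    def test_bit_reproducible_under_seed(self):
        genome = make_genome(5_000, seed=14)
        profile = CoverageProfile.uniform(5_000, 500, 8.0)
        a = simulate_reads(genome, profile, read_len=60, err_rate=0.01, seed=15)
        b = simulate_reads(genome, profile, read_len=60, err_rate=0.01, seed=15)
        assert [(r.read_id, r.bases) for r in a.reads] == [
            (r.read_id, r.bases) for r in b.reads
        ]


class TestWindowDepth:
    def test_single_read_partial_window(self):
        profile = CoverageProfile(1000, [0.0])
        truth = {"r": ReadTruth("r", 100, 200, "+", 0)}
        depths = window_depth(truth, profile)
        assert depths.tolist() == [0.1]

    def test_no_reads_gives_zero(self):
        profile = CoverageProfile(100, [1.0, 2.0, 3.0])
        assert window_depth({}, profile).tolist() == [0.0, 0.0, 0.0]

    def test_matches_brute_force_overlap_oracle(self, rng):
        profile = CoverageProfile(50, [1.0] * 20)  # 1 kb genome
        truth = {}
        for i in range(200):
            s = rng.randint(0, 950)
            truth[f"r{i}"] = ReadTruth(f"r{i}", s, s + rng.randint(10, 80), "+", 0)
        depths = window_depth(truth, profile)
        for w in range(20):
            w0, w1 = w * 50, (w + 1) * 50
            overlap = sum(
                max(0, min(t.end, w1, 1000) - max(t.start, w0)) for t in truth.values()
            )
            assert depths[w] == pytest.approx(overlap / 50)

    def test_selection_restricts_reads(self):
        profile = CoverageProfile(100, [0.0, 0.0])
        truth = {
            "a": ReadTruth("a", 0, 100, "+", 0),
            "b": ReadTruth("b", 100, 200, "+", 1),
        }
        depths = window_depth(truth, profile, selected_ids=["a"])
        assert depths.tolist() == [1.0, 0.0]


class TestScalarMetrics:
    def test_fivefold_boundary_inclusive(self):
        assert fivefold_fraction(np.array([0, 4.9, 5.0, 20])) == 0.5
        assert fivefold_fraction(np.array([10.0, 10.0])) == 1.0
        assert fivefold_fraction(np.array([])) == 0.0

    def test_fivefold_matches_counting_oracle(self, rng):
        for _ in range(20):
            depths = np.array([rng.uniform(0, 10) for _ in range(50)])
            expected = sum(1 for d in depths if d >= 5) / 50
            assert fivefold_fraction(depths) == pytest.approx(expected)

    def test_two_sided_rate_extremes(self):
        pairing = {"a/1": "a/2", "a/2": "a/1", "b/1": "b/2", "b/2": "b/1"}
        assert two_sided_rate({"a/1", "a/2", "b/1", "b/2"}, pairing) == 1.0
        assert two_sided_rate({"a/1", "b/1"}, pairing) == 0.0
        assert two_sided_rate(set(), pairing) == 0.0

    def test_two_sided_rate_matches_partner_scan(self, rng):
        pairing = {}
        universe = []
        for i in range(30):
            a, b = f"p{i}/1", f"p{i}/2"
            pairing[a], pairing[b] = b, a
            universe += [a, b]
        universe += [f"f{i}" for i in range(10)]
        for _ in range(100):
            sel = {r for r in universe if rng.random() < 0.6}
            paired_sel = [r for r in sel if r in pairing]
            both = sum(1 for r in paired_sel if pairing[r] in sel)
            expected = both / len(paired_sel) if paired_sel else 0.0
            assert two_sided_rate(sel, pairing) == pytest.approx(expected)
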