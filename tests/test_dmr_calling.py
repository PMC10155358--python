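import numpy as np
import pytest

from oracles import permutation_mwu_p, reference_bh
from oxbskit.dmr_calling import (
    SegmentationParams,
    Thresholds,
    bh_adjust,
    call_dmrs,
    mann_whitney_normal_p,
    segment_candidates,
    significant_dmrs,
)
from oxbskit.dmr_calling import test_region as region_test
from oxbskit.meth_io import ContrastDesign


class TestSegmentation:
    def test_homogeneous_region_not_split(self):
        pos = 1000 + 50 * np.arange(10)
        diffs = np.full(10, 0.3)
        assert segment_candidates(pos, diffs) == [(0, 10)]

    def test_split_at_effect_boundary_matches_exhaustive_scan(self):
        """A sharp step in the per-CpG difference is split exactly at the
        breakpoint an exhaustive scan of all admissible breakpoints finds."""
        pos = 1000 + 50 * np.arange(10)
        diffs = np.array([0.4] * 5 + [0.0] * 5)
        params = SegmentationParams(min_cpg=5, split_gain=0.05)
        got = segment_candidates(pos, diffs, params)
        # exhaustive scan: best breakpoint maximises |mean_left - mean_right|
        scores = {
            k: abs(diffs[:k].mean() - diffs[k:].mean()) for k in range(5, 6)
        }
        best = max(scores, key=scores.get)
        assert got == [(0, best), (best, 10)]

    def test_gap_rule_separates_runs(self):
        pos = np.array([1000, 2000])
        diffs = np.array([0.3, 0.3])
        params = SegmentationParams(max_gap=300, min_cpg=1)
        assert segment_candidates(pos, diffs, params) == [(0, 1), (1, 2)]
        # with min_cpg above run length both runs are dropped
        params = SegmentationParams(max_gap=300, min_cpg=5)
        assert segment_candidates(pos, diffs, params) == []

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            segment_candidates(np.array([500, 100]), np.array([0.1, 0.1]))


class TestTestRegion:
    def test_complete_separation_3v3(self):
        # 20 equally likely assignments; the two extremes reach |U - mu|
        diff, p = region_test([0.9, 0.8, 0.85], [0.2, 0.1, 0.15])
        assert diff == pytest.approx(0.85 - 0.15)
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        diff, p = region_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert diff == 0.0
        assert p == 1.0

    def test_exact_matches_permutation_oracle(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(2, 6, size=2)
            vals = rng.choice([0.1, 0.2, 0.3, 0.5, 0.8], size=n1 + n2)
            _, p = region_test(vals[:n1], vals[n1:])
            assert p == pytest.approx(permutation_mwu_p(vals[:n1], vals[n1:]), abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        """On 6v6 draws the continuity-corrected normal p tracks the exact
        permutation p to within 0.02."""
        for _ in range(20):
            case = rng.normal(0.5, 0.2, size=6)
            control = rng.normal(0.4, 0.2, size=6)
            _, p_exact = region_test(case, control, exact_limit=12)
            p_norm = mann_whitney_normal_p(case, control)
            assert p_norm == pytest.approx(p_exact, abs=0.02)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            region_test([0.5], [0.4, 0.3])


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04] * 5), [0.04] * 5)

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    def test_matches_reference_implementation(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), reference_bh(p), atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(1e-6, 1, size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCallDmrs:
    def test_recovers_planted_region(self, planted_cohort):
        cohort, design, region = planted_cohort
        dmrs = call_dmrs(cohort, design, "5mC")
        sig = significant_dmrs(dmrs)
        assert sig, "planted +0.35 5mC region not called"
        hits = [
            d for d in sig
            if d.direction == "hyper" and region.start <= (d.start + d.end) // 2 < region.end
        ]
        assert hits
        assert hits[0].mean_diff == pytest.approx(0.35, abs=0.06)

    def test_threshold_gate_by_mark(self, planted_cohort):
        """An effect below the 5mC gate (0.2) but above the 5hmC gate (0.1)
        is only flagged under the 5hmC thresholds."""
        cohort, design, region = planted_cohort
        tight = Thresholds(diff={"5mC": 0.2, "5hmC": 0.1, "BS": 0.2})
        dmrs = call_dmrs(cohort, design, "5mC", thresholds=tight)
        in_region = [
            d for d in dmrs if region.start <= (d.start + d.end) // 2 < region.end
        ]
        d = max(in_region, key=lambda d: abs(d.mean_diff))
        # significance flag recomputes exactly as q-gate AND effect-gate
        assert d.significant == (d.q < 0.05 and abs(d.mean_diff) > 0.2)
        loose = Thresholds(diff={"5mC": 0.1, "5hmC": 0.1, "BS": 0.1})
        dmrs2 = call_dmrs(cohort, design, "5mC", thresholds=loose)
        d2 = [x for x in dmrs2 if (x.start, x.end) == (d.start, d.end)][0]
        assert d2.significant  # 0.35 effect passes the looser gate a fortiori

    def test_label_swap_negates_diffs_preserves_p(self, planted_cohort):
        cohort, design, _ = planted_cohort
        flipped = ContrastDesign(
            "flip",
            {s: ("case" if g == "control" else "control") for s, g in design.groups.items()},
        )
        a = call_dmrs(cohort, design, "5mC")
        b = call_dmrs(cohort, flipped, "5mC")
        assert len(a) == len(b)
        for d1, d2 in zip(a, b):
            assert (d1.chrom, d1.start, d1.end) == (d2.chrom, d2.start, d2.end)
            assert d2.mean_diff == pytest.approx(-d1.mean_diff, abs=1e-12)
            assert d2.p == pytest.approx(d1.p, abs=1e-12)

    def test_tiny_group_rejected(self, planted_cohort):
        cohort, _, _ = planted_cohort
        samples = list(cohort)
        design = ContrastDesign(
            "tiny", {samples[0]: "case", **{s: "control" for s in samples[1:]}}
        )
        with pytest.raises(ValueError):
            call_dmrs(cohort, design, "5mC")
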