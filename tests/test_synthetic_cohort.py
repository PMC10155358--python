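import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import uniform_cpg_map
from oxbskit.synthetic_cohort import (
    PERFECT_CHEMISTRY,
    ChemistryParams,
    CoverageModel,
    RegionEffect,
    TruthSpec,
    expected_read_probability,
    simulate_counts,
    simulate_reference,
    true_levels,
)


class TestExpectedReadProbability:
    @pytest.mark.parametrize(
        "m,h,chem,p_bs,p_ox",
        [
            # perfect chemistry collapses to m+h (BS) and m (oxBS)
            (0.6, 0.3, PERFECT_CHEMISTRY, 0.9, 0.6),
            # conversion failure alone adds false positives
            (0.0, 0.0, ChemistryParams(0.01, 0.0, 1.0), 0.01, 0.01),
            # hand-evaluated with all three error rates active
            (0.5, 0.2, ChemistryParams(0.01, 0.02, 0.95), 0.689, 0.5028),
        ],
    )
    def test_known_values(self, m, h, chem, p_bs, p_ox):
        assert expected_read_probability(m, h, "BS", chem) == pytest.approx(p_bs)
        assert expected_read_probability(m, h, "oxBS", chem) == pytest.approx(p_ox)

    def test_rejects_off_simplex(self):
        with pytest.raises(ValueError):
            expected_read_probability(0.7, 0.5, "BS", PERFECT_CHEMISTRY)

    @settings(deadline=None, derandomize=True)
    @given(
        m=st.floats(0, 1),
        h=st.floats(0, 1),
        dm=st.floats(0, 0.2),
        eta1=st.floats(0, 1),
        eta2=st.floats(0, 1),
    )
    def test_monotonicity(self, m, h, dm, eta1, eta2):
        """BS read-probability non-decreasing in m and h; oxBS
        non-increasing in the oxidation efficiency eta_ox."""
        if m + h > 1:
            m, h = m / 2, h / 2
        chem = ChemistryParams(0.01, 0.01, 0.9)
        base = expected_read_probability(m, h, "BS", chem)
        if m + h + dm <= 1:
            assert expected_read_probability(m + dm, h, "BS", chem) >= base
            assert expected_read_probability(m, h + dm, "BS", chem) >= base
        lo, hi = sorted([eta1, eta2])
        p_lo = expected_read_probability(m, h, "oxBS", ChemistryParams(0.01, 0.01, lo))
        p_hi = expected_read_probability(m, h, "oxBS", ChemistryParams(0.01, 0.01, hi))
        assert p_hi <= p_lo + 1e-12


class TestSimulateReference:
    def test_monotone_and_deterministic(self):
        cpg_map, _ = simulate_reference(1, 100, spacing=50, seed=7)
        assert len(cpg_map) == 100
        assert cpg_map["pos"].is_monotonic_increasing
        assert (cpg_map["pos"].diff().dropna() == 50).all()
        again, _ = simulate_reference(1, 100, spacing=50, seed=7)
        pd.testing.assert_frame_equal(cpg_map, again)

    def test_counts_per_chromosome(self):
        cpg_map, _ = simulate_reference(2, 10, spacing=100, seed=1)
        assert len(cpg_map) == 20
        assert cpg_map.groupby("chrom").size().tolist() == [10, 10]

    def test_gene_model_realises_all_categories(self):
        cpg_map, model = simulate_reference(1, 200, spacing=300, seed=3)
        cats = {
            model.annotate_point("chr1", int(p)) for p in cpg_map["pos"]
        }
        assert cats == {"promoter", "exon", "TTS", "intron", "intergenic"}

    def test_rejects_zero_cpgs(self):
        with pytest.raises(ValueError):
            simulate_reference(1, 0, seed=0)


class TestSimulateCounts:
    def test_seeded_determinism(self):
        truth = TruthSpec(
            cpg_map=uniform_cpg_map(50),
            group_labels=["control", "case"],
            seed=42,
        )
        a = simulate_counts(truth)
        b = simulate_counts(truth)
        for sample in a:
            for lib in ("bs", "ox"):
                pd.testing.assert_frame_equal(a[sample][lib], b[sample][lib])

    def test_zero_mean_coverage_degenerates(self):
        truth = TruthSpec(
            cpg_map=uniform_cpg_map(20),
            group_labels=["control"],
            coverage=CoverageModel(0.0),
            seed=1,
        )
        tables = simulate_counts(truth)["s01"]
        assert tables["bs"].empty and tables["ox"].empty

    def test_law_of_large_numbers_recovers_h(self):
        """At huge coverage and perfect chemistry the empirical BS - oxBS
        ratio difference converges to the true 5hmC level."""
        truth = TruthSpec(
            cpg_map=uniform_cpg_map(200),
            group_labels=["control"],
            baseline_m=0.5,
            baseline_h=0.2,
            coverage=CoverageModel(1e5, dispersion=1e9),
            chemistry=PERFECT_CHEMISTRY,
            seed=5,
        )
        t = simulate_counts(truth)["s01"]
        diff = t["bs"]["ratio"].to_numpy() - t["ox"]["ratio"].to_numpy()
        assert np.all(np.abs(diff - 0.2) < 0.01)

    def test_planted_effect_shifts_case_group(self):
        """A +0.3 5mC region effect raises the case-group oxBS ratio mean
        by ~0.3 relative to controls, within Monte-Carlo error."""
        cpg_map = uniform_cpg_map(60)
        pos = cpg_map["pos"].to_numpy()
        region = RegionEffect("chr1", int(pos[20]), int(pos[39]) + 2, "5mC", 0.3)
        truth = TruthSpec(
            cpg_map=cpg_map,
            group_labels=["control"] * 10 + ["case"] * 10,
            regions=[region],
            baseline_m=0.4,
            baseline_h=0.1,
            coverage=CoverageModel(50.0),
            chemistry=PERFECT_CHEMISTRY,
            seed=9,
        )
        tables = simulate_counts(truth)
        in_region = lambda t: t["ox"][
            (t["ox"]["pos"] >= region.start) & (t["ox"]["pos"] < region.end)
        ]["ratio"].mean()
        case = np.mean([in_region(tables[f"s{i:02d}"]) for i in range(11, 21)])
        control = np.mean([in_region(tables[f"s{i:02d}"]) for i in range(1, 11)])
        assert case - control == pytest.approx(0.3, abs=0.03)

    def test_simplex_conserved_after_effects(self):
        """Even aggressive shifts with coupling keep every per-sample
        (m, h) on the simplex."""
        cpg_map = uniform_cpg_map(100)
        pos = cpg_map["pos"].to_numpy()
        regions = [
            RegionEffect("chr1", int(pos[0]), int(pos[49]) + 2, "5mC", 0.9, coupling=0.5),
            RegionEffect("chr1", int(pos[50]), int(pos[99]) + 2, "5hmC", -0.9, coupling=-0.8),
        ]
        truth = TruthSpec(
            cpg_map=cpg_map,
            group_labels=["control", "case", "case"],
            regions=regions,
            sample_effect_sd=0.3,
            seed=13,
        )
        _, _, M, H = true_levels(truth)
        assert np.all(M >= 0) and np.all(H >= 0)
        assert np.all(M + H <= 1 + 1e-12)

    def test_rejects_unsorted_map(self):
        bad = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 50], "strand": "+"}
        )
        with pytest.raises(ValueError):
            TruthSpec(cpg_map=bad, group_labels=["control"])


def test_region_effect_validation():
    with pytest.raises(ValueError):
        RegionEffect("chr1", 10, 5, "5mC", 0.2)
    with pytest.raises(ValueError):
        RegionEffect("chr1", 0, 10, "5mC", 1.5)
    with pytest.raises(ValueError):
        RegionEffect("chr1", 0, 10, "6mA", 0.2)
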