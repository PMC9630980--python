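"""Locus classification, allele dose, combinatorial effect analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from persistqtl import pleiotropy as pl
from persistqtl import sim


class TestClassify:
    @pytest.mark.parametrize("b,n,cls,ben_b,ben_n", [
        (0.3, 0.1, "general", "3S", "3S"),
        (0.3, -0.1, "antagonistic", "3S", "BY"),
        (-0.2, -0.2, "general", "BY", "BY"),
        (-0.2, 0.4, "antagonistic", "BY", "3S"),
    ])
    def test_quadrants(self, b, n, cls, ben_b, ben_n):
        out = pl.classify(b, n)
        assert out["locus_class"] == cls
        assert out["beneficial_brain"] == ben_b
        assert out["beneficial_nonbrain"] == ben_n
        assert not out["degenerate"]

    def test_zero_delta_degeneracy(self):
        out = pl.classify(0.0, -0.4)
        assert out["locus_class"] == "general" and out["degenerate"]
        with pytest.raises(ValueError):
            pl.classify(0.0, 0.0)
        with pytest.raises(ValueError):
            pl.classify(np.nan, 0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(b=st.floats(-5, 5), n=st.floats(-5, 5))
    def test_sign_symmetry(self, b, n):
        if b == 0 or n == 0:
            return
        both = pl.classify(b, n)
        negated = pl.classify(-b, -n)
        flipped = pl.classify(-b, n)
        assert both["locus_class"] == negated["locus_class"]
        assert flipped["locus_class"] != both["locus_class"]


def toy_classes(n_general=10, n_antagonistic=8):
    rows = []
    for i in range(n_general):
        rows.append({"locus_id": f"G{i}", "effect_marker": f"gm{i}",
                     "locus_class": "general",
                     "beneficial_brain": "3S", "beneficial_nonbrain": "3S"})
    for i in range(n_antagonistic):
        rows.append({"locus_id": f"A{i}", "effect_marker": f"am{i}",
                     "locus_class": "antagonistic",
                     "beneficial_brain": "BY", "beneficial_nonbrain": "3S"})
    return pd.DataFrame(rows)


class TestAlleleDose:
    def test_counts_beneficial_alleles(self):
        classes = toy_classes(3, 2)
        genotypes = pd.DataFrame(
            [[1, 1, 0, 0, 1],   # 2 of 3 general-3S; brain favours BY: 1 of 2
             [1, 1, 1, 1, 1]],  # all 3S: 3 general, 0 brain-favouring
            columns=["gm0", "gm1", "gm2", "am0", "am1"], index=["s1", "s2"])
        doses = pl.allele_dose(genotypes, classes)
        assert doses.loc["s1", "n_general_beneficial"] == 2
        assert doses.loc["s1", "n_brain_favoring"] == 1
        assert doses.loc["s2", "n_general_beneficial"] == 3
        assert doses.loc["s2", "n_brain_favoring"] == 0

    def test_threshold_labels(self):
        classes = toy_classes(10, 8)
        rng = np.random.default_rng(0)
        genotypes = pd.DataFrame(
            rng.integers(0, 2, size=(60, 18)),
            columns=list(classes["effect_marker"]),
            index=[f"s{i}" for i in range(60)])
        genotypes.iloc[0, :10] = 1         # 10 general-beneficial -> enriched
        genotypes.iloc[1, :10] = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]  # 2 -> depleted
        genotypes.iloc[2, 10:] = 0         # all BY at antagonistic: 8 brain-favouring
        doses = pl.allele_dose(genotypes, classes)
        assert doses.loc["s0", "general_class"] == "enriched"
        assert doses.loc["s1", "general_class"] == "depleted"
        assert doses.loc["s2", "brain_class"] == "enriched"

    def test_no_loci_all_neither(self):
        doses = pl.allele_dose(pd.DataFrame(index=["a", "b"]), toy_classes(0, 0))
        assert (doses["general_class"] == "neither").all()
        assert (doses["n_general_beneficial"] == 0).all()

    def test_auto_tune_caps_tails(self):
        classes = toy_classes(10, 8)
        rng = np.random.default_rng(1)
        genotypes = pd.DataFrame(
            rng.integers(0, 2, size=(500, 18)),
            columns=list(classes["effect_marker"]))
        doses = pl.allele_dose(genotypes, classes, auto_tune=True,
                               max_enriched_fraction=0.25)
        for col in ("general_class", "brain_class"):
            assert (doses[col] == "enriched").mean() <= 0.25
            assert (doses[col] == "depleted").mean() <= 0.25

    def test_neutral_cross_counts_are_binomial(self):
        # 10 general loci on 10 chromosomes segregate independently
        mm = sim.make_marker_map(64, seed=5)
        G = sim.simulate_cross(mm, 2000, 3.0, seed=6)
        model = sim.simulate_effect_model(mm, 10, 0, 0.3, seed=7,
                                          per_chromosome_cap=1)
        classes = pd.DataFrame({
            "locus_id": model.loci["marker_id"],
            "effect_marker": model.loci["marker_id"],
            "locus_class": "general",
            "beneficial_brain": "3S", "beneficial_nonbrain": "3S"})
        doses = pl.allele_dose(G, classes)
        counts = np.bincount(doses["n_general_beneficial"], minlength=11)
        expected = stats.binom.pmf(np.arange(11), 10, 0.5) * len(G)
        keep = expected > 5
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2.sf(chi2, keep.sum() - 1) > 0.001


class TestDoseRegression:
    def test_perfect_linear_relation(self):
        counts = np.arange(20)
        y = 0.1 * counts - 0.3
        r2, p, slope = pl.dose_regression(y, counts)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(0.1)

    def test_null_r2_expectation(self):
        rng = np.random.default_rng(2)
        n = 400
        r2s = [pl.dose_regression(rng.normal(size=n),
                                  rng.integers(0, 11, size=n))[0]
               for _ in range(200)]
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=2e-3)

    def test_constant_count_rejected(self):
        with pytest.raises(ValueError):
            pl.dose_regression([1.0, 2.0, 3.0], [4, 4, 4])


class TestTimeSlope:
    def test_two_point_line(self):
        assert pl.time_slope([0.0, 0.8], [1, 5]) == pytest.approx(0.2)
        assert pl.time_slope([0.3, 0.3, 0.3], [1, 2, 5]) == pytest.approx(0.0)

    def test_six_point_normal_equations_oracle(self):
        t = np.array([1, 1, 2, 2, 5, 5], dtype=float)
        y = np.array([0.1, 0.3, 0.2, 0.5, 0.9, 1.1])
        X = np.column_stack([np.ones(6), t])
        slope = np.linalg.solve(X.T @ X, X.T @ y)[1]
        assert pl.time_slope(y, t) == pytest.approx(slope, rel=1e-10)

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            pl.time_slope([1.0, 2.0], [1, 1])


class TestContingency:
    def test_independent_table(self):
        doses = pd.DataFrame({
            "general_class": ["enriched"] * 50 + ["neither"] * 50,
            "brain_class": ["enriched"] * 50 + ["neither"] * 50,
        }, index=[f"s{i}" for i in range(100)])
        slopes = pd.Series([1.0, -1.0] * 50, index=doses.index)
        chi2, p, table = pl.enrichment_contingency(doses, slopes)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=st.integers(1, 50), b=st.integers(1, 50),
           c=st.integers(1, 50), d=st.integers(1, 50))
    def test_matches_closed_form(self, a, b, c, d):
        # realise the table {enriched-both vs not} x {positive slope vs not}
        gen = ["enriched"] * (a + b) + ["neither"] * (c + d)
        brain = ["enriched"] * (a + b) + ["neither"] * (c + d)
        slopes = [1.0] * a + [-1.0] * b + [1.0] * c + [-1.0] * d
        idx = [f"s{i}" for i in range(a + b + c + d)]
        doses = pd.DataFrame({"general_class": gen, "brain_class": brain}, index=idx)
        chi2, _, table = pl.enrichment_contingency(doses, pd.Series(slopes, index=idx))
        assert table.tolist() == [[a, b], [c, d]]
        n = a + b + c + d
        oracle = (n * (a * d - b * c) ** 2
                  / ((a + b) * (c + d) * (a + c) * (b + d)))
        assert chi2 == pytest.approx(oracle, rel=1e-9)

    def test_degenerate_margin_rejected(self):
        doses = pd.DataFrame({"general_class": ["enriched"] * 4,
                              "brain_class": ["enriched"] * 4},
                             index=list("abcd"))
        slopes = pd.Series([1.0, 2.0, 0.5, 0.1], index=doses.index)
        with pytest.raises(ValueError):
            pl.enrichment_contingency(doses, slopes)


class TestTimecourseSummary:
    def _setup(self):
        samples = ["d1_a", "d1_b", "d5_a", "d5_b"]
        meta = pd.DataFrame({"day": [1, 1, 5, 5]}, index=samples)
        doses = pd.DataFrame({
            "general_class": ["enriched", "enriched", "depleted"],
            "brain_class": ["enriched", "depleted", "depleted"],
        }, index=["g1", "g2", "g3"])
        return samples, meta, doses

    def test_no_change_gives_zero(self):
        samples, meta, doses = self._setup()
        mat = pd.DataFrame(np.tile([0.4, -0.2, 0.1], (4, 1)),
                           index=samples, columns=["g1", "g2", "g3"])
        out = pl.timecourse_summary(mat, meta, doses, n_boot=100, seed=0)
        assert np.allclose(out["mean_change"], 0.0)

    def test_singleton_group_bootstrap_is_degenerate(self):
        samples, meta, doses = self._setup()
        mat = pd.DataFrame([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0],
                            [1.0, 0.5, -0.5], [1.0, 0.5, -0.5]],
                           index=samples, columns=["g1", "g2", "g3"])
        out = pl.timecourse_summary(mat, meta, doses, n_boot=100, seed=0)
        row = out[(out["general_class"] == "enriched")
                  & (out["brain_class"] == "enriched")].iloc[0]
        assert row["n_segregants"] == 1
        assert row["boot_low"] == row["boot_high"] == pytest.approx(1.0)
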