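"""The synthetic experiment generator: meiosis, planted loci, selection,
bottlenecks and sequencing noise."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from persistqtl import sim
from tests.conftest import make_map


class TestSimulateCross:
    def test_no_recombination_gives_parental_chromosomes(self, small_map):
        G = sim.simulate_cross(small_map, 25, expected_crossovers_per_chromosome=0.0,
                               seed=5)
        for chrom, grp in small_map.groupby("chromosome"):
            block = G[grp["marker_id"]].to_numpy()
            assert np.all((block.min(axis=1) == block.max(axis=1)))

    def test_marginal_allele_frequency_balanced(self, small_map):
        G = sim.simulate_cross(small_map, 2000, 3.0, seed=6)
        freqs = G.mean(axis=0)
        assert freqs.between(0.45, 0.55).all()

    def test_switch_count_matches_poisson_odd_crossover_oracle(self):
        # observed block switches = gaps with an odd Poisson crossover count;
        # oracle computed exactly from the gap structure of the map
        mm = sim.make_marker_map(512, seed=7)
        G = sim.simulate_cross(mm, 1000, 1.0, seed=8)
        arr = G.to_numpy()
        expected, observed, n_chrom = 0.0, 0.0, 0
        for chrom, grp in mm.groupby("chromosome"):
            pos = grp["position"].to_numpy(dtype=float)
            L = sim.CHROMOSOME_LENGTHS[chrom]
            gaps = np.diff(pos) / L  # fraction of the Poisson(1) intensity
            expected += np.sum((1 - np.exp(-2 * gaps)) / 2)
            cols = grp.index.to_numpy()
            observed += np.mean(np.sum(np.abs(np.diff(arr[:, cols], axis=1)), axis=1))
            n_chrom += 1
        assert observed / n_chrom == pytest.approx(expected / n_chrom, abs=0.05)

    def test_rejects_empty_map_and_bad_args(self, small_map):
        with pytest.raises(ValueError):
            sim.simulate_cross(small_map.iloc[:0], 5)
        with pytest.raises(ValueError):
            sim.simulate_cross(small_map, 0)

    def test_seed_reproducibility(self, small_map):
        a = sim.simulate_cross(small_map, 30, seed=9)
        b = sim.simulate_cross(small_map, 30, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestEffectModel:
    def test_planted_class_structure(self, small_map):
        model = sim.simulate_effect_model(small_map, n_general=10, n_antagonistic=8,
                                          effect_scale=0.3, seed=1,
                                          min_separation_bp=10_000)
        loci = model.loci
        assert len(loci) == 18
        general = loci[loci["locus_class"] == "general"]
        antagonistic = loci[loci["locus_class"] == "antagonistic"]
        assert len(general) == 10 and len(antagonistic) == 8
        s_cols = [f"s_{o}" for o in sim.ORGANS]
        for _, row in general.iterrows():
            assert len(set(np.sign(row[s_cols]))) == 1
        for _, row in antagonistic.iterrows():
            for organ in sim.NONBRAIN_ORGANS:
                assert np.sign(row[f"s_{organ}"]) == -np.sign(row["s_brain"])
        assert loci["marker_id"].is_unique

    def test_empty_request_and_capacity_error(self, small_map):
        model = sim.simulate_effect_model(small_map, 0, 0, 0.2, seed=1)
        assert len(model.loci) == 0
        one_marker = make_map({1: 1})
        with pytest.raises(ValueError):
            sim.simulate_effect_model(one_marker, 2, 0, 0.2, per_chromosome_cap=1)
        with pytest.raises(ValueError):
            sim.simulate_effect_model(small_map, 1, 0, effect_scale=0.0)


@pytest.fixture(scope="module")
def small_experiment(small_map):
    G = sim.simulate_cross(small_map, 60, 3.0, seed=31)
    model = sim.simulate_effect_model(small_map, 2, 1, 0.3, seed=32,
                                      min_separation_bp=10_000)
    assignment = sim.make_barcode_assignment(G.index, n_triplicated=20, seed=33)
    design = sim.ExperimentDesign(sequencing_depth=200_000)
    counts, meta, truth = sim.simulate_experiment(G, assignment, model, design, seed=34)
    return G, model, assignment, design, counts, meta, truth


class TestSimulateExperiment:
    def test_count_rows_sum_to_depth(self, small_experiment):
        _, _, _, design, counts, meta, _ = small_experiment
        totals = counts.sum(axis=1)
        nonzero = totals[totals > 0]
        assert (nonzero == design.sequencing_depth).all()
        assert len(meta) == len(counts)
        organ = meta[meta["type"] == "organ"]
        assert len(organ) == 5 * 2 * 2 * 3 * 3

    def test_neutral_model_reproduces_t0_frequencies(self, small_map):
        G = sim.simulate_cross(small_map, 60, 3.0, seed=41)
        model = sim.simulate_effect_model(small_map, 0, 0, 0.2, seed=42)
        assignment = sim.make_barcode_assignment(G.index, n_triplicated=0, seed=43)
        design = sim.ExperimentDesign(
            sequencing_depth=2_000_000, plate_growth_sigma=0.0,
            cfu_scale={o: 5e6 for o in sim.ORGANS})
        counts, meta, truth = sim.simulate_experiment(G, assignment, model,
                                                      design, seed=44)
        f0 = truth["t0_frequencies"]
        organ = counts.loc[meta.index[meta["type"] == "organ"]]
        freq = organ.div(organ.sum(axis=1), axis=0)
        rel = (freq.mean(axis=0) - f0) / f0
        assert np.abs(rel).max() < 0.05

    def test_positive_selection_enriches_carriers_by_day(self, small_map):
        G = sim.simulate_cross(small_map, 60, 3.0, seed=51)
        model = sim.simulate_effect_model(small_map, 1, 0, 0.5, seed=52)
        marker = model.loci["marker_id"].iloc[0]
        sign = np.sign(model.loci["s_brain"].iloc[0])
        assignment = sim.make_barcode_assignment(G.index, n_triplicated=0, seed=53)
        counts, meta, _ = sim.simulate_experiment(
            G, assignment, model, sim.ExperimentDesign(sequencing_depth=500_000),
            seed=54)
        carrier = (G[marker].to_numpy() == (1 if sign > 0 else 0))
        freq = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
        for organ in sim.ORGANS:
            shares = {}
            for day in (1, 5):
                rows = meta.index[(meta["organ"] == organ) & (meta["day"] == day)]
                shares[day] = float(freq.loc[rows].iloc[:, carrier].sum(axis=1).mean())
            assert shares[5] > shares[1], organ

    def test_bottleneck_lowers_brain_replicate_agreement(self, small_experiment):
        G, _, assignment, _, counts, meta, _ = small_experiment
        freq = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
        trip = assignment[assignment["replicate_index"].isin([1, 2])]
        b1 = trip[trip["replicate_index"] == 1].set_index("segregant_id")["barcode"]
        b2 = trip[trip["replicate_index"] == 2].set_index("segregant_id")["barcode"]
        b2 = b2.reindex(b1.index).dropna()
        b1 = b1.loc[b2.index]

        def mean_corr(organ):
            rows = meta.index[meta["organ"] == organ]
            cors = []
            for s in rows:
                x = freq.loc[s, b1.to_numpy()].to_numpy(dtype=float)
                y = freq.loc[s, b2.to_numpy()].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() > 5 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                    cors.append(np.corrcoef(x[ok], y[ok])[0, 1])
            return float(np.mean(cors))

        assert mean_corr("brain") < mean_corr("liver")

    def test_depth_zero_rejected(self, small_experiment):
        G, model, assignment, _, _, _, _ = small_experiment
        with pytest.raises(ValueError):
            sim.simulate_experiment(G, assignment, model,
                                    sim.ExperimentDesign(sequencing_depth=0))

    def test_seed_reproducibility(self, small_map, small_experiment):
        G, model, assignment, design, counts, _, _ = small_experiment
        counts2, _, _ = sim.simulate_experiment(G, assignment, model, design, seed=34)
        pd.testing.assert_frame_equal(counts, counts2)


class TestBarcodeAssignment:
    def test_structure_and_separation(self):
        ids = [f"s{i}" for i in range(30)]
        bc = sim.make_barcode_assignment(ids, n_triplicated=10, seed=3)
        assert len(bc) == 10 * 3 + 20
        assert bc["barcode"].is_unique
        counts = bc["segregant_id"].value_counts()
        assert (counts.loc[[f"s{i}" for i in range(10)]] == 3).all()
        enc = np.array([[ord(c) for c in b] for b in bc["barcode"]])
        d = (enc[:, None, :] != enc[None, :, :]).sum(axis=2)
        np.fill_diagonal(d, 99)
        assert d.min() >= 7


class TestObservedCalls:
    def test_high_coverage_no_error_recovers_truth(self, small_genotypes, small_map):
        obs = sim.simulate_observed_calls(small_genotypes, mean_coverage=60,
                                          per_read_error=0.0, seed=2)
        arr = obs.to_numpy()
        truth = small_genotypes.to_numpy()
        called = np.isfinite(arr)
        assert called.mean() > 0.99
        assert np.array_equal(arr[called], truth[called].astype(float))

    def test_missing_or_wrong_rate_matches_closed_form(self, small_map):
        # P(miss) = sum_d Pois(d; 2) * P(majority wrong or tied or d = 0)
        cov, err = 2.0, 0.05
        p = 0.0
        for d in range(0, 60):
            pd_ = stats.poisson.pmf(d, cov)
            if d == 0:
                p += pd_
                continue
            k = np.arange(0, d + 1)  # correct reads
            pk = stats.binom.pmf(k, d, 1 - err)
            p += pd_ * pk[k / d <= 0.5].sum()
        G = sim.simulate_cross(sim.make_marker_map(512, seed=61), 200, 3.0, seed=62)
        obs = sim.simulate_observed_calls(G, cov, err, seed=63)
        arr = obs.to_numpy()
        truth = G.to_numpy()
        # site fails when missing, tied, or majority call disagrees with truth
        frac_3s = np.where(truth == 1, arr, 1 - arr)
        failed = ~np.isfinite(arr) | (frac_3s <= 0.5)
        assert failed.mean() == pytest.approx(p, abs=0.01)

    def test_preconditions(self, small_genotypes):
        with pytest.raises(ValueError):
            sim.simulate_observed_calls(small_genotypes, mean_coverage=0)
        with pytest.raises(ValueError):
            sim.simulate_observed_calls(small_genotypes, 2.0, per_read_error=0.6)
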