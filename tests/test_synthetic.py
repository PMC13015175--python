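import numpy as np
import pytest

from stmap.geo_weights import binary_weights, row_standardize
from stmap.spatial_stats import global_morans_i
from stmap.standardize import compute_sir_panel
from stmap.synthetic_data import (SyntheticConfig, Truth, generate_dataset,
                                  geojson_bytes, make_regions,
                                  null_scenario, paper_scenario,
                                  simulate_panel, simulate_truth)


class TestMakeRegions:
    def test_paper_scenario_has_132_cities(self):
        fc, graph, provinces = make_regions(paper_scenario())
        assert graph.n == 132
        assert len(fc["features"]) == 132
        assert len(set(provinces.values())) > 1

    def test_2x2_is_queen_complete(self):
        fc, graph, _ = make_regions(SyntheticConfig(nx=2, ny=2))
        assert all(graph.degree(r) == 3 for r in graph.region_ids)

    def test_geojson_bytes_deterministic(self):
        a = geojson_bytes(make_regions(paper_scenario(seed=1))[0])
        b = geojson_bytes(make_regions(paper_scenario(seed=1))[0])
        assert a == b

    def test_provinces_are_contiguous_blocks(self):
        _, graph, provinces = make_regions(
            SyntheticConfig(nx=4, ny=4, province_block=(2, 2)))
        assert len(set(provinces.values())) == 4


class TestSimulateTruth:
    def test_degenerate_precision_kills_spatial_field(self):
        cfg = SyntheticConfig(nx=6, ny=6, tau_b=1e8, seed=1)
        _, graph, _ = make_regions(cfg)
        truth = simulate_truth(cfg, graph)
        assert np.abs(truth.b).max() < 1e-2
        expected = cfg.alpha + truth.gamma + truth.phi
        assert np.allclose(truth.eta.mean(axis=0), expected, atol=0.05)

    def test_omega_zero_b_has_null_moran(self):
        cfg = SyntheticConfig(nx=6, ny=6, omega=0.0, tau_b=1.0)
        _, graph, _ = make_regions(cfg)
        w = row_standardize(binary_weights(graph))
        e_null = -1.0 / (graph.n - 1)
        stats = []
        rng = np.random.default_rng(99)
        for _ in range(200):
            truth = simulate_truth(cfg, graph, rng)
            res = global_morans_i(truth.b, w, n_perm=2, seed=1)
            stats.append(res.I)
        # mean of Moran's I over replicates matches the null expectation
        se = np.std(stats, ddof=1) / np.sqrt(len(stats))
        assert np.mean(stats) == pytest.approx(e_null, abs=4 * se + 0.01)

    def test_high_omega_with_gradient_gives_positive_moran(self):
        cfg = SyntheticConfig(nx=8, ny=8, omega=0.95, tau_b=1.0,
                              gradient_amplitude=3.0)
        _, graph, _ = make_regions(cfg)
        w = row_standardize(binary_weights(graph))
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            truth = simulate_truth(cfg, graph, rng)
            res = global_morans_i(truth.b, w, n_perm=99, seed=3)
            hits += (res.I > 0) and (res.p <= 0.05)
        assert hits >= 0.95 * n_rep

    def test_interaction_respects_constraints(self):
        cfg = SyntheticConfig(nx=5, ny=5, seed=3,
                              delta_pattern="sparse_positive")
        _, graph, _ = make_regions(cfg)
        truth = simulate_truth(cfg, graph)
        # type IV with AR(1): per-year spatial sum-to-zero
        assert np.allclose(truth.delta.sum(axis=0), 0, atol=1e-8)


class TestSimulatePanel:
    def test_null_truth_sir_centred_on_one(self):
        cfg = null_scenario(seed=11, nx=10, ny=10)
        ds = generate_dataset(cfg)
        out = compute_sir_panel(ds.panel, ds.composition, ds.rates)
        m = out["SIR"].mean()
        se = out["SIR"].std(ddof=1) / np.sqrt(len(out))
        assert m == pytest.approx(1.0, abs=3 * se)

    def test_fixed_seed_reproducible(self):
        cfg = SyntheticConfig(nx=5, ny=5, seed=21)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert a.panel.equals(b.panel)
        assert np.array_equal(a.truth.eta, b.truth.eta)

    def test_doubling_population_doubles_totals(self):
        cfg = SyntheticConfig(nx=8, ny=8, seed=4)
        ds = generate_dataset(cfg)
        cfg2 = SyntheticConfig(nx=8, ny=8, seed=4, pop_median=2 * cfg.pop_median)
        ds2 = generate_dataset(cfg2)
        t1, t2 = ds.panel.cases.sum(), ds2.panel.cases.sum()
        se = np.sqrt(t1 + t2)
        assert t2 - 2 * t1 == pytest.approx(0.0, abs=4 * se)

    def test_counts_are_nonnegative_integers(self):
        ds = generate_dataset(SyntheticConfig(nx=4, ny=4, seed=2))
        assert (ds.panel.cases >= 0).all()
        assert (ds.panel.cases % 1 == 0).all()


class TestPaperScenario:
    @pytest.fixture(scope="class")
    def dataset(self):
        return generate_dataset(paper_scenario(seed=2))

    def test_crude_rate_rises_year_over_year(self):
        rises = 0
        for seed in range(10):
            ds = generate_dataset(paper_scenario(seed=seed))
            tot = ds.panel.groupby("year").apply(
                lambda g: g.cases.sum() / g.male_pop.sum(),
                include_groups=False)
            rises += all(np.diff(tot.values) > 0)
        assert rises >= 9

    def test_majority_negative_interaction(self, dataset):
        frac_neg = (dataset.truth.delta < 0).mean()
        assert frac_neg > 0.6
        assert (dataset.truth.delta > 1.0).any()  # small positive tail

    def test_pipeline_runs_end_to_end_without_external_input(self, dataset):
        out = compute_sir_panel(dataset.panel, dataset.composition,
                                dataset.rates)
        assert len(out) == 132 * 4
        w = row_standardize(binary_weights(dataset.graph))
        vals = out[out.year == 2016].set_index("city_id").loc[
            list(dataset.graph.region_ids), "SIR"].to_numpy()
        res = global_morans_i(vals, w, n_perm=99, seed=1)
        assert np.isfinite(res.I)
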