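import numpy as np
import pytest

from stmap.bayes_stmodel.effects import (ar1_precision, ar2_precision,
                                         build_icar_precision,
                                         build_interaction,
                                         build_temporal_block,
                                         icar_scale_factor, rw_precision)
from stmap.geo_weights import build_queen_adjacency

from conftest import lattice_polygons


def _rank(m):
    return int(np.linalg.matrix_rank(m, tol=1e-8))


class TestICAR:
    def test_laplacian_row_sums_zero(self, grid6):
        blk = build_icar_precision(grid6, scaled=False)
        assert np.allclose(blk.Q.sum(axis=1), 0.0, atol=1e-12)

    def test_path3_eigenvalues(self):
        g = build_queen_adjacency(lattice_polygons(3, 1))
        blk = build_icar_precision(g, scaled=False)
        vals = np.sort(np.linalg.eigvalsh(blk.Q))
        assert np.allclose(vals, [0.0, 1.0, 3.0], atol=1e-10)
        assert blk.rank == 2

    def test_disconnected_components_get_one_constraint_each(self):
        polys = {**{f"L{k}": p for k, p in
                    enumerate(lattice_polygons(2, 1).values())}}
        from conftest import square
        polys["R0"] = square(5, 5)
        polys["R1"] = square(6, 5)
        g = build_queen_adjacency(polys)
        blk = build_icar_precision(g, scaled=False)
        assert len(g.components) == 2
        assert blk.n_constraints == 2
        assert blk.rank == 2

    def test_scaled_icar_unit_geometric_mean_variance(self, grid6):
        blk = build_icar_precision(grid6, scaled=True)
        sig = blk.generalized_inverse()
        gm = np.exp(np.mean(np.log(np.diag(sig))))
        assert gm == pytest.approx(1.0, abs=1e-8)

    def test_scale_factor_positive_and_matches_block(self, grid6):
        blk = build_icar_precision(grid6, scaled=True)
        assert blk.scale_factor == pytest.approx(icar_scale_factor(grid6))

    def test_sample_respects_constraints(self, grid6, rng):
        blk = build_icar_precision(grid6, scaled=True)
        x = blk.sample(rng)
        assert abs(x.sum()) < 1e-8


class TestTemporalBlocks:
    def test_ar1_rho_zero_identity(self):
        assert np.allclose(ar1_precision(5, 0.0), np.eye(5))

    def test_rw1_rank_and_rowsums(self):
        blk = build_temporal_block("rw1", 4)
        assert blk.rank == 3
        assert np.allclose(blk.Q.sum(axis=1), 0)
        assert _rank(blk.Q) == 3

    def test_rw2_rank(self):
        blk = build_temporal_block("rw2", 5)
        assert blk.rank == 3
        assert _rank(blk.Q) == 3

    def test_ar1_matches_analytic_covariance_inverse(self):
        rho, T = 0.5, 3
        cov = np.array([[1, rho, rho ** 2],
                        [rho, 1, rho],
                        [rho ** 2, rho, 1]])
        assert np.allclose(ar1_precision(T, rho), np.linalg.inv(cov),
                           atol=1e-12)

    def test_ar1_unit_marginal_variance(self):
        for rho in (0.3, -0.7, 0.95):
            cov = np.linalg.inv(ar1_precision(6, rho))
            assert np.allclose(np.diag(cov), 1.0, atol=1e-10)

    def test_ar2_unit_marginal_variance(self):
        cov = np.linalg.inv(ar2_precision(6, 0.4, 0.2))
        assert np.allclose(np.diag(cov), 1.0, atol=1e-8)

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ar1_precision(4, 1.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            build_temporal_block("rw2", 2)


class TestInteractions:
    @pytest.fixture()
    def factors(self):
        g = build_queen_adjacency(lattice_polygons(4, 1))  # path of 4
        sp = build_icar_precision(g, scaled=False)
        tm = build_temporal_block("ar1", 4, {"rho": 0.5})
        return sp, tm

    def test_type_i_identity(self, factors):
        sp, tm = factors
        blk = build_interaction("typeI", sp, tm)
        assert np.allclose(blk.Q, np.eye(16))
        assert blk.rank == 16
        assert blk.n_constraints == 0

    def test_type_iv_rank_and_constraints(self, factors):
        sp, tm = factors
        blk = build_interaction("typeIV", sp, tm)
        assert blk.rank == 3 * 4 == 12
        assert _rank(blk.Q) == 12
        # constraints: per-year spatial sums
        d = np.arange(16.0)
        proj = blk.project(d).reshape(4, 4)
        assert np.allclose(proj.sum(axis=0), 0, atol=1e-10)

    def test_type_ii_independent_walks(self):
        g = build_queen_adjacency(lattice_polygons(3, 1))
        sp = build_icar_precision(g, scaled=False)
        tm = build_temporal_block("rw1", 4)
        blk = build_interaction("typeII", sp, tm)
        assert blk.rank == 3 * 3  # n * (T - 1)
        assert _rank(blk.Q) == 9
        proj = blk.project(np.arange(12.0)).reshape(3, 4)
        assert np.allclose(proj.sum(axis=1), 0, atol=1e-10)

    def test_type_iii_structure(self, factors):
        sp, _ = factors
        tm = build_temporal_block("ar1", 3, {"rho": 0.2})
        blk = build_interaction("typeIII", sp, tm)
        assert blk.rank == 3 * 3
        assert np.allclose(blk.Q, np.kron(sp.Q, np.eye(3)))

    def test_kron_null_space_spanned_by_constraints(self, factors):
        sp, tm = factors
        blk = build_interaction("typeIV", sp, tm)
        null_dim = blk.dim - _rank(blk.Q)
        cons_rank = _rank(blk.constraints)
        assert cons_rank == null_dim

    def test_colors_are_proper(self, factors):
        sp, tm = factors
        blk = build_interaction("typeIV", sp, tm)
        q = blk.Q
        for cls in blk.colors:
            sub = q[np.ix_(cls, cls)]
            off = sub - np.diag(np.diag(sub))
            assert np.abs(off).max() < 1e-12
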