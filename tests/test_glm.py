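"""ReML connectivity estimator: component family, recovery, calibration,
edge statistics, symmetrization, motion residualization."""

import numpy as np
import pytest

import lesionconn as lc
from lesionconn.glm import z_from_t


def _ar1(rng, T, phi, sd=1.0):
    y = np.empty(T)
    y[0] = rng.standard_normal() * sd / np.sqrt(1 - phi * phi)
    for t in range(1, T):
        y[t] = phi * y[t - 1] + sd * rng.standard_normal()
    return y


class TestARFamily:
    def test_half_life_definition(self):
        fam = lc.ar_family(100)
        assert len(fam.half_lives) == 8
        q_h1 = fam.components[1]          # h = 1 TR
        assert q_h1[1, 0] == pytest.approx(0.5)
        q_h64 = fam.components[-1]
        assert q_h64[64, 0] == pytest.approx(0.5)
        assert q_h64[99, 35] == pytest.approx(0.5)
        for Q in fam.components:
            assert np.allclose(np.diag(Q), 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lc.ar_family(4)
        with pytest.raises(ValueError):
            lc.ar_family(50, half_lives=(1.0, -2.0))


class TestREMLFit:
    def test_noiseless_recovers_beta_exactly(self, rng, desk_family):
        T = 148
        X = np.column_stack([rng.standard_normal(T), np.ones(T)])
        b = np.array([2.0, 1.0])
        res = lc.reml_fit(X @ b + 1e-10 * rng.standard_normal(T), X,
                          desk_family)
        assert np.allclose(res.beta, b, atol=1e-6)

    def test_white_noise_effective_df_near_T_minus_1(self, desk_family):
        """On white noise with an intercept-only design, the Satterthwaite
        df should sit near T - 1 (median over simulations)."""
        T = 148
        rng = np.random.default_rng(0)
        dfs = [lc.reml_fit(rng.standard_normal(T), np.ones((T, 1)),
                           desk_family).eff_df for _ in range(200)]
        assert np.median(dfs) == pytest.approx(T - 1, rel=0.05)

    def test_ar1_lag_ratio_recovery(self):
        """Fitted V reproduces the lag-1/lag-0 ratio of AR(1) data."""
        T, phi = 600, 0.5
        fam = lc.ar_family(T)
        ratios = []
        for s in range(3):
            y = _ar1(np.random.default_rng(s), T, phi)
            res = lc.reml_fit(y, np.ones((T, 1)), fam)
            ratios.append(res.V[1, 0] / res.V[0, 0])
        assert np.median(ratios) == pytest.approx(phi, abs=0.05)

    def test_rank_deficient_design_raises(self, rng, desk_family):
        x = rng.standard_normal(148)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError):
            lc.reml_fit(rng.standard_normal(148), X, desk_family)

    def test_hyperparameters_nonnegative(self, rng, desk_family):
        res = lc.reml_fit(rng.standard_normal(148), np.ones((148, 1)),
                          desk_family)
        assert (res.lam >= 0).all()


class TestEdgeStatistic:
    def test_near_identical_series_give_large_z(self, rng, desk_family):
        s = rng.standard_normal(148)
        est = lc.edge_statistic(s + 0.01 * rng.standard_normal(148), s,
                                None, desk_family)
        assert est.z > 10

    def test_fisher_z_oracle_for_planted_correlation(self, desk_family):
        """Planted r = 0.5 at T = 148 with a constant-only nuisance: the
        mean edge Z matches the large-sample Fisher transform
        atanh(0.5) * sqrt(T - 3) ~ 6.6."""
        rng = np.random.default_rng(3)
        zs = []
        for _ in range(120):
            x = rng.standard_normal(148)
            y = 0.5 * x + np.sqrt(0.75) * rng.standard_normal(148)
            zs.append(lc.edge_statistic(y, x, None, desk_family).z)
        oracle = np.arctanh(0.5) * np.sqrt(145)
        assert np.mean(zs) == pytest.approx(oracle, abs=0.5)

    def test_scale_invariance(self, rng, desk_family, desk_design):
        x = rng.standard_normal(148)
        y = 0.4 * x + rng.standard_normal(148)
        z1 = lc.edge_statistic(y, x, desk_design, desk_family).z
        z2 = lc.edge_statistic(3.0 * y, 7.0 * x, desk_design, desk_family).z
        assert z1 == pytest.approx(z2, abs=1e-6)

    def test_confound_span_invariance(self, rng, desk_family):
        """Adding a nuisance column inside the span of the existing design
        leaves z unchanged after rank handling."""
        x = rng.standard_normal(148)
        y = 0.4 * x + rng.standard_normal(148)
        nuis = rng.standard_normal((148, 3))
        aug = np.column_stack([nuis, nuis[:, 0] - 2 * nuis[:, 2]])
        z1 = lc.edge_statistic(y, x, nuis, desk_family).z
        with pytest.warns(UserWarning, match="collinear"):
            z2 = lc.edge_statistic(y, x, aug, desk_family).z
        assert z1 == pytest.approx(z2, abs=1e-6)

    def test_effective_df_shrinks_with_nuisance_columns(self, rng,
                                                        desk_family):
        x = rng.standard_normal(148)
        y = rng.standard_normal(148)
        dfs = []
        for p in (1, 5, 20):
            nuis = rng.standard_normal((148, p))
            dfs.append(lc.edge_statistic(y, x, nuis, desk_family).eff_df)
        assert dfs[0] > dfs[1] > dfs[2]


class TestZFromT:
    def test_sign_and_zero(self):
        assert z_from_t(0.0, 40) == 0.0
        assert z_from_t(-2.0, 40) == -z_from_t(2.0, 40)

    def test_extreme_t_is_finite(self):
        z = z_from_t(1e6, 40)
        assert np.isfinite(z) and z > 30

    def test_matches_normal_for_large_df(self):
        assert z_from_t(1.96, 1e9) == pytest.approx(1.96, abs=1e-3)


class TestConnectivityMatrix:
    def test_symmetry_and_finite_edges(self, dmn_cohort, desk_family):
        spec, cohort, part = dmn_cohort
        conn = lc.connectivity_matrix(cohort[0].roi_series, None,
                                      desk_family)
        iu = np.triu_indices(8, 1)
        assert np.allclose(conn.z, conn.z.T, equal_nan=True)
        assert np.isfinite(conn.z[iu]).all()
        assert conn.z[iu].size == 28
        assert np.isnan(np.diag(conn.z)).all()

    def test_permutation_equivariance(self, rng, desk_family):
        Y = rng.standard_normal((6, 148))
        perm = rng.permutation(6)
        a = lc.connectivity_matrix(Y, None, desk_family).z
        b = lc.connectivity_matrix(Y[perm], None, desk_family).z
        assert np.allclose(a[np.ix_(perm, perm)], b, equal_nan=True,
                           atol=1e-8)

    def test_pooled_and_per_edge_agree(self, dmn_cohort, desk_family,
                                       desk_design):
        spec, cohort, part = dmn_cohort
        Y = cohort[0].roi_series
        zp = lc.connectivity_matrix(Y, desk_design, desk_family,
                                    method="pooled").z
        ze = lc.connectivity_matrix(Y, desk_design, desk_family,
                                    method="per-edge").z
        iu = np.triu_indices(8, 1)
        assert np.corrcoef(zp[iu], ze[iu])[0, 1] > 0.9

    def test_extra_lesion_series_appended(self, rng, desk_family):
        Y = rng.standard_normal((4, 148))
        conn = lc.connectivity_matrix(
            Y, None, desk_family,
            extra_series={"lesion": rng.standard_normal(148)})
        assert conn.n_rois == 5
        assert conn.roi_ids[-1] == "lesion"


class TestResidualizeMotion:
    def test_orthogonal_to_motion_after_residualization(self, rng):
        rd = rng.standard_normal(30)
        edge = 0.5 * rd + rng.standard_normal(30)
        out = lc.residualize_motion(edge, rd)
        assert abs(np.corrcoef(out, rd)[0, 1]) < 1e-10

    def test_pure_motion_edge_has_zero_residual_variance(self, rng):
        rd = rng.standard_normal(20)
        out = lc.residualize_motion(2.0 * rd, rd)
        assert out.var() < 1e-20

    def test_mean_preserved(self, rng):
        rd = rng.standard_normal(25)
        edge = rng.standard_normal(25) + 3.0
        out = lc.residualize_motion(edge, rd)
        assert out.mean() == pytest.approx(edge.mean(), abs=1e-10)

    def test_constant_rd_warns_and_passes_through(self, rng):
        edge = rng.standard_normal(10)
        with pytest.warns(UserWarning):
            out = lc.residualize_motion(edge, np.full(10, 0.2))
        assert np.array_equal(out, edge)
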