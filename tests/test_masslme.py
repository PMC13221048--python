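"""Rank transform, mixed-model fitter (vs. statsmodels oracle) and the
weighted-cluster-mass permutation machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from olfosc.masslme import (
    StatMap,
    fit_lme_map,
    fit_random_intercept,
    permute_within_participant,
    rank_inverse_normal,
    wcm_test,
)


class TestRankInverseNormal:
    def test_symmetric_zero_mean_small_input(self):
        out = rank_inverse_normal(np.array([1.0, 2.0, 3.0]))
        assert abs(out.mean()) < 1e-12
        assert np.allclose(out, -out[::-1])

    @given(
        st.lists(st.integers(-1000, 1000), min_size=4, max_size=30, unique=True),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_rescaling_invariance(self, vals, scale, shift):
        v = np.array(vals, dtype=float) / 7.3
        np.testing.assert_array_equal(
            rank_inverse_normal(v), rank_inverse_normal(v * scale + shift)
        )

    def test_blom_scores_match_direct_quantiles(self):
        """n=5 distinct values reproduce the closed-form Blom scores."""
        v = np.array([10.0, 3.0, 47.0, 0.5, 21.0])
        expected = sstats.norm.ppf(
            (sstats.rankdata(v) - 3.0 / 8.0) / (5 + 0.25)
        )
        np.testing.assert_allclose(rank_inverse_normal(v), expected)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_inverse_normal(np.array([2.0, 2.0, 2.0, 2.0]))


class TestFitRandomIntercept:
    def test_matches_statsmodels_mixedlm(self, rng):
        """Profiled-REML solver agrees with the general REML fit."""
        sm = pytest.importorskip("statsmodels.api")
        G, m = 6, 40
        n = G * m
        groups = np.repeat(np.arange(G), m)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 4))])
        u = rng.normal(0, 0.7, G)
        Y = np.column_stack(
            [
                X @ np.array([0.5, 0.3, 0.0, -0.2, 0.1])
                + u[groups]
                + rng.standard_normal(n)
                for _ in range(4)
            ]
        )
        fit = fit_random_intercept(Y, X, groups)
        for j in range(Y.shape[1]):
            res = sm.regression.mixed_linear_model.MixedLM(
                Y[:, j], X, groups
            ).fit(reml=True)
            t_ref = res.fe_params / res.bse_fe
            np.testing.assert_allclose(fit["t"][j], t_ref, rtol=0.01, atol=0.02)
            np.testing.assert_allclose(fit["beta"][j], res.fe_params, atol=5e-3)


def _behav_frame(rng, n_part=6, n_trials=30):
    rows = []
    for p in range(n_part):
        rows.append(
            pd.DataFrame(
                {
                    "participant": f"P{p}",
                    "intensity": rng.uniform(0, 10, n_trials),
                    "valence": rng.uniform(0, 10, n_trials),
                    "sniff_amplitude": rng.uniform(0.5, 1.5, n_trials),
                    "sniff_auc": rng.uniform(0.5, 1.5, n_trials),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestFitLmeMap:
    def test_null_voxel_rate_near_alpha(self, rng):
        """With no true effect ~5% of cells fall below voxel p=.05."""
        behav = _behav_frame(rng)
        n = len(behav)
        power = rng.gamma(2.0, 1.0, size=(n, 6, 20))
        stat = fit_lme_map(power, behav, "intensity")
        rate = np.mean(stat.voxel_p < 0.05)
        # binomial 99% margin at 120 weakly dependent cells
        assert rate < 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / 120) + 0.02

    def test_zero_variance_predictor_rejected(self, rng):
        behav = _behav_frame(rng)
        behav["intensity"] = 5.0
        power = rng.gamma(2.0, 1.0, size=(len(behav), 2, 3))
        with pytest.raises(ValueError):
            fit_lme_map(power, behav, "intensity")

    def test_shapiro_qc_layer_present(self, rng):
        behav = _behav_frame(rng, n_part=4, n_trials=20)
        power = rng.gamma(2.0, 1.0, size=(len(behav), 2, 4))
        stat = fit_lme_map(power, behav, "intensity", qc_shapiro=True)
        assert stat.qc_shapiro_p.shape == stat.t.shape
        # rank-transformed responses should rarely fail normality badly
        assert np.nanmedian(stat.qc_shapiro_p) > 0.05


def _stat_map(t, df=200):
    t = np.asarray(t, dtype=float)
    return StatMap(
        t=t,
        voxel_p=2 * sstats.t.sf(np.abs(t), df),
        df=df,
        beta=t,
        se=np.ones_like(t),
        flagged=np.zeros_like(t, dtype=bool),
        predictor="intensity",
    )


class TestWcm:
    def test_corrected_p_has_monte_carlo_floor(self, rng):
        obs = _stat_map(np.full((3, 3), 9.0))
        perms = [rng.standard_normal((3, 3)) for _ in range(199)]
        res = wcm_test(obs, perms)
        assert res.clusters
        assert all(c["p_corrected"] >= 1.0 / 200 for c in res.clusters)
        # a block exceeding every null maximum sits exactly at the floor
        assert res.clusters[0]["p_corrected"] == pytest.approx(1.0 / 200)

    def test_exchangeable_maps_are_not_significant(self, rng):
        """Observed map drawn from the permutation distribution itself."""
        maps = [rng.standard_normal((5, 8)) * 1.2 for _ in range(201)]
        ps = []
        for i in range(30):
            obs = _stat_map(maps[i])
            perms = maps[:i] + maps[i + 1 :]
            res = wcm_test(obs, perms)
            ps.append(res.min_p)
        assert np.mean([p <= 0.05 for p in ps if p < 1.0] or [0]) <= 0.2
        assert np.mean(ps) > 0.3

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            wcm_test(_stat_map(np.ones((2, 2))), [])

    def test_cluster_masses_use_weight_exponent(self, rng):
        t = np.zeros((4, 4))
        t[1:3, 1:3] = 3.0
        obs = _stat_map(t)
        perms = [np.zeros((4, 4)) for _ in range(100)]
        res = wcm_test(obs, perms, weight_exponent=2.0)
        assert res.clusters[0]["mass"] == pytest.approx(4 * 9.0)
        res1 = wcm_test(obs, perms, weight_exponent=1.0)
        assert res1.clusters[0]["mass"] == pytest.approx(4 * 3.0)


def test_permutation_preserves_participant_marginals(rng):
    parts = np.repeat(np.array(["a", "b", "c"]), 10)
    vals = rng.standard_normal(30)
    perm = permute_within_participant(vals, parts, rng)
    for p in "abc":
        np.testing.assert_array_equal(
            np.sort(vals[parts == p]), np.sort(perm[parts == p])
        )
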