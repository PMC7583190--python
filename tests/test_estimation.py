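"""Likelihood machinery: objective values, AIC, model selection, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from synpd.estimation import (
    BlockVarianceSpec,
    Param,
    Stage,
    VarianceSpec,
    aic,
    fit_ml,
    neg_log_likelihood,
    select_transit_depth,
    sequential_fit,
)

HALF_LN_2PI = 0.5 * math.log(2 * math.pi)


class TestNegLogLikelihood:
    @pytest.mark.parametrize(
        "pred, obs, vspec, expected",
        [
            # zero residual, unit variance
            ([1.0], [1.0], VarianceSpec("constant", 1.0), HALF_LN_2PI),
            # residual^2/2 = 2 on top of the normalizing constant
            ([2.0], [0.0], VarianceSpec("constant", 1.0),
             HALF_LN_2PI + 2.0),
        ],
    )
    def test_constant_error_values(self, pred, obs, vspec, expected):
        assert neg_log_likelihood(
            np.array(pred), np.array(obs), vspec
        ) == pytest.approx(expected, abs=1e-12)

    def test_affine_proportional_matches_density(self):
        # sd = 0.5 + 0.1*10 = 1.5; compare against the Gaussian density
        vspec = VarianceSpec("affine_proportional", delta=0.5, sigma=0.1)
        got = neg_log_likelihood(
            np.array([10.0]), np.array([11.0]), vspec)
        assert got == pytest.approx(
            -stats.norm.logpdf(11.0, loc=10.0, scale=1.5), rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_sum_of_gaussian_logpdfs(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 8)
        pred = rng.uniform(0.5, 5.0, n)
        obs = pred + rng.normal(0, 1, n)
        vspec = VarianceSpec("affine_proportional",
                             delta=rng.uniform(0.1, 1.0),
                             sigma=rng.uniform(0.0, 0.5))
        expected = -stats.norm.logpdf(obs, loc=pred,
                                      scale=vspec.sd(pred)).sum()
        assert neg_log_likelihood(pred, obs, vspec) == pytest.approx(
            expected, rel=1e-10)

    def test_length_mismatch_fails(self):
        with pytest.raises(ValueError, match="mismatch"):
            neg_log_likelihood(np.ones(3), np.ones(2), VarianceSpec())

    def test_nonpositive_variance_reports_index(self):
        vspec = VarianceSpec("affine_proportional", delta=0.0, sigma=1.0)
        with pytest.raises(ValueError, match="index 1"):
            neg_log_likelihood(np.array([1.0, 0.0]), np.zeros(2), vspec)


class TestAic:
    @pytest.mark.parametrize("loglik, n_free, expected",
                             [(-10, 3, 26), (0, 0, 0), (-5.5, 9, 29)])
    def test_values(self, loglik, n_free, expected):
        assert aic(loglik, n_free) == expected

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(-1e6, 1e6), st.integers(0, 50))
    def test_linear_in_n_free_with_slope_two(self, ll, k):
        assert aic(ll, k + 1) - aic(ll, k) == pytest.approx(2.0)


class TestSelectTransitDepth:
    def test_argmin(self):
        assert select_transit_depth([100, 90, 85, 86, 88, 91]) == 2

    def test_tie_prefers_simpler(self):
        assert select_transit_depth([50, 50]) == 0

    def test_empty_fails(self):
        with pytest.raises(ValueError):
            select_transit_depth([])


def _exp_model(times):
    def model(p):
        return 1.0 * np.exp(p["k"] * times)
    return model


class TestFitMl:
    def test_noise_free_exponential_rate_recovery(self):
        times = np.linspace(0, 120, 10)
        data = np.exp(0.0225 * times)
        fr = fit_ml(_exp_model(times), data,
                    free=[Param("k", 0.01, 1e-5, 1.0, log=True)],
                    vspec=VarianceSpec("constant", 0.1), seed=0,
                    n_starts=2)
        assert fr.converged
        assert fr.estimates["k"] == pytest.approx(0.0225, abs=1e-4)
        assert fr.aic == pytest.approx(-2 * fr.loglik + 2)
        assert len(fr.residuals) == fr.n_obs == 10

    def test_agrees_with_grid_search_oracle(self):
        times = np.linspace(0, 100, 8)
        rng = np.random.default_rng(4)
        data = np.exp(0.03 * times) + rng.normal(0, 0.3, len(times))
        vspec = VarianceSpec("constant", 0.3)
        grid = np.linspace(0.005, 0.08, 1000)
        model = _exp_model(times)
        nlls = [neg_log_likelihood(model({"k": k}), data, vspec)
                for k in grid]
        k_grid = grid[int(np.argmin(nlls))]
        fr = fit_ml(model, data,
                    free=[Param("k", 0.02, 1e-4, 0.5, log=True)],
                    vspec=vspec, seed=0, n_starts=2)
        step = grid[1] - grid[0]
        assert abs(fr.estimates["k"] - k_grid) <= step

    def test_variance_parameters_coestimated(self):
        rng = np.random.default_rng(7)
        times = np.linspace(0, 120, 40)
        clean = np.exp(0.02 * times)
        data = clean + rng.normal(0, 0.5, len(times))
        fr = fit_ml(
            _exp_model(times), data,
            free=[Param("k", 0.02, 1e-4, 0.5, log=True),
                  Param("err_delta", 0.2, 1e-4, 10.0, log=True)],
            vspec=VarianceSpec("constant", 1.0), seed=0, n_starts=2)
        assert fr.estimates["err_delta"] == pytest.approx(0.5, rel=0.4)


class TestSequentialFit:
    def test_single_stage_matches_fit_ml(self):
        times = np.linspace(0, 100, 8)
        data = np.exp(0.025 * times)
        free = [Param("k", 0.02, 1e-4, 0.5, log=True)]
        vspec = VarianceSpec("constant", 0.1)
        direct = fit_ml(_exp_model(times), data, free, vspec=vspec,
                        seed=3, n_starts=1)
        chained, = sequential_fit(
            [Stage("only", _exp_model(times), data, free, vspec)],
            seed=3, n_starts=1)
        assert chained.estimates["k"] == pytest.approx(
            direct.estimates["k"], rel=1e-9)

    def test_two_stage_recovery_freezes_upstream(self):
        # stage 1 estimates a decay rate; stage 2 reuses it for a
        # downstream trajectory driven by the frozen upstream curve
        times = np.linspace(0, 24, 10)
        k1_true, k2_true = 0.4, 0.1
        up = np.exp(-k1_true * times)

        def up_model(p):
            return np.exp(-p["k1"] * times)

        def down_model(p):
            # linear intermediate driven by the (frozen) upstream decay
            k1, k2 = p["k1"], p["k2"]
            return (k2 / (k1 - k2)) * (np.exp(-k2 * times)
                                       - np.exp(-k1 * times))

        down = (k2_true / (k1_true - k2_true)) * (
            np.exp(-k2_true * times) - np.exp(-k1_true * times))
        stages = [
            Stage("up", up_model, up,
                  [Param("k1", 0.2, 1e-3, 5.0, log=True)],
                  VarianceSpec("constant", 0.05)),
            Stage("down", down_model, down,
                  [Param("k2", 0.2, 1e-3, 5.0, log=True)],
                  VarianceSpec("constant", 0.05), requires=("k1",)),
        ]
        r1, r2 = sequential_fit(stages, seed=0, n_starts=2)
        assert r1.estimates["k1"] == pytest.approx(k1_true, rel=1e-3)
        assert r2.fixed["k1"] == r1.estimates["k1"]
        assert r2.estimates["k2"] == pytest.approx(k2_true, rel=1e-3)

    def test_stage_before_dependency_fails(self):
        times = np.linspace(0, 10, 5)
        stage = Stage("down", _exp_model(times), np.ones(5),
                      [Param("k", 0.1, 1e-3, 1.0, log=True)],
                      requires=("k_upstream",))
        with pytest.raises(ValueError, match="k_upstream"):
            sequential_fit([stage])


class TestBlockVariance:
    def test_blocks_use_their_own_error_models(self):
        bv = BlockVarianceSpec(
            specs=(VarianceSpec("constant", 2.0),
                   VarianceSpec("affine_proportional", 1.0, 0.5)),
            lengths=(2, 2))
        v = bv.variance(np.array([1.0, 1.0, 10.0, 20.0]))
        assert v == pytest.approx([4.0, 4.0, 36.0, 121.0])
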