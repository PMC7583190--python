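"""Growth/kill model: Hill signals, transit delay, psi, CF, fitting."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synpd.growth import (
    ExposureDesign,
    GrowthParams,
    additivity_ratio,
    correction_factor,
    doubling_time,
    fit_growth,
    killing_signal,
    simulate_growth,
)

REPORTED = GrowthParams(psi=0.69)  # fitted estimates as ground truth


class TestKillingSignal:
    def test_half_maximal_at_kc50(self):
        assert killing_signal(18.3, 0.0233, 18.3) == pytest.approx(
            0.0233 / 2)

    def test_zero_at_zero_concentration(self):
        assert killing_signal(0.0, 0.0233, 18.3) == 0.0

    def test_synergistic_psi_raises_kill_rate(self):
        # psi = 0.69 shifts the effective KC50 down by 31%
        got = killing_signal(18.3, 0.0233, 18.3, psi=0.69)
        assert got == pytest.approx(0.0233 * 18.3 / (0.69 * 18.3 + 18.3),
                                    rel=1e-12)
        assert got == pytest.approx(0.01379, abs=2e-5)

    def test_negative_concentration_fails(self):
        with pytest.raises(ValueError):
            killing_signal(-1.0, 0.02, 10.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 1e4), st.floats(0.2, 2.0))
    def test_monotone_in_conc_and_psi_saturates_at_kmax(self, C, psi):
        k = killing_signal(C, 0.0233, 18.3, psi)
        assert 0 < k < 0.0233
        assert k <= killing_signal(C * 1.5, 0.0233, 18.3, psi)
        assert k >= killing_signal(C, 0.0233, 18.3, psi * 1.5)


class TestDoublingTime:
    def test_reported_growth_rate_gives_30_8_h(self):
        assert doubling_time(0.0225) == pytest.approx(30.8, abs=0.1)

    def test_ln2_rate_gives_unit_time(self):
        assert doubling_time(math.log(2)) == pytest.approx(1.0)

    def test_same_formula_serves_as_half_life(self):
        assert doubling_time(0.649) == pytest.approx(1.07, abs=0.01)

    def test_nonpositive_rate_fails(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)


class TestCorrectionFactor:
    @pytest.mark.parametrize("nd, np_, expected",
                             [(100, 0, 1.0), (0, 50, 0.5),
                              (50, 50, 100 / 150)])
    def test_values(self, nd, np_, expected):
        assert correction_factor(nd, np_) == pytest.approx(expected)

    def test_both_zero_fails(self):
        with pytest.raises(ValueError):
            correction_factor(0, 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_always_in_half_open_interval(self, nd, np_):
        if nd == 0 and np_ == 0:
            return
        assert 0.5 <= correction_factor(nd, np_) <= 1.0


class TestSimulateGrowth:
    def test_control_is_exponential_with_30_8_h_doubling(self):
        design = ExposureDesign(times=(30.8,))
        n = simulate_growth(REPORTED, design)
        assert n[0] == pytest.approx(2.0, rel=1e-3)

    def test_kill_balancing_growth_holds_density_constant(self):
        # choose C so the undelayed PTX signal equals k_G exactly
        p = GrowthParams(n_transit=0)
        C = p.k_G * p.KC50_P / (p.K_maxP - p.k_G)
        design = ExposureDesign(C_P=C, times=(24.0, 72.0, 120.0))
        n = simulate_growth(p, design)
        assert n == pytest.approx(np.ones(3), rel=1e-9)

    def test_analytic_matches_high_accuracy_integration(self):
        design = ExposureDesign(C_B=250.0, C_P=15.0,
                                times=(6.0, 24.0, 48.0, 96.0, 120.0))
        a = simulate_growth(REPORTED, design, method="analytic")
        o = simulate_growth(REPORTED, design, method="ode", rtol=1e-10)
        assert a == pytest.approx(o, abs=1e-6)

    def test_transit_chain_reaches_undelayed_steady_slope(self):
        # at late times the delayed solution declines at the same
        # log-slope as the undelayed one (chain equilibrated)
        p = replace(REPORTED, n_transit=3)
        design = ExposureDesign(C_P=60.0, times=(400.0, 430.0))
        n3 = simulate_growth(p, design)
        n0 = simulate_growth(replace(p, n_transit=0), design)
        slope3 = math.log(n3[1] / n3[0]) / 30.0
        slope0 = math.log(n0[1] / n0[0]) / 30.0
        assert slope3 == pytest.approx(slope0, rel=1e-6)

    def test_saturating_ptx_eradicates_but_brp_only_retards(self):
        # K_maxP > k_G > K_maxB: long-run log-slope signs differ
        p = REPORTED
        assert p.k_G - p.K_maxP < 0   # eradication possible
        assert p.k_G - p.K_maxB > 0   # only growth retardation
        design = ExposureDesign(C_P=1e6, times=(500.0, 600.0))
        nP = simulate_growth(p, design)
        assert nP[1] < nP[0]
        design = ExposureDesign(C_B=1e6, times=(500.0, 600.0))
        nB = simulate_growth(p, design)
        assert nB[1] > nB[0]

    def test_density_stays_positive(self):
        design = ExposureDesign(C_P=60.0, C_B=1000.0,
                                times=tuple(np.linspace(0, 120, 25)))
        assert (simulate_growth(REPORTED, design) > 0).all()


class TestAdditivityRatio:
    DESIGN = ExposureDesign(C_B=250.0, C_P=15.0,
                            times=(24.0, 48.0, 72.0, 96.0, 120.0))

    def test_additive_truth_gives_unit_ratios(self):
        obs = simulate_growth(replace(REPORTED, psi=1.0), self.DESIGN)
        r = additivity_ratio(obs, REPORTED, self.DESIGN)
        assert r == pytest.approx(np.ones(5), rel=1e-9)

    def test_synergy_pushes_ratios_below_one_by_72h(self):
        obs = simulate_growth(replace(REPORTED, psi=0.69), self.DESIGN)
        r = additivity_ratio(obs, REPORTED, self.DESIGN)
        late = np.asarray(self.DESIGN.times) >= 72.0
        assert (r[late] < 1.0).all()

    def test_antagonism_pushes_ratios_above_one(self):
        obs = simulate_growth(replace(REPORTED, psi=1.5), self.DESIGN)
        r = additivity_ratio(obs, REPORTED, self.DESIGN)
        assert (r[np.asarray(self.DESIGN.times) >= 72.0] > 1.0).all()


class TestFitGrowth:
    def test_noise_free_single_agent_recovery(self, growth_table_clean):
        data = growth_table_clean
        single = data[~((data.conc_PTX_nM > 0) & (data.conc_BRP_nM > 0))]
        fit = fit_growth(single, n_transit=3, seed=0, n_starts=1)
        assert fit.params.K_maxP == pytest.approx(0.0233, rel=0.01)
        assert fit.params.KC50_P == pytest.approx(18.3, rel=0.01)
        assert fit.params.k_G == pytest.approx(0.0225, rel=0.01)

    def test_noise_free_psi_recovery(self, growth_table_clean):
        fit = fit_growth(growth_table_clean, n_transit=3, seed=0,
                         n_starts=1)
        assert fit.psi == pytest.approx(0.69, abs=1e-3)

    def test_control_only_flags_kill_parameters(self, growth_table_clean):
        data = growth_table_clean
        ctrl = data[(data.conc_PTX_nM == 0) & (data.conc_BRP_nM == 0)]
        fit = fit_growth(ctrl, n_transit=3, seed=0, n_starts=1)
        assert fit.params.k_G == pytest.approx(0.0225, rel=0.01)
        assert "K_maxP" in fit.unidentifiable
        assert "K_maxB" in fit.unidentifiable

    def test_missing_control_arm_fails(self, growth_table_clean):
        data = growth_table_clean
        no_ctrl = data[(data.conc_PTX_nM > 0) | (data.conc_BRP_nM > 0)]
        with pytest.raises(ValueError, match="control"):
            fit_growth(no_ctrl, n_transit=3)

    def test_bootstrap_ci_brackets_psi(self, growth_table_clean):
        from synpd.growth import bootstrap_psi_ci

        fit = fit_growth(growth_table_clean, n_transit=3, seed=0,
                         n_starts=1)
        lo, hi = bootstrap_psi_ci(fit, growth_table_clean, n_boot=12,
                                  seed=0)
        assert lo <= fit.psi <= hi
        assert hi < 1.0
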