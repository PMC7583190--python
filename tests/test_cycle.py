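"""Cell-cycle/apoptosis compartments, extrapolation, plate context."""

import math
from dataclasses import replace

import numpy as np
import pytest

from synpd.cycle import (
    CycleParams,
    arrested_apoptosis_rate,
    cycle_rhs,
    density_inhibition,
    doubling_time_cycle,
    initial_phase_fractions,
    mitotic_arrest_rate,
    mm_extrapolate,
    plate_context,
    simulate_cycle,
)
from synpd.network import ARM_BP, ARM_P, NetworkParams, Treatment

P = CycleParams()


class TestDensityInhibition:
    def test_at_seeding_equals_log_capacity_fold(self):
        assert density_inhibition(P.live0, P.N_max, P.live0) == \
            pytest.approx(math.log(7.43), rel=1e-12)

    def test_zero_at_capacity(self):
        assert density_inhibition(P.N_max * P.live0, P.N_max,
                                  P.live0) == pytest.approx(0.0, abs=1e-12)

    def test_one_log_unit_below_capacity(self):
        live = P.N_max * P.live0 / math.e
        assert density_inhibition(live, P.N_max, P.live0) == \
            pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_live_fails(self):
        with pytest.raises(ValueError):
            density_inhibition(0.0, P.N_max, P.live0)


class TestMitoticArrestRate:
    def test_zero_at_baseline_elys(self):
        assert mitotic_arrest_rate(1.0, 2.39e-2, 3.0) == 0.0

    def test_cubic_above_baseline(self):
        assert mitotic_arrest_rate(1.5, 2.39e-2, 3.0) == pytest.approx(
            2.39e-2 * 3.375, rel=1e-12)

    def test_zero_below_baseline(self):
        assert mitotic_arrest_rate(0.8, 2.39e-2, 3.0) == 0.0


class TestArrestedApoptosisRate:
    def test_baseline_inputs_give_k_apm0(self):
        assert arrested_apoptosis_rate(1, 1, 1, 1, 0.111) == \
            pytest.approx(0.111)

    def test_reciprocal_in_bcl2(self):
        assert arrested_apoptosis_rate(1, 1, 1, 0.5, 0.111) == \
            pytest.approx(0.222)

    def test_ciap_loss_derepresses(self):
        got = arrested_apoptosis_rate(1, 0.033, 1, 1, 0.111)
        assert got == pytest.approx(0.111 * 0.033 ** -0.0772, rel=1e-6)
        assert got == pytest.approx(0.1444, abs=5e-4)

    def test_nonpositive_input_fails(self):
        with pytest.raises(ValueError):
            arrested_apoptosis_rate(1, 0.0, 1, 1, 0.111)


class TestDoublingTimeCycle:
    def test_at_seeding_density(self):
        assert doubling_time_cycle(P.live0, P) == pytest.approx(25.1,
                                                                abs=0.1)

    def test_one_log_unit_below_capacity(self):
        live = P.N_max * P.live0 / math.e
        expected = 1 / 0.0448 + 1 / 0.129 + 1 / (2 * 0.0807)
        assert doubling_time_cycle(live, P) == pytest.approx(expected,
                                                             rel=1e-6)
        assert expected == pytest.approx(36.3, abs=0.1)

    def test_floor_from_s_and_m_transit(self):
        floor = 1 / 0.129 + 1 / (2 * 0.0807)
        assert floor == pytest.approx(13.95, abs=0.01)
        assert doubling_time_cycle(P.live0, P) > floor

    def test_at_capacity_fails(self):
        with pytest.raises(ValueError):
            doubling_time_cycle(P.N_max * P.live0, P)


class TestCycleRhs:
    def _state(self, g1=8e4, s=5e4, m=6e4, ma=1e4, pl=5e3, apo=2e3):
        return np.array([g1, s, m, ma, pl, apo] + [1.0] * P.n_delay_ASPP2)

    def test_bookkeeping_identity(self):
        # total cell change = division gain - apoptotic clearance
        state = self._state()
        d = cycle_rhs(state, P, None)
        total = d[:6].sum()
        assert total == pytest.approx(
            P.k31 * state[2] - P.k_ap * state[5], rel=1e-12)

    def test_bookkeeping_identity_with_drug_proteins(self):
        state = self._state()
        proteins = {"cIAP1": 0.033, "BAX": 1.2, "Bcl2": 0.4,
                    "ELYS": 1.18, "ASPP2": 1.18}
        d = cycle_rhs(state, P, proteins)
        assert d[:6].sum() == pytest.approx(
            P.k31 * state[2] - P.k_ap * state[5], rel=1e-12)

    def test_polyploid_pool_is_absorbing(self):
        d = cycle_rhs(self._state(), P, None)
        assert d[4] >= 0.0

    def test_nonpositive_protein_fails(self):
        with pytest.raises(ValueError):
            cycle_rhs(self._state(), P,
                      {"cIAP1": 0.0, "BAX": 1, "Bcl2": 1, "ELYS": 1,
                       "ASPP2": 1})


class TestSimulateCycle:
    def test_control_saturates_near_capacity(self):
        # the plateau sits a few percent below N_max*live0: spontaneous
        # apoptosis balances division while the Gompertz factor is
        # still slightly positive
        sim = simulate_cycle(P, times=(0.0, 600.0, 1200.0))
        cap = P.N_max * P.live0
        assert sim.loc[1200.0, "live_cells"] == pytest.approx(
            sim.loc[600.0, "live_cells"], rel=1e-4)  # true plateau
        assert sim.loc[1200.0, "live_cells"] == pytest.approx(cap,
                                                              rel=0.06)

    def test_control_apoptotic_fraction_after_72h(self):
        sim = simulate_cycle(P, times=(72.0,))
        assert sim.loc[72.0, "pct_apoptotic"] == pytest.approx(8.0,
                                                               abs=2.0)

    def test_drug_machinery_inert_at_baseline_proteins(self):
        # a "treated" arm whose drug effects are all zeroed must equal
        # the control simulation exactly
        net = NetworkParams(sti_irak4=0.0, inh_ciap_b=0.0,
                            sti_elys_p=0.0, inh_pjnk_deg_bp=0.0)
        times = (0.0, 17.0, 48.0, 72.0)
        treated = simulate_cycle(P, net, ARM_BP, times)
        control = simulate_cycle(P, None, Treatment(), times)
        cols = ["pct_G0G1", "pct_S", "pct_4N", "pct_polyploid",
                "pct_apoptotic", "total_cells"]
        assert np.allclose(treated[cols], control[cols], rtol=1e-6)

    def test_ptx_4n_peak_then_polyploid_accumulation(self):
        times = np.arange(0.0, 73.0, 1.0)
        sim = simulate_cycle(P, None, ARM_P, times)
        peak_t = float(sim["pct_4N"].idxmax())
        assert 5.0 <= peak_t <= 30.0  # transient arrest near 17 h
        pl = sim["pct_polyploid"]
        assert (np.diff(pl.to_numpy()) >= -1e-9).all()
        assert pl.iloc[-1] > pl.iloc[10]

    def test_compartments_stay_nonnegative(self):
        sim = simulate_cycle(P, None, ARM_BP,
                             times=np.linspace(0, 120, 41))
        assert (sim[["G1", "S", "M", "MA", "PL", "Apo"]].to_numpy()
                >= -1e-6).all()

    def test_initial_fractions_high_g2m(self):
        fr = initial_phase_fractions(P)
        assert fr.sum() == pytest.approx(1.0)
        assert 0.25 <= fr[2] <= 0.40  # partially synchronized culture


class TestMmExtrapolate:
    def test_ic50_back_calculation(self):
        ic50 = 100.0 * (1 - 0.967) / 0.967
        assert ic50 == pytest.approx(3.41, abs=0.01)
        # half-maximal at the back-calculated IC50 by construction
        assert mm_extrapolate(0.967, 100.0, ic50) == pytest.approx(0.5)

    def test_zero_concentration_gives_zero_effect(self):
        assert mm_extrapolate(0.967, 100.0, 0.0) == 0.0
        assert mm_extrapolate(2.22, 10.0, 0.0, "stimulation") == 0.0

    def test_reference_concentration_recovers_reference_effect(self):
        got = mm_extrapolate(0.967, 100.0, 100.0)
        assert got == pytest.approx(0.967, rel=1e-12)

    def test_inhibition_needs_fractional_effect(self):
        with pytest.raises(ValueError):
            mm_extrapolate(1.2, 100.0, 10.0)


class TestPlateContext:
    def test_well96_adjustments(self):
        q = plate_context(P, "well96")
        assert q.N_max == 30.0
        assert q.k_ma0 == pytest.approx(1.673e-2, abs=1e-5)

    def test_well6_is_identity(self):
        assert plate_context(P, "well6") is P

    def test_idempotent(self):
        q1 = plate_context(P, "well96")
        q2 = plate_context(q1, "well96")
        assert q2.k_ma0 == q1.k_ma0
        assert q2.N_max == q1.N_max

    def test_unknown_context_fails(self):
        with pytest.raises(ValueError):
            plate_context(P, "well384")
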