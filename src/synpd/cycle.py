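"""Cell-cycle / apoptosis compartment model linked to the protein network.

Live cells progress G0/G1 -> S -> G2/M and divide (a cell leaving M
re-enters G0/G1 as two cells).  Contact inhibition slows the G0/G1 -> S
transition through a Gompertz factor I0 = ln(N_max*live0) - ln(live).
Cycling cells undergo spontaneous apoptosis at k_ap, modulated by cIAP1
(k_ap * cIAP^gamma, gamma < 0: losing cIAP1 de-represses apoptosis).
Under paclitaxel, accumulating ELYS drives G2/M cells into mitotic arrest
(MA) at k_ma = k_ma0 * ELYS^gamma_ELYS gated on ELYS > 1.  Arrested cells
either die at k_apm = k_apm0 * ASPP2_delayed * cIAP^g1 * BAX^g2 / Bcl2,
or slip into an apoptosis-resistant polyploid pool (PL) at k_pl.  The
apoptotic pool clears at the unmodified k_ap.

The ASPP2 pro-apoptotic signal acts through a transit chain (distributed
delay); the chain is initialized at the baseline value 1.

A Michaelis-Menten conversion extrapolates the fitted drug-effect
magnitudes (estimated at 100 nM BRP / 10 nM PTX) to other concentrations,
and a plate-context adjustment (N_max = 30, k_ma0 * 0.7) transfers the
6-well-calibrated model to 96-well growth assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .estimation import (
    BlockVarianceSpec,
    FitResult,
    Param,
    VarianceSpec,
    fit_ml,
)
from .network import (
    ARMS,
    PROTEINS,
    NetworkParams,
    Treatment,
    network_rhs,
)

__all__ = [
    "CycleParams",
    "density_inhibition",
    "mitotic_arrest_rate",
    "arrested_apoptosis_rate",
    "cycle_rhs",
    "doubling_time_cycle",
    "simulate_cycle",
    "mm_extrapolate",
    "extrapolated_network",
    "plate_context",
    "initial_phase_fractions",
    "fit_cycle",
]

# fitted reference exposure for the drug-effect magnitudes
C_B_REF = 100.0  # nM birinapant
C_P_REF = 10.0   # nM paclitaxel
# the cIAP1 reference inhibition (0.967) anchors the saturation fraction
# assumed when converting stimulation magnitudes to MM form
_SAT = 0.967


@dataclass(frozen=True)
class CycleParams:
    """Transition rates (1/h), capacity and protein-linkage coefficients."""

    k12: float = 4.48e-2
    k23: float = 0.129
    k31: float = 8.07e-2
    k_ap: float = 2.18e-3
    k_pl: float = 1.97e-2
    k_ma0: float = 2.39e-2
    k_apm0: float = 0.111
    N_max: float = 7.43
    live0: float = 2.0e5
    gamma_cIAP_ap: float = -0.532
    gamma_cIAP_apm: float = -7.72e-2
    gamma_BAX: float = 0.208
    gamma_ELYS: float = 3.0
    n_delay_ASPP2: int = 3
    tau_ASPP2: float = 24.0
    apo0_frac: float = 0.0     # apoptotic fraction at T0
    context: str = "well6"

    def __post_init__(self) -> None:
        for name in ("k12", "k23", "k31", "k_ap", "k_pl", "k_ma0",
                     "k_apm0", "live0", "tau_ASPP2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.N_max <= 1:
            raise ValueError("N_max must exceed 1")
        if self.gamma_ELYS <= 0:
            raise ValueError("gamma_ELYS must be positive")
        if self.gamma_cIAP_ap >= 0 or self.gamma_cIAP_apm >= 0:
            raise ValueError("cIAP1 coefficients must be negative "
                             "(cIAP1 inhibits apoptosis)")
        if self.n_delay_ASPP2 < 1:
            raise ValueError("n_delay_ASPP2 must be >= 1")
        if not (0.0 <= self.apo0_frac < 0.1):
            raise ValueError("apo0_frac must be in [0, 0.1)")


def density_inhibition(live: float, N_max: float, live0: float) -> float:
    """Gompertz factor I0 = ln(N_max*live0) - ln(live); 0 at capacity."""
    if live <= 0:
        raise ValueError("live count must be positive")
    return math.log(N_max * live0) - math.log(live)


def mitotic_arrest_rate(ELYS: float, k_ma0: float,
                        gamma_ELYS: float) -> float:
    """k_ma = k_ma0 * ELYS^gamma gated on ELYS above baseline, else 0."""
    if ELYS <= 0:
        raise ValueError("ELYS fold-change must be positive")
    if ELYS <= 1.0:
        return 0.0
    return k_ma0 * ELYS**gamma_ELYS


def arrested_apoptosis_rate(ASPP2_delayed: float, cIAP: float, BAX: float,
                            Bcl2: float, k_apm0: float,
                            gamma_cIAP: float = -7.72e-2,
                            gamma_BAX: float = 0.208) -> float:
    """k_apm = k_apm0 * ASPP2_delayed * cIAP^g * BAX^g' / Bcl2."""
    if min(ASPP2_delayed, cIAP, BAX, Bcl2) <= 0:
        raise ValueError("protein inputs must be positive")
    return (k_apm0 * ASPP2_delayed * cIAP**gamma_cIAP
            * BAX**gamma_BAX / Bcl2)


def doubling_time_cycle(live: float, params: CycleParams) -> float:
    """Doubling-time approximation 1/(k12*I0) + 1/k23 + 1/(2*k31)."""
    I0 = density_inhibition(live, params.N_max, params.live0)
    if I0 <= 0:
        raise ValueError("live count at or above capacity")
    return 1.0 / (params.k12 * I0) + 1.0 / params.k23 \
        + 1.0 / (2.0 * params.k31)


def initial_phase_fractions(params: CycleParams) -> np.ndarray:
    """Default T0 phase distribution (G0/G1, S, G2/M fractions).

    The dominant eigenvector of the cycling subsystem at seeding density:
    the phase mix a culture settles into during unperturbed growth.  It
    carries the relatively high G2/M fraction (~30%) seen in cycling
    PANC-1 cultures.
    """
    a = params.k12 * density_inhibition(params.live0, params.N_max,
                                        params.live0)
    kap = params.k_ap
    A = np.array([
        [-a - kap, 0.0, 2.0 * params.k31],
        [a, -params.k23 - kap, 0.0],
        [0.0, params.k23, -params.k31 - kap],
    ])
    w, v = np.linalg.eig(A)
    lead = np.argmax(w.real)
    vec = np.abs(v[:, lead].real)
    return vec / vec.sum()


def _initial_state(params: CycleParams,
                   fractions: Sequence[float] | None = None) -> np.ndarray:
    fr = (np.asarray(fractions, float) if fractions is not None
          else initial_phase_fractions(params))
    if fr.shape != (3,) or abs(fr.sum() - 1.0) > 1e-8 or np.any(fr < 0):
        raise ValueError("phase fractions must be a non-negative "
                         "3-vector summing to 1")
    live = params.live0
    apo = params.apo0_frac / (1.0 - params.apo0_frac) * live
    state = np.concatenate([
        fr * live, [0.0, 0.0, apo],
        np.ones(params.n_delay_ASPP2),
    ])
    return state


def cycle_rhs(state: np.ndarray, params: CycleParams,
              proteins: Mapping[str, float] | None = None) -> np.ndarray:
    """Derivatives of [G1, S, M, MA, PL, Apo, D1..Dn].

    ``proteins`` maps protein name -> current fold-change; omitted means
    baseline (all 1), under which the drug machinery is inert and the
    model reduces exactly to unperturbed growth.
    """
    state = np.asarray(state, dtype=float)
    n = params.n_delay_ASPP2
    G1, S, M, MA, PL, Apo = state[:6]
    delay = state[6:6 + n]
    if proteins is None:
        cIAP = BAX = Bcl2 = ELYS = ASPP2 = 1.0
    else:
        cIAP = proteins["cIAP1"]
        BAX = proteins["BAX"]
        Bcl2 = proteins["Bcl2"]
        ELYS = proteins["ELYS"]
        ASPP2 = proteins["ASPP2"]
    if min(cIAP, BAX, Bcl2, ELYS, ASPP2) <= 0:
        raise ValueError("protein inputs must be positive")

    live = G1 + S + M + MA + PL
    I0 = density_inhibition(max(live, 1e-12), params.N_max, params.live0)
    I0 = max(I0, 0.0)
    k_ap_eff = params.k_ap * cIAP**params.gamma_cIAP_ap
    k_ma = mitotic_arrest_rate(ELYS, params.k_ma0, params.gamma_ELYS)
    k_apm = arrested_apoptosis_rate(
        delay[-1], cIAP, BAX, Bcl2, params.k_apm0,
        params.gamma_cIAP_apm, params.gamma_BAX)

    d = np.empty_like(state)
    d[0] = 2.0 * params.k31 * M - params.k12 * I0 * G1 - k_ap_eff * G1
    d[1] = params.k12 * I0 * G1 - params.k23 * S - k_ap_eff * S
    d[2] = params.k23 * S - params.k31 * M - k_ma * M - k_ap_eff * M
    d[3] = k_ma * M - (k_apm + params.k_pl) * MA
    d[4] = params.k_pl * MA
    d[5] = k_ap_eff * (G1 + S + M) + k_apm * MA - params.k_ap * Apo
    rate = n / params.tau_ASPP2
    prev = ASPP2
    for j in range(n):
        d[6 + j] = (prev - delay[j]) * rate
        prev = delay[j]
    return d


# ---------------------------------------------------------------------------
# concentration extrapolation and plate context


def mm_extrapolate(E_ref: float, C_ref: float, C: float,
                   mode: str = "inhibition_unit_max") -> float:
    """Extrapolate a fitted effect magnitude to another concentration.

    ``inhibition_unit_max``: the reference fractional inhibition E_ref at
    C_ref implies IC50 = C_ref*(1-E_ref)/E_ref, and the effect at C is
    C/(C+IC50) (saturating at 1).

    ``stimulation``: the magnitude keeps its fitted ceiling (E_max =
    E_ref) and the reference exposure is treated as 96.7%-saturating --
    the saturation fraction of the one case the data pin down (cIAP1
    inhibition) -- giving EC50 = C_ref*(1-0.967)/0.967.
    """
    if C_ref <= 0:
        raise ValueError("C_ref must be positive")
    if C < 0:
        raise ValueError("C must be non-negative")
    if mode == "inhibition_unit_max":
        if not (0.0 < E_ref < 1.0):
            raise ValueError("inhibition E_ref must be in (0, 1)")
        ic50 = C_ref * (1.0 - E_ref) / E_ref
        return C / (C + ic50)
    if mode == "stimulation":
        ec50 = C_ref * (1.0 - _SAT) / _SAT
        return E_ref * C / (C + ec50)
    raise ValueError(f"unknown mode {mode!r}")


def extrapolated_network(network: NetworkParams,
                         treatment: Treatment) -> NetworkParams:
    """Network parameters with drug effects scaled to the treatment's
    concentrations.

    IRAK4 stimulation is concentration-independent (its profile was the
    same across arms).  The pJNK degradation block, active only under the
    combination, scales as the product of the two drugs' occupancies.
    """
    inh_b = network.inh_ciap_b
    sti_p = network.sti_elys_p
    inh_jnk = network.inh_pjnk_deg_bp
    if treatment.has_B and treatment.C_B > 0:
        inh_b = mm_extrapolate(network.inh_ciap_b, C_B_REF,
                               treatment.C_B, "inhibition_unit_max")
    if treatment.has_P and treatment.C_P > 0:
        sti_p = mm_extrapolate(network.sti_elys_p, C_P_REF,
                               treatment.C_P, "stimulation")
    if treatment.combination and treatment.C_B > 0 and treatment.C_P > 0:
        occ_b = mm_extrapolate(_SAT, C_B_REF, treatment.C_B,
                               "inhibition_unit_max")
        occ_p = mm_extrapolate(_SAT, C_P_REF, treatment.C_P,
                               "inhibition_unit_max")
        inh_jnk = network.inh_pjnk_deg_bp * occ_b * occ_p
    return replace(network, inh_ciap_b=inh_b, sti_elys_p=sti_p,
                   inh_pjnk_deg_bp=inh_jnk)


_WELL96_NMAX = 30.0
_WELL96_KMA0_SCALE = 0.7


def plate_context(params: CycleParams, context: str) -> CycleParams:
    """Adjust capacity and arrest rate for the assay plate format.

    96-well growth assays seed far below confluency, so N_max is set to
    30 and k_ma0 reduced by 0.3-fold; 6-well (the calibration format) is
    the identity.  Absolute values are set, so the conversion is
    idempotent.
    """
    if context == "well6":
        return params
    if context == "well96":
        if params.context == "well96":
            return params
        return replace(params, N_max=_WELL96_NMAX,
                       k_ma0=params.k_ma0 * _WELL96_KMA0_SCALE,
                       context="well96")
    raise ValueError(f"unknown plate context {context!r}")


# ---------------------------------------------------------------------------
# simulation


OBSERVABLES = ("pct_G0G1", "pct_S", "pct_4N", "pct_polyploid",
               "pct_apoptotic", "total_cells")


def simulate_cycle(params: CycleParams,
                   network: NetworkParams | None = None,
                   treatment: Treatment = Treatment(),
                   times: Sequence[float] = (0.0, 17.0, 48.0, 72.0),
                   fractions: Sequence[float] | None = None,
                   extrapolate: bool = False,
                   rtol: float = 1e-8, atol: float = 1e-6,
                   ) -> pd.DataFrame:
    """Co-integrate the protein network and cell-cycle compartments.

    Returns a time-indexed table of the flow-cytometry observables:
    %G0/G1, %S, %4N (= G2/M + mitotically arrested, both carry 4N DNA),
    %polyploid and %apoptotic (of live+apoptotic), plus live and total
    cell counts.  ``extrapolate=True`` rescales the drug-effect
    magnitudes to the treatment's concentrations via the MM conversion;
    otherwise the fitted reference magnitudes apply whenever a drug is
    present.
    """
    network = network or NetworkParams()
    if extrapolate:
        network = extrapolated_network(network, treatment)
    times = np.asarray(times, dtype=float)
    t_eval = np.sort(np.unique(times))
    n_prot = len(PROTEINS)
    idx = {p: i for i, p in enumerate(PROTEINS)}
    y0 = np.concatenate([np.ones(n_prot), _initial_state(params, fractions)])
    active = treatment.any_drug

    def rhs(_t, y):
        prot = np.maximum(y[:n_prot], 1e-12)
        if active:
            dprot = network_rhs(prot, network, treatment)
        else:
            dprot = np.zeros(n_prot)
        pmap = {p: prot[idx[p]] for p in
                ("cIAP1", "BAX", "Bcl2", "ELYS", "ASPP2")}
        dcycle = cycle_rhs(np.maximum(y[n_prot:], 0.0), params,
                           pmap if active else None)
        return np.concatenate([dprot, dcycle])

    sol = solve_ivp(rhs, (0.0, float(max(t_eval.max(), 1e-9))), y0,
                    t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"cycle integration failed: {sol.message}")
    G1, S, M, MA, PL, Apo = sol.y[n_prot:n_prot + 6]
    live = G1 + S + M + MA + PL
    out = pd.DataFrame({
        "pct_G0G1": 100.0 * G1 / live,
        "pct_S": 100.0 * S / live,
        "pct_4N": 100.0 * (M + MA) / live,
        "pct_polyploid": 100.0 * PL / live,
        "pct_apoptotic": 100.0 * Apo / (live + Apo),
        "live_cells": live,
        "total_cells": live + Apo,
        "G1": G1, "S": S, "M": M, "MA": MA, "PL": PL, "Apo": Apo,
    }, index=t_eval)
    out.index.name = "time_h"
    for p in PROTEINS:
        out[p] = sol.y[idx[p]]
    out["ASPP2_delayed"] = sol.y[n_prot + 6 + params.n_delay_ASPP2 - 1]
    return out


def apoptosis_rate_trajectory(params: CycleParams,
                              network: NetworkParams | None,
                              treatment: Treatment,
                              times: Sequence[float]) -> pd.Series:
    """k_apm(t): the arrested-cell apoptosis rate along a simulation."""
    sim = simulate_cycle(params, network, treatment, times)
    vals = [
        arrested_apoptosis_rate(
            row["ASPP2_delayed"], row["cIAP1"], row["BAX"], row["Bcl2"],
            params.k_apm0, params.gamma_cIAP_apm, params.gamma_BAX)
        for _, row in sim.iterrows()
    ]
    return pd.Series(vals, index=sim.index, name="k_apm")


# ---------------------------------------------------------------------------
# fitting

_PCT_COLS = ("pct_G0G1", "pct_S", "pct_4N", "pct_polyploid",
             "pct_apoptotic")


def _cycle_predictions(params: CycleParams, network: NetworkParams | None,
                       rows: pd.DataFrame,
                       fractions: Sequence[float]) -> np.ndarray:
    """Stacked predictions: all percentage rows then all count rows."""
    pct_preds = []
    cnt_preds = []
    for arm_name, sub in rows.groupby("arm", sort=False):
        treatment = ARMS[arm_name]
        times = np.sort(sub.time_h.unique())
        sim = simulate_cycle(params, network, treatment, times,
                             fractions=fractions)
        for _, r in sub.iterrows():
            srow = sim.loc[r.time_h]
            pct_preds.extend(srow[c] for c in _PCT_COLS)
            cnt_preds.append(srow["total_cells"])
    return np.asarray(pct_preds + cnt_preds)


def _flatten_observations(rows: pd.DataFrame) -> tuple[np.ndarray, int]:
    pct = []
    cnt = []
    for _, sub in rows.groupby("arm", sort=False):
        for _, r in sub.iterrows():
            pct.extend(r[c] for c in _PCT_COLS)
            cnt.append(r["total_cells"])
    return np.asarray(pct + cnt), len(pct)


def _fractions_from(p: Mapping[str, float],
                    default: np.ndarray) -> np.ndarray:
    if "frac_G1" in p and "frac_S" in p:
        g1, s = p["frac_G1"], p["frac_S"]
        if g1 + s >= 1.0:
            raise ValueError("phase fractions exceed 1")
        return np.array([g1, s, 1.0 - g1 - s])
    return default


def fit_cycle(control_data: pd.DataFrame,
              drug_data: pd.DataFrame | None = None,
              network: NetworkParams | None = None,
              seed: int = 0, n_starts: int = 2,
              pct_delta: float = 2.0,
              count_delta: float = 5e3, count_sigma: float = 0.05,
              stage2_free: Sequence[str] = (
                  "k_ma0", "k_apm0", "k_pl", "gamma_cIAP_ap"),
              ) -> list[FitResult]:
    """Two-stage fit: control kinetics first, then drug-linked couplings.

    Stage 1 estimates the cycle transition rates, capacity, spontaneous
    apoptosis and the T0 phase distribution from the vehicle arm.  Stage
    2 freezes those and the supplied protein-network parameters, fitting
    the drug-linked rate constants and power coefficients to the drug
    arms.  Percentages carry constant error; counts the
    affine-proportional model.

    Data columns: arm, time_h, replicate, pct_G0G1, pct_S, pct_4N,
    pct_polyploid, pct_apoptotic, total_cells.
    """
    network = network or NetworkParams()
    base = CycleParams()
    default_fr = initial_phase_fractions(base)
    pct_spec = VarianceSpec("constant", delta=pct_delta)
    cnt_spec = VarianceSpec("affine_proportional", delta=count_delta,
                            sigma=count_sigma)

    def make_model(rows: pd.DataFrame, names: Sequence[str]):
        def model_fn(p: Mapping[str, float]) -> np.ndarray:
            kw = {k: v for k, v in p.items()
                  if k not in ("frac_G1", "frac_S")}
            params = replace(base, **kw)
            fr = _fractions_from(p, default_fr)
            return _cycle_predictions(params, network, rows, fr)
        return model_fn

    results: list[FitResult] = []

    # --- stage 1: vehicle control ------------------------------------
    ctrl = control_data[control_data.arm == "control"]
    if ctrl.empty:
        raise ValueError("control arm required")
    ctrl = ctrl.sort_values(["time_h", "replicate"]).reset_index(drop=True)
    obs1, n_pct1 = _flatten_observations(ctrl)
    vspec1 = BlockVarianceSpec(specs=(pct_spec, cnt_spec),
                               lengths=(n_pct1, len(obs1) - n_pct1))
    free1 = [
        Param("k12", 0.05, 1e-4, 1.0, log=True),
        Param("k23", 0.1, 1e-4, 2.0, log=True),
        Param("k31", 0.08, 1e-4, 2.0, log=True),
        Param("k_ap", 2e-3, 1e-6, 0.1, log=True),
        Param("N_max", 8.0, 1.5, 100.0, log=True),
        Param("frac_G1", float(default_fr[0]), 0.05, 0.9),
        Param("frac_S", float(default_fr[1]), 0.05, 0.9),
    ]
    fr1 = fit_ml(make_model(ctrl, [p.name for p in free1]), obs1,
                 free=free1, vspec=vspec1, seed=seed, n_starts=n_starts,
                 name="cycle:control")
    results.append(fr1)
    stage1 = {k: v for k, v in fr1.estimates.items()
              if k not in ("frac_G1", "frac_S")}
    fitted_fr = _fractions_from(fr1.estimates, default_fr)
    base = replace(base, **stage1)

    # --- stage 2: drug arms ------------------------------------------
    if drug_data is not None and not drug_data.empty:
        drugs = drug_data[drug_data.arm != "control"]
        drugs = drugs.sort_values(["arm", "time_h", "replicate"]
                                  ).reset_index(drop=True)
        obs2, n_pct2 = _flatten_observations(drugs)
        vspec2 = BlockVarianceSpec(specs=(pct_spec, cnt_spec),
                                   lengths=(n_pct2, len(obs2) - n_pct2))
        starts = {"k_ma0": 0.03, "k_apm0": 0.1, "k_pl": 0.02,
                  "gamma_cIAP_ap": -0.5, "gamma_cIAP_apm": -0.1,
                  "gamma_BAX": 0.2, "tau_ASPP2": 24.0}
        free2 = []
        for name in stage2_free:
            s = starts[name]
            if name.startswith("gamma_cIAP"):
                free2.append(Param(name, s, -20.0, -1e-6))
            elif name.startswith("gamma"):
                free2.append(Param(name, s, -20.0, 20.0))
            else:
                free2.append(Param(name, s, 1e-5, 10.0, log=True))

        def model2(p: Mapping[str, float]) -> np.ndarray:
            params = replace(base, **dict(p))
            return _cycle_predictions(params, network, drugs, fitted_fr)

        fr2 = fit_ml(model2, obs2, free=free2, vspec=vspec2,
                     seed=seed + 1, n_starts=n_starts,
                     name="cycle:drug-arms")
        results.append(fr2)
    return results
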