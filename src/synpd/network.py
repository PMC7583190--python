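"""Indirect-response ODE network for the 10 modeled signaling proteins.

Each protein's fold-change P_i (1 = untreated baseline) follows a turnover
model whose synthesis rate is modulated by drug effects and by other
proteins through multiplicative power laws:

    dP_i/dt = k_deg_i * (1 + Sti_i) * (1 - Inh_i) * prod_j P_j^gamma_ij
              - k_deg_i * (1 - InhDeg_i) * P_i

Because the baseline is 1, k_syn = k_deg and every protein sits exactly at
1 with no treatment.  Drug inputs: birinapant (B) suppresses cIAP1
synthesis (Inh_B = 0.967); paclitaxel (P) stimulates ELYS synthesis
(Sti_P = 2.22); any treatment stimulates IRAK4 (Sti_X = 0.960); the B+P
combination fully blocks pJNK degradation (the only degradation-side
effect).  Regulatory edges and their power coefficients follow the fitted
interaction map: cIAP1 -| pNF-kB -> {BAX, Bcl2}; IRAK4 -> pSTAT3 -> Bcl2;
pJNK -> VDAC1 -| Bcl2 and pJNK -| pSTAT3; ELYS -> ASPP2; BAX and ELYS
carry negative self-feedback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .estimation import (
    FitResult,
    Param,
    Stage,
    VarianceSpec,
    sequential_fit,
)

__all__ = [
    "PROTEINS",
    "NetworkParams",
    "Treatment",
    "network_rhs",
    "simulate_network",
    "half_life",
    "fit_network",
]

PROTEINS = (
    "cIAP1", "pNFkB", "BAX", "Bcl2", "IRAK4",
    "pJNK", "pSTAT3", "VDAC1", "ELYS", "ASPP2",
)

_DEFAULT_KDEG = {
    "cIAP1": 0.649, "pNFkB": 0.649, "Bcl2": 0.649,
    "IRAK4": 0.127, "pJNK": 8.26e-3, "pSTAT3": 3.16e-2,
    "VDAC1": 0.696, "ELYS": 2.80e-2, "ASPP2": 0.861,
    "BAX": 2.91e-2,
}

# (target, regulator) -> power coefficient on the target's synthesis
_DEFAULT_GAMMA = {
    ("pNFkB", "cIAP1"): -0.298,
    ("BAX", "pNFkB"): 1.85,
    ("Bcl2", "pNFkB"): 0.768,
    ("pSTAT3", "IRAK4"): 1.0,
    ("VDAC1", "pJNK"): 1.0,
    ("ASPP2", "ELYS"): 1.0,
    ("Bcl2", "pSTAT3"): 1.33,
    ("Bcl2", "VDAC1"): -4.16,
    ("pSTAT3", "pJNK"): -2.30,
    ("BAX", "BAX"): -9.55,
    ("ELYS", "ELYS"): -6.10,
}


@dataclass(frozen=True)
class Treatment:
    """Exposure arm: which drugs are present (and at what concentration).

    Concentrations are consumed only by the Michaelis-Menten
    extrapolation layer; at the reference condition (100 nM BRP / 10 nM
    PTX) the fitted effect magnitudes apply directly.
    """

    has_B: bool = False
    has_P: bool = False
    C_B: float = 0.0
    C_P: float = 0.0

    @property
    def any_drug(self) -> bool:
        return self.has_B or self.has_P

    @property
    def combination(self) -> bool:
        return self.has_B and self.has_P


CONTROL = Treatment()
ARM_B = Treatment(has_B=True, C_B=100.0)
ARM_P = Treatment(has_P=True, C_P=10.0)
ARM_BP = Treatment(has_B=True, has_P=True, C_B=100.0, C_P=10.0)

ARMS = {"control": CONTROL, "B": ARM_B, "P": ARM_P, "BP": ARM_BP}


@dataclass(frozen=True)
class NetworkParams:
    """Turnover constants, regulatory powers and drug-effect magnitudes."""

    k_deg: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_KDEG))
    gamma: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_GAMMA))
    sti_irak4: float = 0.960        # any treatment
    inh_ciap_b: float = 0.967       # BRP
    sti_elys_p: float = 2.22        # PTX
    inh_pjnk_deg_bp: float = 1.0    # combination only, degradation side

    def __post_init__(self) -> None:
        for prot in PROTEINS:
            if self.k_deg.get(prot, 0.0) <= 0:
                raise ValueError(f"k_deg[{prot!r}] must be positive")
        for (tgt, reg) in self.gamma:
            if tgt not in PROTEINS or reg not in PROTEINS:
                raise ValueError(f"edge ({tgt}, {reg}) references an "
                                 "unmodeled protein")
        if not (0.0 <= self.inh_ciap_b <= 1.0):
            raise ValueError("inh_ciap_b must be in [0, 1]")
        if not (0.0 <= self.inh_pjnk_deg_bp <= 1.0):
            raise ValueError("inh_pjnk_deg_bp must be in [0, 1]")
        if self.sti_irak4 < 0 or self.sti_elys_p < 0:
            raise ValueError("stimulation terms must be non-negative")

    def with_overrides(self, overrides: Mapping[str, float]
                       ) -> "NetworkParams":
        """New params with flat-named overrides applied.

        Recognized names: ``k_deg_<protein>``, ``gamma_<target>_<reg>``,
        ``sti_irak4``, ``inh_ciap_b``, ``sti_elys_p``,
        ``inh_pjnk_deg_bp``.
        """
        k_deg = dict(self.k_deg)
        gamma = dict(self.gamma)
        scalars = {
            "sti_irak4": self.sti_irak4,
            "inh_ciap_b": self.inh_ciap_b,
            "sti_elys_p": self.sti_elys_p,
            "inh_pjnk_deg_bp": self.inh_pjnk_deg_bp,
        }
        for name, value in overrides.items():
            if name.startswith("k_deg_"):
                prot = name[len("k_deg_"):]
                if prot not in PROTEINS:
                    raise KeyError(name)
                k_deg[prot] = value
            elif name.startswith("gamma_"):
                tgt, reg = name[len("gamma_"):].split("_", 1)
                gamma[(tgt, reg)] = value
            elif name in scalars:
                scalars[name] = value
            else:
                raise KeyError(name)
        return NetworkParams(k_deg=k_deg, gamma=gamma, **scalars)


def half_life(k_deg: float) -> float:
    """ln(2)/k_deg in hours."""
    if k_deg <= 0:
        raise ValueError("k_deg must be positive")
    return math.log(2.0) / k_deg


_IDX = {p: i for i, p in enumerate(PROTEINS)}


def _rhs_arrays(params: NetworkParams, treatment: Treatment
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precompute (k_deg, gamma matrix, synthesis factor, k_out)."""
    k = np.array([params.k_deg[p] for p in PROTEINS])
    G = np.zeros((len(PROTEINS), len(PROTEINS)))
    for (tgt, reg), g in params.gamma.items():
        G[_IDX[tgt], _IDX[reg]] = g
    syn_mult = np.ones(len(PROTEINS))
    if treatment.has_B:
        syn_mult[_IDX["cIAP1"]] *= 1.0 - params.inh_ciap_b
    if treatment.has_P:
        syn_mult[_IDX["ELYS"]] *= 1.0 + params.sti_elys_p
    if treatment.any_drug:
        syn_mult[_IDX["IRAK4"]] *= 1.0 + params.sti_irak4
    k_out = k.copy()
    if treatment.combination:
        # sole degradation-side effect: pJNK turnover blocked under B+P
        k_out[_IDX["pJNK"]] *= 1.0 - params.inh_pjnk_deg_bp
    return k, G, syn_mult, k_out


def network_rhs(state: np.ndarray, params: NetworkParams,
                treatment: Treatment) -> np.ndarray:
    """Time derivative of the 10 protein fold-changes (PROTEINS order)."""
    state = np.asarray(state, dtype=float)
    if np.any(state <= 0):
        raise ValueError("protein fold-changes must stay positive")
    k, G, syn_mult, k_out = _rhs_arrays(params, treatment)
    return k * syn_mult * np.exp(G @ np.log(state)) - k_out * state


def simulate_network(params: NetworkParams, treatment: Treatment,
                     times: np.ndarray, log2: bool = False,
                     rtol: float = 1e-8, atol: float = 1e-10,
                     ) -> pd.DataFrame:
    """Protein fold-change trajectories from the all-ones baseline.

    Returns a DataFrame indexed by time with one column per protein;
    ``log2=True`` returns log2 fold-changes for comparison with
    expression data.
    """
    times = np.asarray(times, dtype=float)
    t_eval = np.sort(np.unique(times))
    y0 = np.ones(len(PROTEINS))
    if not treatment.any_drug:
        # baseline is an exact stationary point
        values = np.ones((len(t_eval), len(PROTEINS)))
    else:
        k, G, syn_mult, k_out = _rhs_arrays(params, treatment)

        def rhs(_t, y):
            y = np.maximum(y, 1e-12)
            return k * syn_mult * np.exp(G @ np.log(y)) - k_out * y

        sol = solve_ivp(
            rhs, (0.0, float(max(t_eval.max(), 1e-9))), y0,
            t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"network integration failed: {sol.message}")
        values = sol.y.T
    df = pd.DataFrame(np.maximum(values, 1e-12), index=t_eval,
                      columns=list(PROTEINS))
    df.index.name = "time_h"
    if log2:
        df = np.log2(df)
    return df


# ---------------------------------------------------------------------------
# sequential fitting to log2 fold-change expression profiles

REQUIRED_ARMS = ("B", "P", "BP")
DEFAULT_TIMES = (6.0, 24.0, 48.0, 72.0)

# stage -> (protein fitted, arms used, free parameter names, upstream deps)
_STAGE_PLAN = (
    ("cIAP1", ("B", "BP"), ("k_deg_cIAP1", "inh_ciap_b"), ()),
    ("pNFkB", ("B", "BP"), ("gamma_pNFkB_cIAP1",),
     ("k_deg_cIAP1", "inh_ciap_b")),
    ("IRAK4", ("B", "P", "BP"), ("k_deg_IRAK4", "sti_irak4"), ()),
    ("pJNK", ("BP",), ("k_deg_pJNK",), ()),
    ("ELYS", ("P", "BP"),
     ("k_deg_ELYS", "sti_elys_p", "gamma_ELYS_ELYS"), ()),
    ("BAX", ("B", "BP"), ("k_deg_BAX", "gamma_BAX_pNFkB",
                          "gamma_BAX_BAX"),
     ("gamma_pNFkB_cIAP1",)),
    ("pSTAT3", ("B", "P", "BP"), ("k_deg_pSTAT3", "gamma_pSTAT3_pJNK"),
     ("k_deg_IRAK4", "sti_irak4", "k_deg_pJNK")),
    ("VDAC1", ("BP",), ("k_deg_VDAC1",), ("k_deg_pJNK",)),
    ("ASPP2", ("P", "BP"), ("k_deg_ASPP2",),
     ("k_deg_ELYS", "sti_elys_p", "gamma_ELYS_ELYS")),
    ("Bcl2", ("B", "P", "BP"),
     ("gamma_Bcl2_pNFkB", "gamma_Bcl2_pSTAT3", "gamma_Bcl2_VDAC1"),
     ("gamma_pNFkB_cIAP1", "k_deg_pSTAT3", "k_deg_VDAC1")),
)

_PARAM_STARTS = {
    "k_deg_cIAP1": (0.5, True), "inh_ciap_b": (0.9, False),
    "gamma_pNFkB_cIAP1": (-0.3, False),
    "k_deg_IRAK4": (0.1, True), "sti_irak4": (1.0, True),
    "k_deg_pJNK": (0.01, True),
    "k_deg_ELYS": (0.03, True), "sti_elys_p": (2.0, True),
    "gamma_ELYS_ELYS": (-5.0, False),
    "k_deg_BAX": (0.03, True), "gamma_BAX_pNFkB": (1.5, False),
    "gamma_BAX_BAX": (-8.0, False),
    "k_deg_pSTAT3": (0.03, True), "gamma_pSTAT3_pJNK": (-2.0, False),
    "k_deg_VDAC1": (0.5, True),
    "k_deg_ASPP2": (0.5, True),
    "gamma_Bcl2_pNFkB": (0.7, False), "gamma_Bcl2_pSTAT3": (1.0, False),
    "gamma_Bcl2_VDAC1": (-3.0, False),
}


def _profile_model(protein: str, arms: tuple[str, ...],
                   rows: pd.DataFrame, base: NetworkParams):
    """Model function: full-network simulation, read out one protein."""

    def model_fn(p: Mapping[str, float]) -> np.ndarray:
        params = base.with_overrides(p)
        preds = np.empty(len(rows))
        pos = 0
        for arm in arms:
            sub = rows[rows.arm == arm]
            times = np.sort(sub.time_h.unique())
            traj = simulate_network(params, ARMS[arm], times, log2=True)
            vals = traj[protein]
            preds[pos:pos + len(sub)] = vals.loc[
                sub.time_h.to_numpy()].to_numpy()
            pos += len(sub)
        return preds

    return model_fn


def fit_network(profiles: pd.DataFrame, seed: int = 0,
                n_starts: int = 2, delta_p: float = 0.2,
                mean_profiles: bool = False) -> list[FitResult]:
    """Sequentially fit the network to log2 fold-change profiles.

    ``profiles`` columns: protein, arm ('B'|'P'|'BP'), time_h,
    replicate, value (log2 fold-change vs time-matched vehicle).
    Upstream drug targets (cIAP1, IRAK4, pJNK, ELYS) are fitted first
    and frozen before their downstream readouts, mirroring how the
    signal propagates through the interaction map.  Residuals are on
    the log2 scale under a constant error model.
    """
    needed = {"protein", "arm", "time_h", "replicate", "value"}
    if not needed.issubset(profiles.columns):
        raise ValueError(f"profiles must have columns {sorted(needed)}")
    have_arms = set(profiles.arm.unique())
    missing = [a for a in REQUIRED_ARMS if a not in have_arms]
    if missing:
        raise ValueError(f"missing required arms: {missing}")
    if mean_profiles:
        profiles = (profiles
                    .groupby(["protein", "arm", "time_h"], as_index=False)
                    .value.mean())
        profiles["replicate"] = 1

    base = NetworkParams()
    vspec = VarianceSpec("constant", delta=delta_p)
    stages = []
    for protein, arms, free_names, requires in _STAGE_PLAN:
        rows = profiles[(profiles.protein == protein)
                        & (profiles.arm.isin(arms))]
        rows = pd.concat(
            [rows[rows.arm == a].sort_values(["time_h", "replicate"])
             for a in arms]).reset_index(drop=True)
        if rows.empty:
            raise ValueError(f"no profiles for protein {protein!r}")
        free = []
        for name in free_names:
            start, positive = _PARAM_STARTS[name]
            if name == "inh_ciap_b":
                free.append(Param(name, start, 0.0, 1.0))
            elif positive:
                free.append(Param(name, start, 1e-4, 20.0, log=True))
            else:
                free.append(Param(name, start, -15.0, 15.0))
        stages.append(Stage(
            name=f"network:{protein}",
            model_fn=_profile_model(protein, arms, rows, base),
            observations=rows.value.to_numpy(),
            free=free, vspec=vspec, requires=tuple(requires)))
    # objective tolerance sits above the ODE-solver error so the simplex
    # does not chase integration noise
    return sequential_fit(stages, seed=seed, n_starts=n_starts,
                          tol=1e-6, maxiter=3000)


def params_from_fits(fits: list[FitResult],
                     base: NetworkParams | None = None) -> NetworkParams:
    """Assemble a NetworkParams from a sequential-fit chain."""
    base = base or NetworkParams()
    merged: dict[str, float] = {}
    for fr in fits:
        merged.update(fr.estimates)
    merged = {k: v for k, v in merged.items()
              if not k.startswith("err_")}
    return base.with_overrides(merged)
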