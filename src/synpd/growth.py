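"""Cell growth kinetic model with delayed, concentration-dependent killing.

PANC-1 cells grow exponentially with net rate constant k_G.  Each drug
(paclitaxel, PTX; birinapant, BRP) contributes a cytotoxic signal described
by a Hill function of its constant medium concentration,

    S0 = K_max * C / (psi * KC50 + C),

delayed through a chain of ``n_transit`` first-order transit compartments
with mean transit time tau (per-compartment rate n_transit/tau).  The two
delayed signals add on the cell-loss side:

    dN/dt = (k_G - S_B[n] - S_P[n]) * N.

The dimensionless interaction term psi multiplies both drugs' KC50 in
combination arms: psi < 1 means each drug's potency is enhanced by the
other (synergy), psi = 1 is additivity, psi > 1 antagonism.  psi is fixed
to 1 for single-drug exposure.

For constant concentrations the model has a closed-form solution: the
transit chain's output is S0 * P(n, r t) with P the regularized lower
incomplete gamma function (an Erlang CDF), and its time integral is also
analytic, so N(t) is evaluated without numerical integration.  A
``method="ode"`` path integrates the same system with scipy for
cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.special import gammainc

from .estimation import (
    ERR_DELTA,
    ERR_SIGMA,
    FitResult,
    Param,
    VarianceSpec,
    fit_ml,
    select_transit_depth,
)

__all__ = [
    "GrowthParams",
    "ExposureDesign",
    "killing_signal",
    "simulate_growth",
    "doubling_time",
    "correction_factor",
    "additivity_ratio",
    "fit_growth",
    "GrowthFit",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the growth/kill model (rates in 1/h, conc. in nM)."""

    k_G: float = 0.0225
    K_maxB: float = 0.0153
    K_maxP: float = 0.0233
    KC50_B: float = 277.0
    KC50_P: float = 18.3
    tau_B: float = 24.0
    tau_P: float = 24.0
    n_transit: int = 3
    psi: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_G", "K_maxB", "K_maxP", "KC50_B", "KC50_P",
                     "tau_B", "tau_P", "psi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_transit < 0:
            raise ValueError("n_transit must be >= 0")


@dataclass(frozen=True)
class ExposureDesign:
    """Constant-concentration exposure: which arm, observed when."""

    C_B: float = 0.0
    C_P: float = 0.0
    times: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0, 120.0)
    N0: float = 1.0  # density normalized to the T0 mean

    def __post_init__(self) -> None:
        if self.C_B < 0 or self.C_P < 0:
            raise ValueError("concentrations must be non-negative")
        if any(t < 0 for t in self.times):
            raise ValueError("observation times must be non-negative")
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")


def killing_signal(C: float, K_max: float, KC50: float,
                   psi: float = 1.0) -> float:
    """Hill cytotoxic signal K_max*C/(psi*KC50 + C); zero at C = 0."""
    if C < 0:
        raise ValueError("concentration must be non-negative")
    if C == 0:
        return 0.0
    return K_max * C / (psi * KC50 + C)


def doubling_time(k: float) -> float:
    """ln(2)/k: doubling time of exponential growth (or a half-life)."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return math.log(2.0) / k


def correction_factor(n_diploid: float, n_polyploid: float,
                      polyploid_weight: float = 2.0) -> float:
    """SRB polyploidy correction CF = (Nd + Np) / (Nd + w*Np).

    The SRB stain reports protein mass; a polyploid cell carries about
    ``polyploid_weight`` (default 2) times the protein of a diploid cell,
    so the apparent count overestimates the true count.  CF multiplies
    measured optical densities.  CF is in (1/w, 1].
    """
    if n_diploid < 0 or n_polyploid < 0:
        raise ValueError("counts must be non-negative")
    if n_diploid == 0 and n_polyploid == 0:
        raise ValueError("at least one count must be positive")
    return (n_diploid + n_polyploid) / (
        n_diploid + polyploid_weight * n_polyploid
    )


def _kill_integral(S0: float, n: int, tau: float,
                   t: np.ndarray) -> np.ndarray:
    """Integral of the delayed kill signal from 0 to t (closed form).

    The chain output is S0 * P(n, r t), r = n/tau; its integral is
    S0 * [t - (1/r) * sum_{m=1..n} P(m, r t)].
    """
    if S0 == 0.0:
        return np.zeros_like(t)
    if n == 0:
        return S0 * t
    r = n / tau
    acc = np.zeros_like(t)
    for m in range(1, n + 1):
        acc += gammainc(m, r * t)
    return S0 * (t - acc / r)


def simulate_growth(params: GrowthParams, design: ExposureDesign,
                    method: str = "analytic",
                    rtol: float = 1e-10) -> np.ndarray:
    """Normalized cell density N(t) at the design's observation times.

    ``method="analytic"`` uses the closed-form solution (constant
    concentrations only, which is all the design supports);
    ``method="ode"`` integrates the transit-chain ODE system with LSODA
    as an independent numerical route.
    """
    t = np.asarray(design.times, dtype=float)
    S0B = killing_signal(design.C_B, params.K_maxB, params.KC50_B,
                         params.psi)
    S0P = killing_signal(design.C_P, params.K_maxP, params.KC50_P,
                         params.psi)
    if method == "analytic":
        expo = (params.k_G * t
                - _kill_integral(S0B, params.n_transit, params.tau_B, t)
                - _kill_integral(S0P, params.n_transit, params.tau_P, t))
        return design.N0 * np.exp(expo)
    if method != "ode":
        raise ValueError(f"unknown method {method!r}")

    n = params.n_transit

    def rhs(_t, y):
        N = y[0]
        dy = np.empty_like(y)
        if n == 0:
            sB, sP = S0B, S0P
            dy[0] = (params.k_G - sB - sP) * N
            return dy
        sB_chain = y[1:1 + n]
        sP_chain = y[1 + n:1 + 2 * n]
        rB = n / params.tau_B
        rP = n / params.tau_P
        dy[0] = (params.k_G - sB_chain[-1] - sP_chain[-1]) * N
        prevB = S0B
        for j in range(n):
            dy[1 + j] = (prevB - sB_chain[j]) * rB
            prevB = sB_chain[j]
        prevP = S0P
        for j in range(n):
            dy[1 + n + j] = (prevP - sP_chain[j]) * rP
            prevP = sP_chain[j]
        return dy

    y0 = np.zeros(1 + 2 * n)
    y0[0] = design.N0
    t_end = float(max(t.max(), 1e-9))
    sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=np.sort(t),
                    method="LSODA", rtol=rtol, atol=rtol * 1e-2)
    if not sol.success:
        raise RuntimeError(f"growth ODE integration failed: {sol.message}")
    order = np.argsort(np.argsort(t))
    return sol.y[0][order]


def additivity_ratio(observed: np.ndarray, params: GrowthParams,
                     design: ExposureDesign) -> np.ndarray:
    """Observed / additive-prediction ratios per time point.

    The prediction forces psi = 1 (pure additivity of the two killing
    signals) with single-agent parameters; ratios below 1 mean the real
    combination killed more than additivity predicts (supra-additive).
    """
    predicted = simulate_growth(replace(params, psi=1.0), design)
    if np.any(predicted <= 0):
        raise ValueError("additive prediction reached zero density")
    return np.asarray(observed, dtype=float) / predicted


# ---------------------------------------------------------------------------
# fitting


@dataclass
class GrowthFit:
    """Staged growth-model fit: per-stage results plus the merged view."""

    stages: list[FitResult]
    params: GrowthParams
    n_transit: int
    psi_ci: tuple[float, float]
    unidentifiable: list[str] = field(default_factory=list)

    @property
    def psi(self) -> float:
        return self.params.psi

    def report_text(self) -> str:
        parts = [fr.report_text() for fr in self.stages]
        parts.append(
            f"selected transit depth: {self.n_transit}\n"
            f"psi = {self.params.psi:.4f} "
            f"(95% CI {self.psi_ci[0]:.4f}-{self.psi_ci[1]:.4f})"
        )
        if self.unidentifiable:
            parts.append(
                "unidentifiable (no informative arms): "
                + ", ".join(self.unidentifiable)
            )
        return "\n\n".join(parts)


_COLS = ("time_h", "conc_PTX_nM", "conc_BRP_nM", "replicate",
         "density_norm")


def _check_table(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLS if c not in data.columns]
    if missing:
        raise ValueError(f"proliferation table missing columns {missing}")
    ctrl = data[(data.conc_PTX_nM == 0) & (data.conc_BRP_nM == 0)]
    if ctrl.empty:
        raise ValueError("proliferation table has no vehicle control arm")
    return data


def _arm_predictions(params: GrowthParams, arms: pd.DataFrame) -> np.ndarray:
    """Model prediction for each row of an (already grouped) arm table."""
    out = np.empty(len(arms))
    for (cp, cb), idx in arms.groupby(
            ["conc_PTX_nM", "conc_BRP_nM"]).groups.items():
        sub = arms.loc[idx]
        design = ExposureDesign(C_B=float(cb), C_P=float(cp),
                                times=tuple(sub.time_h.to_numpy()))
        out[arms.index.get_indexer(idx)] = simulate_growth(params, design)
    return out


def _stage_model(arms: pd.DataFrame, base: dict, n_transit: int):
    def model_fn(p: dict) -> np.ndarray:
        full = dict(base)
        full.update(p)
        gp = GrowthParams(
            k_G=full["k_G"], K_maxB=full["K_maxB"], K_maxP=full["K_maxP"],
            KC50_B=full["KC50_B"], KC50_P=full["KC50_P"],
            tau_B=full["tau_B"], tau_P=full["tau_P"],
            n_transit=n_transit, psi=full["psi"])
        return _arm_predictions(gp, arms)
    return model_fn


_DEFAULT_BASE = dict(k_G=0.02, K_maxB=0.02, K_maxP=0.02, KC50_B=300.0,
                     KC50_P=20.0, tau_B=24.0, tau_P=24.0, psi=1.0)


def fit_growth(data: pd.DataFrame, n_transit: int | str = "auto",
               seed: int = 0, n_starts: int = 3,
               vspec: VarianceSpec | None = None,
               transit_candidates: Sequence[int] = (0, 1, 2, 3, 4, 5),
               ) -> GrowthFit:
    """Fit the growth model to a proliferation table.

    The fit is staged in the order the information arrives: the vehicle
    arm identifies k_G; each drug's single-agent arms identify its
    K_max/KC50/tau with psi fixed at 1; the combination arms then
    identify psi with everything upstream frozen.  The affine-proportional
    variance parameters (delta, sigma) are co-estimated in each stage.
    Transit-chain depth is chosen by AIC over ``transit_candidates`` when
    ``n_transit="auto"``.
    """
    data = _check_table(data.reset_index(drop=True))
    if vspec is None:
        vspec = VarianceSpec("affine_proportional", delta=0.05, sigma=0.1)

    if n_transit == "auto":
        fits = [
            _fit_growth_at_depth(data, d, seed, n_starts, vspec)
            for d in transit_candidates
        ]
        aics = [sum(s.aic for s in f.stages) for f in fits]
        best = transit_candidates[select_transit_depth(aics)]
        chosen = fits[list(transit_candidates).index(best)]
        return chosen
    return _fit_growth_at_depth(data, int(n_transit), seed, n_starts, vspec)


def _fit_growth_at_depth(data: pd.DataFrame, depth: int, seed: int,
                         n_starts: int, vspec: VarianceSpec) -> GrowthFit:
    ctrl = data[(data.conc_PTX_nM == 0) & (data.conc_BRP_nM == 0)]
    ptx = data[(data.conc_PTX_nM > 0) & (data.conc_BRP_nM == 0)]
    brp = data[(data.conc_BRP_nM > 0) & (data.conc_PTX_nM == 0)]
    combo = data[(data.conc_PTX_nM > 0) & (data.conc_BRP_nM > 0)]

    err_free = [
        Param(ERR_DELTA, vspec.delta or 0.05, 1e-6, 10.0, log=True),
        Param(ERR_SIGMA, vspec.sigma or 0.05, 1e-6, 10.0, log=True),
    ]
    stages: list[FitResult] = []
    base = dict(_DEFAULT_BASE)
    unidentifiable: list[str] = []

    # stage 1: control arm -> k_G
    fr = fit_ml(
        _stage_model(ctrl, base, depth), ctrl.density_norm.to_numpy(),
        free=[Param("k_G", 0.02, 1e-5, 1.0, log=True), *err_free],
        vspec=vspec, seed=seed, n_starts=n_starts, name="control:k_G")
    base["k_G"] = fr.estimates["k_G"]
    stages.append(fr)

    # stage 2/3: single-agent arms (psi pinned at 1)
    for label, arm, pnames in (
            ("PTX", ptx, ("K_maxP", "KC50_P", "tau_P")),
            ("BRP", brp, ("K_maxB", "KC50_B", "tau_B"))):
        if arm.empty:
            unidentifiable.extend(pnames)
            continue
        kc_start = 20.0 if label == "PTX" else 300.0
        free = [
            Param(pnames[0], 0.02, 1e-5, 1.0, log=True),
            Param(pnames[1], kc_start, 1e-2, 1e5, log=True),
            *err_free,
        ]
        if depth > 0:
            free.insert(2, Param(pnames[2], 24.0, 0.1, 500.0, log=True))
        fr = fit_ml(
            _stage_model(arm, base, depth), arm.density_norm.to_numpy(),
            free=free, vspec=vspec, seed=seed + 1, n_starts=n_starts,
            name=f"{label}:single-agent")
        base.update(fr.estimates)
        stages.append(fr)

    # stage 4: combination arms -> psi
    psi_hat, psi_ci = 1.0, (math.nan, math.nan)
    if not combo.empty and not ptx.empty and not brp.empty:
        fr = fit_ml(
            _stage_model(combo, base, depth),
            combo.density_norm.to_numpy(),
            free=[Param("psi", 1.0, 1e-3, 100.0, log=True), *err_free],
            vspec=vspec, seed=seed + 2, n_starts=n_starts,
            name="combination:psi")
        psi_hat = fr.estimates["psi"]
        psi_ci = fr.ci("psi")
        base["psi"] = psi_hat
        stages.append(fr)
    elif not combo.empty:
        unidentifiable.append("psi")

    params = GrowthParams(
        k_G=base["k_G"], K_maxB=base["K_maxB"], K_maxP=base["K_maxP"],
        KC50_B=base["KC50_B"], KC50_P=base["KC50_P"], tau_B=base["tau_B"],
        tau_P=base["tau_P"], n_transit=depth, psi=psi_hat)
    return GrowthFit(stages=stages, params=params, n_transit=depth,
                     psi_ci=psi_ci, unidentifiable=unidentifiable)


def bootstrap_psi_ci(fit: GrowthFit, data: pd.DataFrame,
                     n_boot: int = 200, seed: int = 0,
                     level: float = 0.95) -> tuple[float, float]:
    """Seeded parametric bootstrap CI for psi (percentile method).

    Re-simulates combination arms from the fitted parameters with the
    fitted noise model and refits psi only; slower but free of the
    asymptotic-normality assumption behind the Wald interval.
    """
    combo = data[(data.conc_PTX_nM > 0) & (data.conc_BRP_nM > 0)]
    combo = combo.reset_index(drop=True)
    psi_stage = fit.stages[-1]
    delta = psi_stage.estimates.get(ERR_DELTA, 0.05)
    sigma = psi_stage.estimates.get(ERR_SIGMA, 0.1)
    vspec = VarianceSpec("affine_proportional", delta=delta, sigma=sigma)
    preds = _arm_predictions(fit.params, combo)
    rng = np.random.default_rng(seed)
    base = dict(_DEFAULT_BASE)
    for name in ("k_G", "K_maxB", "K_maxP", "KC50_B", "KC50_P",
                 "tau_B", "tau_P"):
        base[name] = getattr(fit.params, name)
    psis = []
    for b in range(n_boot):
        sim = preds + rng.normal(0.0, vspec.sd(preds))
        fr = fit_ml(
            _stage_model(combo, base, fit.n_transit), sim,
            free=[Param("psi", fit.params.psi, 1e-3, 100.0, log=True)],
            vspec=vspec, seed=seed + b, n_starts=1, name="boot:psi")
        psis.append(fr.estimates["psi"])
    lo, hi = np.quantile(psis, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)
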