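"""Maximum-likelihood fitting machinery shared by all models.

Observations are treated as independent Gaussians whose variance follows one
of two error models used throughout the analysis:

* ``constant``: Var = delta^2 for every observation (used for log2
  fold-changes and cell-cycle percentages);
* ``affine_proportional``: Var = (delta + sigma * Y)^2 where Y is the model
  prediction (used for cell densities and total cell counts).

Point estimation minimizes the negative log-likelihood with a seeded
multi-start Nelder-Mead simplex; bounds are enforced by smooth parameter
transformations (log for positive rate/variance constants, logistic for
two-sided boxes).  Parameter uncertainty (CV%) is the standard asymptotic
ML approximation from a finite-difference observed-information matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "VarianceSpec",
    "BlockVarianceSpec",
    "Param",
    "FitResult",
    "Stage",
    "neg_log_likelihood",
    "fit_ml",
    "aic",
    "select_transit_depth",
    "sequential_fit",
]

_LOG_2PI = math.log(2.0 * math.pi)

# reserved free-parameter names routed into the variance model
ERR_DELTA = "err_delta"
ERR_SIGMA = "err_sigma"


@dataclass(frozen=True)
class VarianceSpec:
    """Gaussian error model evaluated at the model prediction."""

    kind: str = "constant"  # "constant" | "affine_proportional"
    delta: float = 1.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "affine_proportional"):
            raise ValueError(f"unknown variance kind: {self.kind!r}")
        if self.delta < 0 or self.sigma < 0:
            raise ValueError("variance parameters must be non-negative")

    def variance(self, predictions: np.ndarray) -> np.ndarray:
        predictions = np.asarray(predictions, dtype=float)
        if self.kind == "constant":
            return np.full_like(predictions, self.delta**2)
        sd = self.delta + self.sigma * predictions
        return sd**2

    def sd(self, predictions: np.ndarray) -> np.ndarray:
        return np.sqrt(self.variance(predictions))


@dataclass(frozen=True)
class BlockVarianceSpec:
    """Concatenated observation blocks with different error models.

    Used when one fit mixes observable kinds (e.g. cell-cycle
    percentages under constant error together with total counts under
    the affine-proportional model).  ``blocks`` maps contiguous slices
    of the prediction vector to their VarianceSpec.
    """

    specs: tuple[VarianceSpec, ...]
    lengths: tuple[int, ...]

    # mimic the VarianceSpec interface used by neg_log_likelihood
    delta: float = float("nan")
    sigma: float = float("nan")

    def variance(self, predictions: np.ndarray) -> np.ndarray:
        predictions = np.asarray(predictions, dtype=float)
        if predictions.size != sum(self.lengths):
            raise ValueError("prediction length does not match blocks")
        out = np.empty_like(predictions)
        start = 0
        for spec, n in zip(self.specs, self.lengths):
            out[start:start + n] = spec.variance(
                predictions[start:start + n])
            start += n
        return out

    def sd(self, predictions: np.ndarray) -> np.ndarray:
        return np.sqrt(self.variance(predictions))


def neg_log_likelihood(
    predictions: np.ndarray,
    observations: np.ndarray,
    vspec: VarianceSpec,
) -> float:
    """Negative Gaussian log-likelihood under ``vspec``.

    Raises ``ValueError`` on length mismatch or a non-positive variance,
    reporting the first offending index.
    """
    predictions = np.asarray(predictions, dtype=float)
    observations = np.asarray(observations, dtype=float)
    if predictions.shape != observations.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} predictions vs "
            f"{observations.shape} observations"
        )
    v = vspec.variance(predictions)
    bad = np.flatnonzero(v <= 0)
    if bad.size:
        raise ValueError(f"non-positive variance at index {bad[0]}")
    resid2 = (observations - predictions) ** 2
    return float(0.5 * np.sum(np.log(2.0 * np.pi * v) + resid2 / v))


def aic(loglik: float, n_free: int) -> float:
    """Akaike information criterion, -2*loglik + 2*n_free."""
    if n_free < 0:
        raise ValueError("n_free must be non-negative")
    return -2.0 * loglik + 2.0 * n_free


@dataclass(frozen=True)
class Param:
    """A free parameter: starting value, box bounds, and transform.

    ``log=True`` optimizes ln(x) (for strictly positive rate and variance
    constants); finite two-sided bounds are mapped through a logistic.
    Power coefficients are typically left unconstrained (``log=False``,
    infinite bounds).
    """

    name: str
    start: float
    lo: float = -math.inf
    hi: float = math.inf
    log: bool = False

    def __post_init__(self) -> None:
        if not (self.lo <= self.start <= self.hi):
            raise ValueError(
                f"start {self.start} outside bounds for {self.name!r}"
            )
        if self.log and self.start <= 0:
            raise ValueError(f"log-transformed {self.name!r} needs start > 0")

    # --- internal <-> natural space ----------------------------------
    def to_internal(self, x: float) -> float:
        if math.isfinite(self.lo) and math.isfinite(self.hi):
            # logistic: clamp away from the edges for a finite image
            span = self.hi - self.lo
            f = min(max((x - self.lo) / span, 1e-12), 1 - 1e-12)
            return math.log(f / (1 - f))
        if self.log:
            return math.log(x)
        return x

    def from_internal(self, y: float) -> float:
        y = min(max(y, -700.0), 700.0)  # guard exp overflow
        if math.isfinite(self.lo) and math.isfinite(self.hi):
            return self.lo + (self.hi - self.lo) / (1.0 + math.exp(-y))
        if self.log:
            return math.exp(y)
        return y


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    estimates: dict[str, float]
    cv_percent: dict[str, float]
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    residuals: np.ndarray
    fixed: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    n_starts: int = 1
    name: str = ""

    @property
    def n_free(self) -> int:
        return len(self.estimates)

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Asymptotic Wald confidence interval for one parameter."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        est, s = self.estimates[name], self.se[name]
        if not math.isfinite(s):
            return (math.nan, math.nan)
        return (est - z * s, est + z * s)

    def report_text(self) -> str:
        lines = [
            f"model: {self.name or '(unnamed)'}",
            f"n_obs={self.n_obs}  loglik={self.loglik:.4f}  "
            f"AIC={self.aic:.4f}  converged={self.converged}",
            f"{'parameter':<20}{'estimate':>14}{'CV%':>10}  status",
        ]
        for k, v in self.estimates.items():
            cv = self.cv_percent.get(k, math.nan)
            cv_s = f"{cv:.2f}" if math.isfinite(cv) else "n/a"
            lines.append(f"{k:<20}{v:>14.6g}{cv_s:>10}  free")
        for k, v in self.fixed.items():
            lines.append(f"{k:<20}{v:>14.6g}{'-':>10}  fixed")
        return "\n".join(lines)


def _make_objective(
    model_fn: Callable[[Mapping[str, float]], np.ndarray],
    observations: np.ndarray,
    free: Sequence[Param],
    fixed: Mapping[str, float],
    vspec: VarianceSpec,
):
    names = [p.name for p in free]

    def nll_natural(x: np.ndarray) -> float:
        params = dict(fixed)
        params.update(zip(names, x))
        vs = vspec
        if ERR_DELTA in params or ERR_SIGMA in params:
            vs = replace(
                vspec,
                delta=params.pop(ERR_DELTA, vspec.delta),
                sigma=params.pop(ERR_SIGMA, vspec.sigma),
            )
        try:
            preds = model_fn(params)
            if not np.all(np.isfinite(preds)):
                return 1e12
            return neg_log_likelihood(preds, observations, vs)
        except (ValueError, FloatingPointError, OverflowError,
                RuntimeError):
            return 1e12

    return nll_natural


def _weighted_residuals(
    model_fn, observations, params: Mapping[str, float], vspec: VarianceSpec
) -> np.ndarray:
    params = dict(params)
    vs = replace(
        vspec,
        delta=params.pop(ERR_DELTA, vspec.delta),
        sigma=params.pop(ERR_SIGMA, vspec.sigma),
    )
    preds = model_fn(params)
    return (np.asarray(observations, float) - preds) / vs.sd(preds)


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-6)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x.copy() for _ in range(4))
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4 * h[i] * h[j])
    return H


def fit_ml(
    model_fn: Callable[[Mapping[str, float]], np.ndarray],
    observations: np.ndarray,
    free: Sequence[Param],
    fixed: Mapping[str, float] | None = None,
    vspec: VarianceSpec = VarianceSpec(),
    seed: int = 0,
    n_starts: int = 5,
    tol: float = 1e-8,
    maxiter: int = 5000,
    name: str = "",
) -> FitResult:
    """Fit free parameters by maximum likelihood.

    ``model_fn`` maps a full parameter dict (free merged over ``fixed``) to
    a prediction vector aligned with ``observations``.  The reserved names
    ``err_delta``/``err_sigma`` in ``free`` co-estimate the variance-model
    parameters.  Multi-start is controlled by ``seed``; the first start is
    the supplied starting point, later ones are jittered in transformed
    space.
    """
    fixed = dict(fixed or {})
    observations = np.asarray(observations, dtype=float)
    if not free:
        raise ValueError("no free parameters")
    nll_nat = _make_objective(model_fn, observations, free, fixed, vspec)

    def nll_internal(y: np.ndarray) -> float:
        x = np.array([p.from_internal(v) for p, v in zip(free, y)])
        return nll_nat(x)

    rng = np.random.default_rng(seed)
    y0 = np.array([p.to_internal(p.start) for p in free])
    best = None
    any_converged = False
    # pick the extra starts from a seeded random scan around the
    # supplied start (mixed scales), keeping the lowest-objective
    # points: local simplex runs can then begin in distinct basins
    starts = [y0]
    if n_starts > 1:
        n_scan = 10 * len(free)
        cand = [y0 + rng.normal(0.0, scale, size=len(y0))
                for scale in np.tile((0.5, 1.0),
                                     (n_scan + 1) // 2)[:n_scan]]
        scored = [(nll_internal(y), i, y) for i, y in enumerate(cand)]
        scored = [t for t in scored if t[0] < 1e11]
        scored.sort(key=lambda t: t[:2])
        starts.extend(y for _, _, y in scored[: n_starts - 1])
    for y_start in starts:
        res = optimize.minimize(
            nll_internal,
            y_start,
            method="Nelder-Mead",
            options={
                "fatol": tol,
                "xatol": tol,
                "maxiter": maxiter,
                "maxfev": maxiter,
            },
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    # polish: restart the simplex at the incumbent optimum (a fresh
    # simplex often walks off a premature plateau)
    res = optimize.minimize(
        nll_internal, best.x, method="Nelder-Mead",
        options={"fatol": tol, "xatol": tol,
                 "maxiter": maxiter, "maxfev": maxiter})
    if res.fun < best.fun:
        best = res
        any_converged = any_converged or bool(res.success)

    x_hat = np.array([p.from_internal(v) for p, v in zip(free, best.x)])
    names = [p.name for p in free]
    estimates = dict(zip(names, (float(v) for v in x_hat)))
    loglik = -float(best.fun)

    # observed information in natural parameter space
    se: dict[str, float] = {}
    cv: dict[str, float] = {}
    try:
        H = _fd_hessian(nll_nat, x_hat)
        cov = np.linalg.pinv(H)
        diag = np.diag(cov)
        for k, est, d in zip(names, x_hat, diag):
            if d > 0 and np.isfinite(d):
                se[k] = float(np.sqrt(d))
                cv[k] = (
                    100.0 * se[k] / abs(est) if est != 0 else math.inf
                )
            else:
                se[k] = math.nan
                cv[k] = math.nan
    except (np.linalg.LinAlgError, ValueError):
        se = {k: math.nan for k in names}
        cv = {k: math.nan for k in names}

    params_hat = dict(fixed)
    params_hat.update(estimates)
    residuals = _weighted_residuals(model_fn, observations, params_hat, vspec)

    return FitResult(
        estimates=estimates,
        cv_percent=cv,
        loglik=loglik,
        aic=aic(loglik, len(free)),
        n_obs=observations.size,
        converged=any_converged,
        residuals=residuals,
        fixed=fixed,
        se=se,
        n_starts=n_starts,
        name=name,
    )


def select_transit_depth(fit_results: Sequence[FitResult | float]) -> int:
    """Index (= number of transit compartments) with the lowest AIC.

    Ties break toward fewer compartments (the simpler model).
    """
    if not len(fit_results):
        raise ValueError("no candidate fits")
    aics = [
        fr.aic if isinstance(fr, FitResult) else float(fr)
        for fr in fit_results
    ]
    best = 0
    for i, a in enumerate(aics):
        if a < aics[best]:
            best = i
    return best


@dataclass
class Stage:
    """One stage of a sequential (fix-upstream, fit-downstream) chain."""

    name: str
    model_fn: Callable[[Mapping[str, float]], np.ndarray]
    observations: np.ndarray
    free: Sequence[Param]
    vspec: VarianceSpec = VarianceSpec()
    fixed: dict[str, float] = field(default_factory=dict)
    requires: tuple[str, ...] = ()


def sequential_fit(
    stages: Iterable[Stage],
    seed: int = 0,
    n_starts: int = 5,
    **fit_kwargs,
) -> list[FitResult]:
    """Fit stages in order, freezing every earlier estimate downstream.

    Each stage's ``requires`` lists upstream parameter names it consumes;
    a stage placed before its dependency fails the precondition check.
    """
    accumulated: dict[str, float] = {}
    results: list[FitResult] = []
    for i, stage in enumerate(stages):
        available = set(accumulated) | set(stage.fixed)
        missing = [r for r in stage.requires if r not in available]
        if missing:
            raise ValueError(
                f"stage {stage.name!r} requires upstream estimates "
                f"{missing} that are not yet available"
            )
        fixed = dict(accumulated)
        fixed.update(stage.fixed)
        fr = fit_ml(
            stage.model_fn,
            stage.observations,
            stage.free,
            fixed=fixed,
            vspec=stage.vspec,
            seed=seed + i,
            n_starts=n_starts,
            name=stage.name,
            **fit_kwargs,
        )
        if not fr.converged:
            results.append(fr)
            raise RuntimeError(
                f"stage {stage.name!r} did not converge; downstream "
                "stages aborted"
            )
        accumulated.update(fr.estimates)
        results.append(fr)
    return results
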