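"""Synthetic data generation for every pipeline input.

Each generator simulates the corresponding model at a ground-truth
parameter set (the fitted estimates by default) and adds noise with the
same error structure the fitting assumes: affine-proportional Gaussian
noise for cell densities and counts, constant Gaussian error for
percentages and for log2 fold-changes.  Percentage tables are
renormalized to sum to 100 across the DNA-content classes after
perturbation; counts are redrawn rather than clipped when a draw falls
below zero.  A fixed seed makes every generator byte-reproducible.

The clustering matrix generator emulates the large-scale expression
experiment: ~3325 proteins partitioned into 9 temporal archetypes
(cluster sizes drawn in the 30-508 range), measured in two batches with
distinct rank-preserving intensity distortions so that quantile
normalization has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cycle import CycleParams, simulate_cycle
from .growth import ExposureDesign, GrowthParams, simulate_growth
from .network import ARMS, NetworkParams, simulate_network
from .proteomics import ProteomicsMatrix

__all__ = [
    "SyntheticSpec",
    "generate_growth_data",
    "generate_cycle_data",
    "generate_protein_profiles",
    "generate_cluster_matrix",
]

PTX_LEVELS = (2.5, 5.0, 10.0, 15.0, 30.0, 60.0)   # nM, six levels
BRP_LEVELS = (15.0, 60.0, 250.0, 1000.0)          # nM, four levels
GROWTH_TIMES = (24.0, 48.0, 72.0, 96.0, 120.0)
CYCLE_TIMES = (0.0, 17.0, 48.0, 72.0)
PROTEIN_TIMES = (6.0, 24.0, 48.0, 72.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth, design grids and noise levels for all generators."""

    seed: int = 0
    n_replicates: int = 3
    growth: GrowthParams = field(
        default_factory=lambda: GrowthParams(psi=0.69))
    network: NetworkParams = field(default_factory=NetworkParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    ptx_levels: tuple[float, ...] = PTX_LEVELS
    brp_levels: tuple[float, ...] = BRP_LEVELS
    growth_times: tuple[float, ...] = GROWTH_TIMES
    cycle_times: tuple[float, ...] = CYCLE_TIMES
    protein_times: tuple[float, ...] = PROTEIN_TIMES
    # noise: density (affine-proportional), percentages and log2
    # fold-changes (constant), counts (affine-proportional)
    density_delta: float = 0.05
    density_sigma: float = 0.1
    pct_delta: float = 2.0
    count_delta: float = 5e3
    count_sigma: float = 0.05
    lfc_delta: float = 0.2

    def __post_init__(self) -> None:
        for name in ("density_delta", "density_sigma", "pct_delta",
                     "count_delta", "count_sigma", "lfc_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray,
                      sd: np.ndarray, max_redraw: int = 100) -> np.ndarray:
    """Gaussian draws redrawn (not clipped) until non-negative."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    out = rng.normal(mean, sd)
    for _ in range(max_redraw):
        neg = out < 0
        if not neg.any():
            break
        out[neg] = rng.normal(mean[neg], sd[neg])
    np.clip(out, 0.0, None, out=out)
    return out


def growth_arms(spec: SyntheticSpec) -> list[tuple[float, float]]:
    """(C_PTX, C_BRP) for control, single agents and the 24 combos."""
    arms = [(0.0, 0.0)]
    arms += [(p, 0.0) for p in spec.ptx_levels]
    arms += [(0.0, b) for b in spec.brp_levels]
    arms += [(p, b) for p in spec.ptx_levels for b in spec.brp_levels]
    return arms


def generate_growth_data(spec: SyntheticSpec,
                         noise: bool = True) -> pd.DataFrame:
    """Proliferation table: time_h, conc_PTX_nM, conc_BRP_nM,
    replicate, density_norm."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cp, cb in growth_arms(spec):
        params = spec.growth
        if not (cp > 0 and cb > 0):
            params = replace(params, psi=1.0)  # interaction needs both
        design = ExposureDesign(C_B=cb, C_P=cp, times=spec.growth_times)
        clean = simulate_growth(params, design)
        for rep in range(1, spec.n_replicates + 1):
            if noise:
                sd = spec.density_delta + spec.density_sigma * clean
                vals = _truncated_normal(rng, clean, sd)
            else:
                vals = clean
            rows.append(pd.DataFrame({
                "time_h": spec.growth_times, "conc_PTX_nM": cp,
                "conc_BRP_nM": cb, "replicate": rep,
                "density_norm": vals}))
    return pd.concat(rows, ignore_index=True)


_CYCLE_ARMS = ("control", "B", "P", "BP")
_PARTITION = ("pct_G0G1", "pct_S", "pct_4N", "pct_polyploid")


def generate_cycle_data(spec: SyntheticSpec,
                        noise: bool = True) -> pd.DataFrame:
    """Flow-cytometry summary table at the reference exposures.

    Columns: arm, conc_PTX_nM, conc_BRP_nM, time_h, replicate, the four
    DNA-content percentages (renormalized to 100), pct_apoptotic, and
    total_cells.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for arm in _CYCLE_ARMS:
        treatment = ARMS[arm]
        sim = simulate_cycle(spec.cycle, spec.network, treatment,
                             times=spec.cycle_times)
        for rep in range(1, spec.n_replicates + 1):
            pct = sim[list(_PARTITION)].to_numpy()
            apo = sim["pct_apoptotic"].to_numpy()
            cnt = sim["total_cells"].to_numpy()
            if noise:
                pct = _truncated_normal(
                    rng, pct, np.full_like(pct, spec.pct_delta))
                apo = _truncated_normal(
                    rng, apo, np.full_like(apo, spec.pct_delta))
                cnt = _truncated_normal(
                    rng, cnt, spec.count_delta + spec.count_sigma * cnt)
            pct = 100.0 * pct / pct.sum(axis=1, keepdims=True)
            df = pd.DataFrame(pct, columns=list(_PARTITION))
            df.insert(0, "arm", arm)
            df.insert(1, "conc_PTX_nM", treatment.C_P)
            df.insert(2, "conc_BRP_nM", treatment.C_B)
            df.insert(3, "time_h", sim.index.to_numpy())
            df.insert(4, "replicate", rep)
            df["pct_apoptotic"] = apo
            df["total_cells"] = cnt
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


def generate_protein_profiles(spec: SyntheticSpec,
                              noise: bool = True) -> pd.DataFrame:
    """log2 fold-change profiles: protein, arm, time_h, replicate,
    value; arms B, P and BP at the reference exposures."""
    rng = np.random.default_rng(spec.seed + 2)
    rows = []
    for arm in ("B", "P", "BP"):
        traj = simulate_network(spec.network, ARMS[arm],
                                np.asarray(spec.protein_times), log2=True)
        for rep in range(1, spec.n_replicates + 1):
            long = traj.reset_index().melt(
                id_vars="time_h", var_name="protein", value_name="value")
            if noise:
                long["value"] += rng.normal(0.0, spec.lfc_delta,
                                            size=len(long))
            long["arm"] = arm
            long["replicate"] = rep
            rows.append(long[["protein", "arm", "time_h",
                              "replicate", "value"]])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# full-size clustering matrix

# archetype log2 fold-change builders on the (arm, time) grid; `u` is
# time scaled to [0, 1].  Up- and down-regulated patterns are roughly
# balanced in mass so treatment does not shift whole-sample intensity
# distributions (quantile normalization assumes that).
_ARCHETYPES = (
    # sustained induction, all arms
    lambda u, arm: 1.6 * (1 - np.exp(-4 * u)),
    # sustained repression, all arms
    lambda u, arm: -1.6 * (1 - np.exp(-4 * u)),
    # transient pulse up, all arms
    lambda u, arm: 1.8 * np.exp(-((u - 0.25) / 0.2) ** 2),
    # transient dip down, all arms
    lambda u, arm: -1.8 * np.exp(-((u - 0.25) / 0.2) ** 2),
    # late induction, combination only
    lambda u, arm: (1.8 * u**2 if arm == "BP" else 0.0 * u),
    # late repression, combination only
    lambda u, arm: (-1.8 * u**2 if arm == "BP" else 0.0 * u),
    # BRP-driven induction (B and BP)
    lambda u, arm: (1.5 * (1 - np.exp(-6 * u))
                    if arm in ("B", "BP") else 0.0 * u),
    # PTX-driven repression (P and BP)
    lambda u, arm: (-1.5 * (1 - np.exp(-6 * u))
                    if arm in ("P", "BP") else 0.0 * u),
    # PTX-driven induction (P and BP): the spindle/kinetochore pattern
    lambda u, arm: (1.5 * np.sqrt(u) if arm in ("P", "BP") else 0.0 * u),
)


def _draw_sizes(rng: np.random.Generator, n_proteins: int,
                n_groups: int, lo: int = 30, hi: int = 508) -> np.ndarray:
    """Group sizes in [lo, hi] summing to n_proteins."""
    if not (n_groups * lo <= n_proteins <= n_groups * hi):
        raise ValueError("n_proteins incompatible with size range")
    sizes = rng.integers(lo, hi + 1, size=n_groups)
    # iterative repair of the total within the box constraints
    for _ in range(10_000):
        diff = n_proteins - int(sizes.sum())
        if diff == 0:
            break
        i = rng.integers(n_groups)
        step = np.clip(diff, -(sizes[i] - lo), hi - sizes[i])
        sizes[i] += step
    if sizes.sum() != n_proteins:
        raise RuntimeError("size repair failed")
    return sizes


def generate_cluster_matrix(
    spec: SyntheticSpec,
    n_proteins: int = 3325,
    n_archetypes: int = 9,
    noise_sd_log2: float = 0.3,
    batch_distortion: bool = True,
) -> tuple[ProteomicsMatrix, pd.Series]:
    """Protein x sample intensity matrix with planted temporal clusters.

    The design mirrors the two-experiment structure of large label-free
    studies: the drug arms ({B, P, BP} x {6, 24, 48, 72} h x replicates)
    come from one batch, while the vehicle-control time course was
    quantified in a separate batch.  Every control-matched fold-change
    therefore crosses the batch boundary.  With ``batch_distortion`` the
    baseline batch sits on a different, mildly compressive intensity
    scale and every sample carries a random loading factor; both are
    rank-preserving, so quantile normalization removes them, but raw
    cross-batch ratios are biased and time-scrambled without it.
    Returns the matrix and the ground-truth archetype label per protein.
    """
    if n_archetypes > len(_ARCHETYPES):
        raise ValueError(
            f"at most {len(_ARCHETYPES)} archetypes available")
    if n_archetypes > n_proteins:
        raise ValueError("more archetypes than proteins")
    rng = np.random.default_rng(spec.seed + 3)
    times = np.asarray(spec.protein_times, float)
    u = (times - times.min()) / (times.max() - times.min())
    arms = ("control", "B", "P", "BP")
    n_rep = spec.n_replicates

    sizes = _draw_sizes(rng, n_proteins, n_archetypes)
    labels = np.repeat(np.arange(n_archetypes), sizes)
    protein_ids = [f"PROT{i:05d}" for i in range(n_proteins)]

    # per-protein baseline intensity (log-normal across the proteome;
    # the wide spread mirrors the dynamic range of label-free MS)
    baseline = np.exp(rng.normal(np.log(1e7), 1.5, size=n_proteins))

    sample_names, meta_rows, cols = [], [], []
    for arm in arms:
        batch = "baseline" if arm == "control" else "treatment"
        for rep in range(1, n_rep + 1):
            for t_i, t in enumerate(times):
                name = f"{arm}_t{int(t)}_r{rep}"
                sample_names.append(name)
                meta_rows.append((arm, t, rep, batch))
                lfc = np.zeros(n_proteins)
                if arm != "control":
                    for a in range(n_archetypes):
                        shape = _ARCHETYPES[a](u, arm)
                        val = (shape[t_i] if np.ndim(shape) else shape)
                        lfc[labels == a] = val
                noisy = lfc + rng.normal(0.0, noise_sd_log2, n_proteins)
                col = baseline * 2.0**noisy
                if batch_distortion:
                    # per-sample loading/instrument-drift factor
                    col = col * np.exp(rng.normal(0.0, 0.4))
                    if batch == "baseline":
                        # the earlier experiment's saturating detector
                        # response: rank-preserving, but the log-offset
                        # it adds depends on protein abundance, so raw
                        # cross-batch ratios are biased per protein
                        K = np.median(baseline) * 2.0
                        col = 3e8 * col / (col + K)
                cols.append(col)
    values = pd.DataFrame(
        np.column_stack(cols), index=protein_ids, columns=sample_names)
    meta = pd.DataFrame(
        meta_rows, index=sample_names,
        columns=["arm", "time_h", "replicate", "batch"])
    matrix = ProteomicsMatrix(values, meta)
    truth = pd.Series(labels, index=protein_ids, name="archetype")
    return matrix, truth
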