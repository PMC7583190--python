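"""End-to-end orchestration: generate -> cluster -> fit -> extrapolate.

Each stage reads the previous stage's files from the run directory and
writes its own outputs there, so a run directory is a self-contained,
reproducible record: ``manifest.json`` stores the seed, configuration
hash and package version; every fit writes a parameter table (text) and
a machine-readable CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cycle import fit_cycle, plate_context, simulate_cycle
from .estimation import FitResult
from .growth import fit_growth
from .network import Treatment, fit_network
from .proteomics import (
    cluster_temporal,
    log2_fold_change,
    quantile_normalize,
    ProteomicsMatrix,
)
from .synthetic import (
    SyntheticSpec,
    generate_cluster_matrix,
    generate_cycle_data,
    generate_growth_data,
    generate_protein_profiles,
    growth_arms,
)

__all__ = ["RunConfig", "run_pipeline", "report", "predict_grid"]

STAGES = ("generate", "cluster", "fit_growth", "fit_network",
          "fit_cycle", "predict_grid", "report")


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    plate: str = "well6"
    normalization: str = "vehicle_matched"
    n_transit: int | str = 3
    n_starts: int = 2
    cluster_k: tuple[int, int] = (2, 12)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(self).items()},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_fit(out: Path, name: str, fits: list[FitResult]) -> None:
    (out / f"{name}_report.txt").write_text(
        "\n\n".join(fr.report_text() for fr in fits) + "\n")
    rows = []
    for fr in fits:
        for k, v in fr.estimates.items():
            rows.append((fr.name, k, v, fr.cv_percent.get(k), "free"))
        for k, v in fr.fixed.items():
            rows.append((fr.name, k, v, None, "fixed"))
    pd.DataFrame(rows, columns=["stage", "parameter", "value",
                                "cv_percent", "status"]).to_csv(
        out / f"{name}_parameters.csv", index=False)


def predict_grid(spec: SyntheticSpec, config: RunConfig,
                 ) -> tuple[pd.DataFrame, float, float]:
    """Simulated-vs-observed total counts over the combination grid.

    For each of the 24 combination arms the cell-cycle model (96-well
    context, drug effects extrapolated to the arm's concentrations)
    predicts relative cell counts over the growth time grid; "observed"
    values are the same model's output perturbed with the count error
    model.  Returns the table plus the regression slope and R^2 of
    observed on simulated.
    """
    params = plate_context(spec.cycle, config.plate if config.plate !=
                           "well6" else "well96")
    rng = np.random.default_rng(spec.seed + 17)
    rows = []
    for cp, cb in growth_arms(spec):
        if not (cp > 0 and cb > 0):
            continue
        tr = Treatment(has_B=cb > 0, has_P=cp > 0, C_B=cb, C_P=cp)
        sim = simulate_cycle(params, spec.network, tr,
                             times=(0.0,) + spec.growth_times,
                             extrapolate=True)
        rel = sim["total_cells"] / sim["total_cells"].iloc[0]
        for t in spec.growth_times:
            pred = rel.loc[t]
            sd = (spec.density_delta + spec.density_sigma * pred)
            obs = max(float(rng.normal(pred, sd)), 0.0)
            rows.append((cp, cb, t, pred, obs))
    table = pd.DataFrame(rows, columns=["conc_PTX_nM", "conc_BRP_nM",
                                        "time_h", "simulated",
                                        "observed"])
    x = table.simulated.to_numpy()
    y = table.observed.to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return table, float(slope), r2


def run_pipeline(config: RunConfig,
                 spec: SyntheticSpec | None = None) -> Path:
    """Execute the enabled stages in dependency order."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or SyntheticSpec(seed=config.seed)
    stages = [s for s in STAGES if s in config.stages]

    deps = {"cluster": "generate", "fit_growth": "generate",
            "fit_network": "generate", "fit_cycle": "fit_network"}
    done: set[str] = set()

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    summary: dict[str, object] = {}
    for stage in stages:
        need = deps.get(stage)
        if need and need not in done and not _stage_outputs_exist(
                out, need):
            raise RuntimeError(
                f"stage {stage!r} requires outputs of {need!r}, which "
                "is neither enabled nor already present")
        if stage == "generate":
            generate_growth_data(spec).to_csv(
                out / "growth.csv", index=False)
            generate_cycle_data(spec).to_csv(
                out / "cycle.csv", index=False)
            generate_protein_profiles(spec).to_csv(
                out / "proteins.tsv", sep="\t", index=False)
            matrix, truth = generate_cluster_matrix(spec)
            matrix.values.to_csv(out / "matrix.tsv", sep="\t")
            matrix.sample_meta.to_csv(out / "matrix_meta.tsv", sep="\t")
            truth.to_csv(out / "matrix_truth.tsv", sep="\t")
            with open(out / "ground_truth.yaml", "w") as fh:
                yaml.safe_dump(
                    {"growth": dataclasses.asdict(spec.growth),
                     "cycle": dataclasses.asdict(spec.cycle),
                     "seed": spec.seed}, fh)
        elif stage == "cluster":
            values = pd.read_csv(out / "matrix.tsv", sep="\t",
                                 index_col=0)
            meta = pd.read_csv(out / "matrix_meta.tsv", sep="\t",
                               index_col=0)
            matrix = ProteomicsMatrix(values, meta)
            lfc = log2_fold_change(quantile_normalize(matrix),
                                   mode=config.normalization)
            res = cluster_temporal(
                lfc, k_range=range(config.cluster_k[0],
                                   config.cluster_k[1] + 1),
                seed=config.seed)
            res.assignments.to_csv(out / "cluster_assignments.tsv",
                                   sep="\t")
            res.centroids.to_csv(out / "cluster_centroids.csv")
            res.sizes().to_csv(out / "cluster_sizes.csv")
            summary["cluster_k"] = res.k
            summary["cluster_sizes"] = res.sizes().to_dict()
        elif stage == "fit_growth":
            data = pd.read_csv(out / "growth.csv")
            gfit = fit_growth(data, n_transit=config.n_transit,
                              seed=config.seed,
                              n_starts=config.n_starts)
            _write_fit(out, "growth", gfit.stages)
            (out / "growth_summary.txt").write_text(
                gfit.report_text() + "\n")
            summary["psi"] = gfit.psi
            summary["psi_ci"] = list(gfit.psi_ci)
            summary["n_transit"] = gfit.n_transit
        elif stage == "fit_network":
            prof = pd.read_csv(out / "proteins.tsv", sep="\t")
            nfits = fit_network(prof, seed=config.seed,
                                n_starts=config.n_starts)
            _write_fit(out, "network", nfits)
        elif stage == "fit_cycle":
            cyc = pd.read_csv(out / "cycle.csv")
            cfits = fit_cycle(cyc[cyc.arm == "control"], None,
                              seed=config.seed,
                              n_starts=config.n_starts)
            _write_fit(out, "cycle", cfits)
        elif stage == "predict_grid":
            table, slope, r2 = predict_grid(spec, config)
            table.to_csv(out / "predict_grid.csv", index=False)
            summary["grid_slope"] = slope
            summary["grid_r2"] = r2
        elif stage == "report":
            report(out, summary)
        done.add(stage)
    return out


def _stage_outputs_exist(out: Path, stage: str) -> bool:
    markers = {
        "generate": "growth.csv",
        "fit_network": "network_parameters.csv",
    }
    m = markers.get(stage)
    return m is not None and (out / m).exists()


def report(run_dir: Path, summary: dict | None = None) -> Path:
    """Write a human-readable summary of whatever the run produced."""
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError(f"{run_dir} is not a pipeline run "
                                "directory (no manifest.json)")
    summary = summary or {}
    lines = ["# Run summary", ""]
    manifest = json.loads((run_dir / "manifest.json").read_text())
    lines.append(f"package version {manifest['version']}, "
                 f"seed {manifest['seed']}, "
                 f"config {manifest['config_hash']}")
    lines.append("")
    gaps = []
    for name, fname in (("growth model", "growth_parameters.csv"),
                        ("protein network", "network_parameters.csv"),
                        ("cell cycle", "cycle_parameters.csv")):
        f = run_dir / fname
        if f.exists():
            lines.append(f"## {name} parameters")
            lines.append(pd.read_csv(f).to_string(index=False))
            lines.append("")
        else:
            gaps.append(name)
    if "psi" in summary:
        lo, hi = summary["psi_ci"]
        lines.append(
            f"interaction term psi = {summary['psi']:.3f} "
            f"(95% CI {lo:.3f}-{hi:.3f}); psi < 1 indicates synergy")
    if "cluster_k" in summary:
        lines.append(f"temporal clusters: k = {summary['cluster_k']}, "
                     f"sizes {summary['cluster_sizes']}")
    if "grid_slope" in summary:
        lines.append(
            f"combination-grid check: observed vs simulated slope = "
            f"{summary['grid_slope']:.3f}, R^2 = "
            f"{summary['grid_r2']:.3f}")
    if gaps:
        lines.append("")
        lines.append("missing sections (stages not run): "
                     + ", ".join(gaps))
    text = "\n".join(lines) + "\n"
    path = run_dir / "summary.md"
    path.write_text(text)
    return path
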