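"""Proteomics preprocessing and temporal clustering.

Pipeline: quantile-normalize intensities across the pooled samples (to
remove between-batch distribution shifts), compute log2 fold-changes of
each treatment arm against the time-matched vehicle control, and cluster
the resulting temporal profiles with seeded k-means.  The cluster count
is chosen by the maximum member-to-centroid deviation: scanning k upward,
the selected k is the smallest one beyond which adding another cluster no
longer buys a substantial reduction in that maximum deviation (pure
minimization would always favor the largest k, since the criterion is
monotone in k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ProteomicsMatrix",
    "ClusterResult",
    "quantile_normalize",
    "log2_fold_change",
    "cluster_temporal",
    "representative_profile",
]


@dataclass
class ProteomicsMatrix:
    """Protein x sample intensity table with sample annotations.

    ``values``: DataFrame indexed by protein id, one column per sample.
    ``sample_meta``: DataFrame indexed by the same sample names with
    columns arm (control|B|P|BP), time_h, replicate, batch.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.sample_meta.index):
            if set(self.values.columns) != set(self.sample_meta.index):
                raise ValueError("sample metadata does not match columns")
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        need = {"arm", "time_h", "replicate", "batch"}
        if not need.issubset(self.sample_meta.columns):
            raise ValueError(f"sample_meta must have columns {sorted(need)}")
        if self.values.isna().any().any():
            raise ValueError("matrix contains missing values")
        if (self.values <= 0).any().any():
            raise ValueError("intensities must be positive")

    def drop_nonfinite(self) -> tuple["ProteomicsMatrix", list[str]]:
        """Drop proteins with any non-finite value; return the manifest."""
        finite = np.isfinite(self.values).all(axis=1)
        dropped = list(self.values.index[~finite])
        return (ProteomicsMatrix(self.values.loc[finite],
                                 self.sample_meta), dropped)


def quantile_normalize(matrix: ProteomicsMatrix) -> ProteomicsMatrix:
    """Map every sample onto the mean-quantile reference distribution.

    After normalization each sample's sorted values equal the across-
    sample mean of sorted values; within-sample ranks are preserved and
    ties receive the average of their reference quantiles.  Idempotent.
    """
    v = matrix.values
    if v.shape[1] < 2:
        raise ValueError("need at least two samples")
    arr = v.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0)
    reference = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = reference
    # average reference values over ties, per sample
    normed = pd.DataFrame(out, index=v.index, columns=v.columns)
    for col in normed.columns:
        col_in = v[col]
        if col_in.duplicated().any():
            normed[col] = normed.groupby(col_in.to_numpy())[col] \
                .transform("mean")
    return ProteomicsMatrix(normed, matrix.sample_meta)


def log2_fold_change(matrix: ProteomicsMatrix,
                     mode: str = "vehicle_matched") -> pd.DataFrame:
    """Per-protein log2 fold-change profiles for each treatment arm.

    ``vehicle_matched`` (default): log2(mean treated / mean control at
    the same time point) -- isolates the drug effect from culture-age
    effects.  ``t0``: each arm normalized to its own earliest time point
    instead.  Returns a long table with columns protein, arm, time_h,
    value.
    """
    meta = matrix.sample_meta
    v = matrix.values
    means = {}
    for (arm, t), cols in meta.groupby(["arm", "time_h"]).groups.items():
        m = v[list(cols)].mean(axis=1)
        if (m <= 0).any():
            bad = m.index[m <= 0][0]
            raise ValueError(
                f"non-positive mean for protein {bad!r} in arm "
                f"{arm!r} at t={t}")
        means[(arm, t)] = m
    arms = sorted({a for a, _ in means if a != "control"})
    times = sorted({t for _, t in means})
    records = []
    for arm in arms:
        for t in times:
            if (arm, t) not in means:
                continue
            if mode == "vehicle_matched":
                if ("control", t) not in means:
                    raise ValueError(f"no control samples at t={t}")
                ref = means[("control", t)]
            elif mode == "t0":
                t0 = min(tt for a, tt in means if a == arm)
                ref = means[(arm, t0)]
            else:
                raise ValueError(f"unknown mode {mode!r}")
            lfc = np.log2(means[(arm, t)] / ref)
            records.append(pd.DataFrame({
                "protein": lfc.index, "arm": arm, "time_h": t,
                "value": lfc.to_numpy()}))
    return pd.concat(records, ignore_index=True)


def profiles_to_wide(profiles: pd.DataFrame) -> pd.DataFrame:
    """Long fold-change table -> one row per protein (arm x time grid)."""
    wide = profiles.pivot_table(index="protein", columns=["arm", "time_h"],
                                values="value")
    if wide.isna().any().any():
        wide = wide.dropna()
    return wide


@dataclass
class ClusterResult:
    """k-means clustering of temporal profiles."""

    k: int
    assignments: pd.Series          # protein -> cluster id
    centroids: pd.DataFrame         # cluster id x profile grid
    max_deviation: pd.Series        # per-cluster max member distance
    profiles: pd.DataFrame = field(default_factory=pd.DataFrame)
    scan: dict[int, float] = field(default_factory=dict)

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def _fit_kmeans(X: np.ndarray, k: int, seed: int,
                n_restarts: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(X)
    return km


def _max_deviation(X: np.ndarray, km: KMeans) -> float:
    d = np.linalg.norm(X - km.cluster_centers_[km.labels_], axis=1)
    return float(d.max())


def cluster_temporal(profiles: pd.DataFrame,
                     k_range: Sequence[int] | int = range(2, 16),
                     seed: int = 0, n_restarts: int = 10,
                     rel_tol: float = 0.15) -> ClusterResult:
    """Cluster temporal profiles and select the cluster count.

    ``profiles`` is either the long fold-change table or an already-wide
    protein x timegrid frame.  For each k the maximum member-centroid
    Euclidean deviation is computed and the smallest k whose deviation
    comes within ``rel_tol`` of the lowest one seen is selected (the
    criterion keeps shrinking slowly as clusters split, so near-ties
    resolve toward the more parsimonious k).  A fixed integer
    ``k_range`` skips selection.  Same seed, same result.
    """
    if {"protein", "arm", "time_h", "value"}.issubset(profiles.columns):
        wide = profiles_to_wide(profiles)
    else:
        wide = profiles
    X = wide.to_numpy(dtype=float)
    n = X.shape[0]

    if isinstance(k_range, int):
        ks = [k_range]
    else:
        ks = sorted(k_range)
    if ks[-1] > n:
        raise ValueError(f"k={ks[-1]} exceeds {n} profiles")

    fits: dict[int, KMeans] = {}
    devs: dict[int, float] = {}
    for k in ks:
        km = _fit_kmeans(X, k, seed, n_restarts)
        fits[k] = km
        devs[k] = _max_deviation(X, km)

    if len(ks) == 1:
        k_sel = ks[0]
    else:
        best = min(devs.values())
        k_sel = next(k for k in ks
                     if devs[k] <= (1.0 + rel_tol) * best)

    km = fits[k_sel]
    assignments = pd.Series(km.labels_, index=wide.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=wide.columns)
    centroids.index.name = "cluster"
    dist = np.linalg.norm(X - km.cluster_centers_[km.labels_], axis=1)
    max_dev = pd.Series(dist).groupby(km.labels_).max()
    max_dev.index.name = "cluster"
    return ClusterResult(k=k_sel, assignments=assignments,
                         centroids=centroids, max_deviation=max_dev,
                         profiles=wide, scan=devs)


def representative_profile(cluster: ClusterResult, cluster_id: int,
                           named_member: str | None = None) -> pd.Series:
    """A cluster's representative: its centroid, or a named member.

    The centroid is the arithmetic mean profile of the members.  Naming
    a member (e.g. ELYS for the kinetochore/spindle group) returns that
    member's own profile; it must belong to the cluster.
    """
    if cluster_id not in cluster.centroids.index:
        raise KeyError(f"no cluster {cluster_id}")
    if named_member is None:
        return cluster.centroids.loc[cluster_id]
    if named_member not in cluster.assignments.index:
        raise KeyError(f"unknown protein {named_member!r}")
    if cluster.assignments[named_member] != cluster_id:
        raise ValueError(
            f"{named_member!r} belongs to cluster "
            f"{cluster.assignments[named_member]}, not {cluster_id}")
    return cluster.profiles.loc[named_member]
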