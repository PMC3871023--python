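"""Replicate-reliability filtering, z-scoring and k-means profile clustering.

The expression matrix (feature x sample NPKMs) is reduced to features with
reproducible replicates: a per-sampling-point one-sample t-test against
zero must reach P < 0.15 in at least three of the five points, and the
feature's maximal NPKM must exceed 10.  Replicate means per point are then
z-scored per feature and clustered by Euclidean k-means; the number of
clusters is chosen by figure-of-merit (FOM) analysis, the
leave-one-condition-out estimate of a clustering's predictive power.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .genome_model import SAMPLING_POINTS, SampleSheet

logger = logging.getLogger("regulome")


def _fit_kmeans(km: KMeans, X: np.ndarray) -> np.ndarray:
    # duplicate profiles can collapse clusters; that is fine here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return km.fit_predict(X)


# ---------------------------------------------------------------------------
# reliability filter
# ---------------------------------------------------------------------------

def _one_sample_p(values: np.ndarray) -> float:
    """Two-sided one-sample t-test P against 0; degenerate replicates
    (zero variance) give P=0 for a nonzero mean and P=1 otherwise."""
    if len(values) < 2:
        return math.nan
    if np.ptp(values) == 0:
        return 0.0 if values[0] != 0 else 1.0
    return float(stats.ttest_1samp(values, 0.0).pvalue)


def reliability_filter(npkm: pd.DataFrame, sheet: SampleSheet,
                       p_thresh: float = 0.15, min_points: int = 3,
                       min_npkm: float = 10.0,
                       test: str = "one_sample") -> list[str]:
    """Feature ids whose replicates are reliable enough for clustering.

    A feature is retained iff its per-point replicate t-test reaches
    ``P < p_thresh`` in at least ``min_points`` sampling points and its
    maximal NPKM over all samples exceeds ``min_npkm``.  ``test`` is
    ``one_sample`` (replicates against zero, the default consistency
    screen) or ``welch`` (each point's replicates against all others,
    a between-point alternative).
    """
    if test not in ("one_sample", "welch"):
        raise ValueError(f"unknown test {test!r}")
    point_cols = {p: [sid for sid in sheet.ids_for(p, "rnaseq")
                      if sid in npkm.columns]
                  for p in SAMPLING_POINTS}
    for p, cols in point_cols.items():
        if 0 < len(cols) < 2:
            logger.warning("sampling point %s has <2 replicates; it cannot "
                           "contribute to the reliability count", p)
    retained = []
    for fid, row in npkm.iterrows():
        if row.max() <= min_npkm:
            continue
        n_good = 0
        for p, cols in point_cols.items():
            if len(cols) < 2:
                continue
            vals = row[cols].to_numpy(dtype=float)
            if test == "one_sample":
                pval = _one_sample_p(vals)
            else:
                others = row[[c for cs in point_cols.values() for c in cs
                              if c not in cols]].to_numpy(dtype=float)
                with np.errstate(all="ignore"):
                    pval = float(stats.ttest_ind(
                        vals, others, equal_var=False).pvalue)
            if not math.isnan(pval) and pval < p_thresh:
                n_good += 1
        if n_good >= min_points:
            retained.append(str(fid))
    return retained


def point_means(npkm: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Replicate means per sampling point (RNA-Seq samples only)."""
    data = {}
    for p in SAMPLING_POINTS:
        cols = [sid for sid in sheet.ids_for(p, "rnaseq")
                if sid in npkm.columns]
        if cols:
            data[p] = npkm[cols].mean(axis=1)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

def zscore_profiles(means: pd.DataFrame) -> pd.DataFrame:
    """Per-feature standardization to mean 0, sd 1 (population sd).

    Zero-variance rows carry no profile shape and are dropped with a
    warning.  Idempotent on already-standardized rows.
    """
    mat = means.to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    flat = (sd[:, 0] == 0)
    if flat.any():
        logger.warning("dropping %d zero-variance profile(s): %s",
                       flat.sum(), list(means.index[flat]))
    keep = ~flat
    z = (mat[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=means.index[keep], columns=means.columns)


# ---------------------------------------------------------------------------
# figure of merit
# ---------------------------------------------------------------------------

@dataclass
class FomResult:
    curve: dict[int, float]
    selected_k: int
    elbow_threshold: float


def figure_of_merit(profiles: pd.DataFrame, k_range: Sequence[int],
                    seed: int = 0, restarts: int = 10,
                    elbow_threshold: float = 0.10) -> FomResult:
    """Leave-one-condition-out FOM curve and elbow-selected k.

    For each k and each left-out condition, features are clustered on the
    remaining conditions and the root-mean-square deviation of the
    left-out values from their cluster means is computed, adjusted by
    sqrt(n/(n-k)); FOM(k) sums the conditions.  The selected k is the
    largest one whose relative improvement over its predecessor still
    reaches the elbow threshold - beyond it the curve has flattened and
    extra clusters no longer buy predictive power.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = len(profiles)
    if not ks or ks[-1] >= n:
        raise ValueError(f"k_range up to {ks[-1] if ks else '-'} needs more "
                         f"than {n} features")
    X = profiles.sort_index().to_numpy(dtype=float)
    curve: dict[int, float] = {}
    for k in ks:
        total = 0.0
        for c in range(X.shape[1]):
            rest = np.delete(X, c, axis=1)
            if k == 1:
                labels = np.zeros(n, dtype=int)
            else:
                km = KMeans(n_clusters=k, n_init=restarts,
                            random_state=_stable_seed(seed, k, c))
                labels = _fit_kmeans(km, rest)
            dev = 0.0
            for lab in np.unique(labels):
                vals = X[labels == lab, c]
                dev += float(((vals - vals.mean()) ** 2).sum())
            adj = math.sqrt(n / (n - k)) if n > k else 1.0
            total += math.sqrt(dev / n) * adj
        curve[k] = total
    selected = ks[0]
    for prev, k in zip(ks, ks[1:]):
        if curve[prev] <= 0:
            break
        improvement = (curve[prev] - curve[k]) / curve[prev]
        if improvement >= elbow_threshold:
            selected = k
    return FomResult(curve, selected, elbow_threshold)


def _stable_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    k: int
    labels: pd.Series  # feature -> cluster label in 1..k
    centroids: pd.DataFrame  # cluster x condition
    inertia: float
    seed: int
    fom: FomResult | None = None


def kmeans_cluster(profiles: pd.DataFrame, k: int, seed: int = 0,
                   restarts: int = 25) -> ClusteringResult:
    """Euclidean k-means, best of ``restarts`` initializations.

    Features are processed in sorted-id order so the labeling is invariant
    to the input row order given the same seed.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds feature count {len(profiles)}")
    sorted_profiles = profiles.sort_index()
    X = sorted_profiles.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=restarts,
                random_state=_stable_seed(seed, k))
    raw = _fit_kmeans(km, X)
    labels = pd.Series(raw + 1, index=sorted_profiles.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_,
                             index=range(1, k + 1),
                             columns=sorted_profiles.columns)
    return ClusteringResult(k, labels, centroids, float(km.inertia_), seed)


def cluster_profiles(profiles: pd.DataFrame, seed: int = 0,
                     k: int | None = None,
                     k_range: Sequence[int] | None = None,
                     fom_restarts: int = 10, kmeans_restarts: int = 25,
                     elbow_threshold: float = 0.10) -> ClusteringResult:
    """FOM-select k (unless given) and cluster."""
    fom = None
    if k is None:
        if k_range is None:
            k_range = range(1, min(11, len(profiles)))
        fom = figure_of_merit(profiles, k_range, seed, fom_restarts,
                              elbow_threshold)
        k = fom.selected_k
    result = kmeans_cluster(profiles, k, seed, kmeans_restarts)
    result.fom = fom
    return result


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_clusters(result: ClusteringResult, path: str | Path) -> None:
    result.labels.rename_axis("feature").to_frame().to_csv(path, sep="\t")


def write_centroids(result: ClusteringResult, path: str | Path) -> None:
    result.centroids.rename_axis("cluster").to_csv(
        path, sep="\t", float_format="%.6f")


def write_fom(fom: FomResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tfom\tselected\n")
        for k in sorted(fom.curve):
            fh.write(f"{k}\t{fom.curve[k]:.6f}\t"
                     f"{int(k == fom.selected_k)}\n")


def plot_cluster_profiles(profiles: pd.DataFrame, result: ClusteringResult,
                          path: str | Path) -> None:
    """Per-cluster z-score profile panels over sampling points I-V."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = result.k
    ncol = min(4, k)
    nrow = (k + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow),
                             squeeze=False, sharey=True)
    x = np.arange(profiles.shape[1])
    for lab in range(1, k + 1):
        ax = axes[(lab - 1) // ncol][(lab - 1) % ncol]
        members = result.labels[result.labels == lab].index
        for fid in members:
            ax.plot(x, profiles.loc[fid], color="grey", alpha=0.4, lw=0.8)
        ax.plot(x, result.centroids.loc[lab], color="crimson", lw=2)
        ax.set_title(f"cluster {lab} (n={len(members)})", fontsize=9)
        ax.set_xticks(x, profiles.columns)
    for j in range(k, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
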