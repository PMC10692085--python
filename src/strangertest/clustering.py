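"""Coping-style clustering in movement space.

K-means (Lloyd's algorithm, k-means++ init, best of ``n_init`` restarts)
on the movement-space embedding vectors, with the elbow method choosing
the number of clusters, a single-pass medoid-distance outlier rule run
before clustering, cluster-vs-expert-score cross-tabulation, and a
normalized 2-D t-SNE projection for plotting.

Because the embedding vectors are aligned and of equal length,
time-series k-means reduces to Euclidean k-means; no elastic (DTW)
metric is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE


@dataclass
class ClusteringResult:
    """Output of the full clustering stage."""

    k_selected: int
    assignments: dict[str, int]
    centroids: np.ndarray
    inertia_curve: dict[int, float]
    excluded_outliers: list[str] = field(default_factory=list)
    seed: int = 0


def kmeans_fit(
    Z: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Euclidean k-means: (assignments, centroids, inertia)."""
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("embeddings contain non-finite values")
    n = Z.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in [1, n={n}]")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(Z)
    return labels, km.cluster_centers_, float(km.inertia_)


def elbow_select(inertia_curve: dict[int, float], tol: float = 1e-6) -> int:
    """Elbow (knee) point of the inertia-vs-k curve.

    Both axes are min-max normalized; the selected k maximizes the
    perpendicular distance to the chord joining the first and last
    points.  A curve with no elbow (max distance < tol) yields k = 1.
    Invariant under affine rescaling of the inertia axis.
    """
    ks = np.array(sorted(inertia_curve))
    if len(ks) < 3:
        raise ValueError("need inertia values for at least 3 values of k")
    y = np.array([inertia_curve[k] for k in ks], dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("inertia curve contains non-finite values")
    if np.any(np.diff(y) > 1e-9 * max(abs(y).max(), 1.0)):
        warnings.warn("inertia curve is not non-increasing in k", stacklevel=2)
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    span = y[0] - y[-1]
    if abs(span) < 1e-30:
        return int(ks[0])
    yn = (y - y[-1]) / span
    # chord runs from (0, 1) to (1, 0); distance = |x + y - 1| / sqrt(2)
    dist = np.abs(x + yn - 1.0) / np.sqrt(2.0)
    if dist.max() < tol:
        return int(ks[0])
    return int(ks[int(np.argmax(dist))])


def detect_outliers(
    Z: np.ndarray, trial_ids: list[str] | None = None, mad_factor: float = 3.5
) -> list[str]:
    """Medoid-distance MAD rule, single pass before clustering.

    Excludes points whose Euclidean distance to the embedding medoid
    exceeds ``median + mad_factor * MAD`` of those distances.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points for outlier detection")
    if trial_ids is None:
        trial_ids = [f"trial{i:03d}" for i in range(n)]
    pair = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=2)
    medoid = int(np.argmin(pair.sum(axis=1)))
    d = pair[medoid]
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    cut = med + mad_factor * mad
    return [trial_ids[i] for i in np.flatnonzero(d > cut)]


def cluster_embeddings(
    Z: np.ndarray,
    trial_ids: list[str],
    k_max: int = 8,
    seed: int = 0,
    n_init: int = 10,
    exclude_outliers: bool = True,
) -> ClusteringResult:
    """Outlier exclusion, inertia curve over k = 1..k_max, elbow, final fit."""
    Z = np.asarray(Z, dtype=float)
    excluded = detect_outliers(Z, trial_ids) if exclude_outliers else []
    keep = [i for i, t in enumerate(trial_ids) if t not in set(excluded)]
    Zk = Z[keep]
    kept_ids = [trial_ids[i] for i in keep]
    k_max = min(k_max, len(kept_ids))
    curve = {}
    fits = {}
    for k in range(1, k_max + 1):
        labels, cents, inertia = kmeans_fit(Zk, k, seed=seed, n_init=n_init)
        curve[k] = inertia
        fits[k] = (labels, cents)
    k_star = elbow_select(curve)
    labels, cents = fits[k_star]
    return ClusteringResult(
        k_selected=k_star,
        assignments=dict(zip(kept_ids, (int(c) for c in labels))),
        centroids=cents,
        inertia_curve=curve,
        excluded_outliers=excluded,
        seed=seed,
    )


def crosstab(assignments: dict[str, int], labels: dict[str, str]) -> pd.DataFrame:
    """Label-by-cluster contingency table with margins.

    Rows are expert labels, columns cluster indices; the ``Total``
    row/column hold the margins.
    """
    if set(assignments) != set(labels):
        missing = set(assignments) ^ set(labels)
        raise ValueError(f"trial id mismatch between assignments and labels: {sorted(missing)}")
    ids = sorted(assignments)
    df = pd.DataFrame({"label": [labels[t] for t in ids],
                       "cluster": [assignments[t] for t in ids]})
    table = pd.crosstab(df["label"], df["cluster"], margins=True, margins_name="Total")
    return table


def project_2d(Z: np.ndarray, seed: int = 0) -> np.ndarray:
    """t-SNE to 2-D, min-max normalized to [0, 1] per axis."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points for a 2-D projection")
    perplexity = min(30.0, (n - 1) / 3.0)
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    xy = ts.fit_transform(Z)
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    span = np.where(hi - lo < 1e-12, 1.0, hi - lo)
    return (xy - lo) / span
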