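"""Day-type discovery by K-means and strike-association analysis.

Days are clustered on standardised airfield feature vectors (strike
information is never part of the feature matrix).  Clustering tendency is
screened with the Hopkins statistic, K is chosen by elbow / average
silhouette / gap statistic, and solutions are validated with silhouette
widths and the Dunn index.  Whether a day type is associated with
collisions is decided by comparing each cluster's bootstrap confidence
interval for the daily strike probability with the overall interval:
non-overlap flags a strike-associated day type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from ._rng import substream, derive_seed

__all__ = [
    "ClusterModel",
    "ValidationReport",
    "ClusterAssociation",
    "standardise",
    "hopkins",
    "choose_k",
    "kmeans",
    "silhouette",
    "dunn",
    "pca_contributions",
    "strike_association",
    "round_half_up",
]


@dataclass
class ClusterModel:
    K: int
    centroids: np.ndarray
    assignments: np.ndarray  # 1..K
    wss: float
    seed: int
    centre: np.ndarray | None = None  # standardisation parameters
    scale: np.ndarray | None = None
    restart_wss: list[float] = field(default_factory=list)


@dataclass
class ValidationReport:
    silhouette_values: np.ndarray
    silhouette_avg: float
    dunn_index: float
    hopkins_value: float
    recommended_k: dict[str, int]


def standardise(matrix: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Z-score columns (unbiased sd); zero-variance columns are dropped.

    Returns (z_matrix, centres, scales, kept column indices).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    names = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else list(range(X.shape[1]))
    sd = X.std(axis=0, ddof=1)
    keep = [j for j in range(X.shape[1]) if sd[j] > 0]
    dropped = [names[j] for j in range(X.shape[1]) if sd[j] == 0]
    if not keep:
        raise ValueError("all columns are constant; nothing to standardise")
    if dropped:
        warnings.warn(f"dropping zero-variance column(s): {dropped}")
    mu = X[:, keep].mean(axis=0)
    sc = sd[keep]
    return (X[:, keep] - mu) / sc, mu, sc, keep


def hopkins(matrix: np.ndarray, sample_fraction: float = 0.1, seed: int = 0) -> float:
    """Clustering-tendency statistic W / (U + W), in [0, 1].

    W sums nearest-neighbour distances within a sample of the data; U sums
    nearest-neighbour distances from uniform points (drawn in the data's
    bounding box) to the data.  Values close to zero indicate clusterable
    structure; uniform data gives about one half.
    """
    X = np.asarray(matrix, dtype=float)
    n = len(X)
    m = int(np.floor(n * sample_fraction))
    if m < 1 or n <= 2 / sample_fraction:
        raise ValueError("too few rows for the requested sample fraction")
    rng = substream(seed, "hopkins")
    idx = rng.choice(n, size=m, replace=False)

    nn = NearestNeighbors(n_neighbors=2).fit(X)
    d_real, _ = nn.kneighbors(X[idx])
    W = float(d_real[:, 1].sum())  # column 0 is the point itself

    lo, hi = X.min(axis=0), X.max(axis=0)
    U_pts = rng.uniform(lo, hi, size=(m, X.shape[1]))
    d_unif, _ = NearestNeighbors(n_neighbors=1).fit(X).kneighbors(U_pts)
    U = float(d_unif[:, 0].sum())
    return W / (U + W)


def kmeans(
    matrix: np.ndarray, K: int, n_init: int = 10, max_iter: int = 300, seed: int = 0
) -> ClusterModel:
    """Best-of-``n_init`` Lloyd's K-means with k-means++ seeding."""
    X = np.asarray(matrix, dtype=float)
    if K > len(X):
        raise ValueError(f"K={K} exceeds number of rows {len(X)}")
    restart_wss: list[float] = []
    best: KMeans | None = None
    for i in range(n_init):
        km = KMeans(
            n_clusters=K,
            n_init=1,
            max_iter=max_iter,
            random_state=derive_seed(seed, "kmeans", str(i)),
        ).fit(X)
        restart_wss.append(float(km.inertia_))
        if best is None or km.inertia_ < best.inertia_:
            best = km
    assert best is not None
    return ClusterModel(
        K=K,
        centroids=best.cluster_centers_,
        assignments=best.labels_ + 1,
        wss=float(best.inertia_),
        seed=seed,
        restart_wss=restart_wss,
    )


def silhouette(matrix: np.ndarray, assignments: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-point silhouette widths and their average (Euclidean distance).

    Points in singleton clusters get width 0 by convention.
    """
    labels = np.asarray(assignments)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    vals = silhouette_samples(np.asarray(matrix, dtype=float), labels)
    return vals, float(vals.mean())


def dunn(matrix: np.ndarray, assignments: np.ndarray) -> float:
    """Dunn index: min between-cluster distance / max within-cluster diameter.

    Separated clusters of zero diameter give +inf.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index is undefined for a single cluster")
    D = squareform(pdist(X))
    max_diam = 0.0
    for c in uniq:
        members = np.where(labels == c)[0]
        if len(members) > 1:
            max_diam = max(max_diam, float(D[np.ix_(members, members)].max()))
    min_sep = np.inf
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            ia, ib = np.where(labels == a)[0], np.where(labels == b)[0]
            min_sep = min(min_sep, float(D[np.ix_(ia, ib)].min()))
    if max_diam == 0.0:
        return np.inf if min_sep > 0 else 0.0
    return min_sep / max_diam


def choose_k(
    matrix: np.ndarray,
    k_range=range(2, 11),
    methods=("wss_elbow", "avg_silhouette", "gap"),
    seed: int = 0,
    gap_B: int = 20,
) -> dict[str, int]:
    """Recommend K per method over ``k_range``.

    avg_silhouette: K maximising the mean silhouette width.  wss_elbow: K at
    the maximum second difference of the within-cluster sum of squares.
    gap: Tibshirani's gap statistic against ``gap_B`` uniform reference sets,
    smallest K with gap(K) >= gap(K+1) - s(K+1).
    """
    X = np.asarray(matrix, dtype=float)
    ks = sorted(k_range)
    if not ks or ks[0] < 2 or ks[-1] > len(X) - 1:
        raise ValueError(f"k_range must lie in [2, n-1], got {ks}")
    models = {k: kmeans(X, k, seed=seed) for k in ks}
    out: dict[str, int] = {}
    if "avg_silhouette" in methods:
        sils = {k: silhouette(X, models[k].assignments)[1] for k in ks}
        out["avg_silhouette"] = max(sils, key=sils.get)
    if "wss_elbow" in methods:
        # include K=1 so the second difference exists at the smallest K
        wss = {1: float(((X - X.mean(axis=0)) ** 2).sum())}
        wss.update({k: models[k].wss for k in ks})
        grid = sorted(wss)
        second = {
            grid[i]: wss[grid[i - 1]] - 2 * wss[grid[i]] + wss[grid[i + 1]]
            for i in range(1, len(grid) - 1)
        }
        out["wss_elbow"] = max(second, key=second.get) if second else ks[0]
    if "gap" in methods:
        rng = substream(seed, "gap")
        lo, hi = X.min(axis=0), X.max(axis=0)
        log_w = {k: np.log(max(models[k].wss, 1e-12)) for k in ks}
        ref_log_w = {k: [] for k in ks}
        for b in range(gap_B):
            ref = rng.uniform(lo, hi, size=X.shape)
            for k in ks:
                ref_log_w[k].append(
                    np.log(max(kmeans(ref, k, n_init=1, seed=derive_seed(seed, "gapref", str(b))).wss, 1e-12))
                )
        gap = {k: float(np.mean(ref_log_w[k]) - log_w[k]) for k in ks}
        s = {k: float(np.std(ref_log_w[k]) * np.sqrt(1 + 1 / gap_B)) for k in ks}
        rec = ks[-1]
        for i, k in enumerate(ks[:-1]):
            if gap[k] >= gap[ks[i + 1]] - s[ks[i + 1]]:
                rec = k
                break
        out["gap"] = rec
    return out


def pca_contributions(matrix: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Loadings and per-variable contribution percentages for the leading PCs.

    Contribution of variable j to component k is its squared loading,
    normalised so each component's contributions sum to 100.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] < n_components:
        raise ValueError("fewer variables than requested components")
    pca = PCA(n_components=n_components)
    pca.fit(X)
    loadings = pca.components_  # (components, variables), unit rows
    sq = loadings**2
    contrib = 100.0 * sq / sq.sum(axis=1, keepdims=True)
    return loadings, contrib


def round_half_up(x: float, digits: int = 3) -> float:
    """Decimal rounding with ties away from zero (report convention)."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClusterAssociation:
    """Per-cluster (and overall) strike probabilities with bootstrap CIs."""

    table: pd.DataFrame  # columns: cluster, days, strikes, p, ci_low, ci_high, overlap

    def to_csv(self, path) -> None:
        out = self.table.copy()
        for col in ("p", "ci_low", "ci_high"):
            out[col] = [round_half_up(v, 3) for v in out[col]]
        out.to_csv(path, index=False)


def _bootstrap_ci(flags: np.ndarray, B: int, rng: np.random.Generator, level: float) -> tuple[float, float]:
    n = len(flags)
    idx = rng.integers(0, n, size=(B, n))
    props = flags[idx].mean(axis=1)
    a = (1.0 - level) / 2.0
    return float(np.quantile(props, a)), float(np.quantile(props, 1.0 - a))


def strike_association(
    assignments: np.ndarray,
    strike_flags: np.ndarray,
    B: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> ClusterAssociation:
    """Daily collision probability per day-type cluster, with bootstrap CIs.

    For the pooled data and each cluster: p = strike-days / days, and a
    percentile bootstrap CI from ``B`` resamples of the group's day-level
    outcomes.  A cluster's ``overlap`` flag is "Y" iff its CI intersects
    the overall CI (closed intervals); "N" marks a strike-associated or
    strike-averse day type.
    """
    labels = np.asarray(assignments)
    flags = np.asarray(strike_flags, dtype=float)
    if len(labels) != len(flags):
        raise ValueError("assignments and strike flags differ in length")
    if B < 1000:
        raise ValueError("B must be at least 1000 for stable percentile endpoints")
    rng = substream(seed, "bootstrap")

    rows = []
    lo_all, hi_all = _bootstrap_ci(flags, B, rng, level)
    rows.append(
        {
            "cluster": "All",
            "days": len(flags),
            "strikes": int(flags.sum()),
            "p": flags.mean(),
            "ci_low": lo_all,
            "ci_high": hi_all,
            "overlap": "",
        }
    )
    for c in np.unique(labels):
        sub = flags[labels == c]
        if len(sub) == 0:
            raise ValueError(f"cluster {c} is empty")
        lo, hi = _bootstrap_ci(sub, B, rng, level)
        overlap = "Y" if (lo <= hi_all and lo_all <= hi) else "N"
        rows.append(
            {
                "cluster": str(c),
                "days": len(sub),
                "strikes": int(sub.sum()),
                "p": sub.mean(),
                "ci_low": lo,
                "ci_high": hi,
                "overlap": overlap,
            }
        )
    return ClusterAssociation(pd.DataFrame(rows))
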