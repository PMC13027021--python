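"""Three-way outlier detection in 3-D expression-ratio space.

Retained genes live in the space of control-normalised ratios
(r40, r80, r300).  Three independent detectors flag "sentinel" genes:

1. distance ranking — Euclidean distance from the Global Center (the mean
   profile over all genes), with either a fixed top-k cut or a largest-gap
   ("inflection point") cut;
2. DBSCAN — density-based clustering with ε chosen from the 5-distance
   (k-th nearest neighbour) curve; noise points are the outliers;
3. symbolic singletons — genes with a unique trajectory triplet (see
   :mod:`deupanel.symbols`).

Their Venn consensus highlights genes flagged by every route.  Distances use
raw ratio coordinates (no standardisation): the three axes already share
units, and the ε scale is defined on them.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

NOISE = -1


# ---------------------------------------------------------------------------
# pathway centroid geometry


@dataclass
class CentroidTable:
    """Per-pathway mean profiles plus the Global Center.

    ``centroids`` has one row per pathway (columns r40, r80, r300, n_genes);
    ``global_center`` is the unweighted mean profile over all genes, which by
    construction equals the gene-count-weighted mean of the pathway centroids.
    """

    centroids: pd.DataFrame
    global_center: np.ndarray


def pathway_centroids(profiles: pd.DataFrame, annotation) -> CentroidTable:
    """Arithmetic mean profile per pathway and the overall Global Center.

    Parameters
    ----------
    profiles : DataFrame
        Columns gene_id, r40, r80, r300.
    annotation : mapping or Series
        gene_id -> pathway bin; every gene must be annotated to exactly one.
    """
    annotation = pd.Series(dict(annotation)) if not isinstance(annotation, pd.Series) else annotation
    genes = profiles["gene_id"]
    unannotated = [g for g in genes if g not in annotation.index]
    if unannotated:
        raise ValueError(f"unannotated genes: {unannotated[:5]}")
    df = profiles.copy()
    df["pathway"] = annotation.loc[genes].to_numpy()
    ratio_cols = ["r40", "r80", "r300"]
    grouped = df.groupby("pathway")[ratio_cols].mean()
    grouped["n_genes"] = df.groupby("pathway").size()
    center = df[ratio_cols].mean().to_numpy()
    return CentroidTable(centroids=grouped, global_center=center)


def global_center_from_centroids(centroids, gene_counts) -> np.ndarray:
    """Gene-count-weighted mean of pathway centroids (weighted-mean identity)."""
    c = np.asarray(centroids, dtype=float)
    w = np.asarray(gene_counts, dtype=float)
    if len(c) != len(w):
        raise ValueError("one gene count per centroid required")
    return (c * w[:, None]).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# distance ranking


def rank_by_centroid_distance(profiles: pd.DataFrame, center) -> pd.DataFrame:
    """Euclidean distance of every gene from ``center``, most distant first.

    Ties are broken by gene symbol so the ranking is deterministic.
    """
    center = np.asarray(center, dtype=float)
    if not np.all(np.isfinite(center)):
        raise ValueError("center must be finite")
    X = profiles[["r40", "r80", "r300"]].to_numpy(dtype=float)
    dist = np.linalg.norm(X - center, axis=1)
    out = pd.DataFrame({"gene_id": profiles["gene_id"].to_numpy(), "distance": dist})
    out = out.sort_values(["distance", "gene_id"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def select_top_by_gap(ranking: pd.DataFrame, default_k: int = 6, mode: str = "fixed-k"):
    """Select the most distant genes, by fixed k or by the largest gap.

    ``largest-gap`` operationalises the "clear inflection point": the cut is
    placed at the largest consecutive drop within the top half of the sorted
    distances.  If every candidate gap is zero the selection falls back to
    ``default_k`` (logged).  Returns ``(genes, method_used)``.
    """
    if ranking.empty:
        raise ValueError("empty ranking")
    n = len(ranking)
    if mode == "fixed-k":
        if default_k > n:
            raise ValueError(f"k={default_k} exceeds gene count {n}")
        return list(ranking["gene_id"].iloc[:default_k]), "fixed-k"
    if mode != "largest-gap":
        raise ValueError(f"unknown mode {mode!r}")
    dist = ranking["distance"].to_numpy()
    half = min((n + 1) // 2, n - 1)  # candidate cuts within the top half
    gaps = dist[:half] - dist[1 : half + 1] if n > 1 else np.array([])
    if gaps.size == 0 or np.max(gaps) <= 0:
        logger.warning("degenerate distance distribution; falling back to fixed k=%d", default_k)
        return list(ranking["gene_id"].iloc[: min(default_k, n)]), "fixed-k-fallback"
    cut = int(np.argmax(gaps)) + 1
    return list(ranking["gene_id"].iloc[:cut]), "largest-gap"


# ---------------------------------------------------------------------------
# DBSCAN with k-distance epsilon selection


def kdist_profile(profiles, k: int = 5) -> np.ndarray:
    """Sorted k-th nearest-neighbour distances (self excluded), ascending.

    The classic "k-distance plot" used to pick ε: with min_samples = 5 one
    inspects the 5-distance curve and places ε at its knee.
    """
    X = _as_matrix(profiles)
    n = len(X)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} genes for a {k}-distance profile")
    d = cdist(X, X)
    d.sort(axis=1)
    return np.sort(d[:, k])  # column 0 is the self-distance


def select_epsilon(kdist, default: float = 0.13) -> float:
    """ε at the point of maximum discrete curvature of the sorted k-distance curve.

    Curvature is the second difference of the sorted values; for a flat curve
    followed by a jump this lands just below the jump.  If the curve has no
    positive curvature (e.g. strictly linear) the configured default is
    returned with a warning.
    """
    kd = np.asarray(kdist, dtype=float)
    if kd.size == 0:
        raise ValueError("empty k-distance profile")
    if kd.size < 3:
        warnings.warn("k-distance curve too short for curvature; using default epsilon")
        return float(default)
    d2 = kd[2:] - 2 * kd[1:-1] + kd[:-2]
    if np.max(d2) <= 1e-12:
        warnings.warn("ambiguous (flat/linear) k-distance curve; using default epsilon")
        return float(default)
    knee = int(np.argmax(d2)) + 1
    return float(kd[knee])


def _as_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, pd.DataFrame):
        cols = [c for c in ("r40", "r80", "r300") if c in profiles.columns]
        if cols:
            return profiles[cols].to_numpy(dtype=float)
        return profiles.to_numpy(dtype=float)
    return np.asarray(profiles, dtype=float)


class DeterministicDBSCAN(ClusterMixin, BaseEstimator):
    """DBSCAN with fully reproducible labels.

    Core points have at least ``min_samples`` neighbours within ``eps``
    (the point itself counts, so min_samples = 5 means 4 true neighbours);
    clusters are maximal density-connected sets of core points plus the
    border points they reach.  Points are processed in a deterministic key
    order (gene symbol), and a border point in reach of several clusters
    joins the one created first in that order — the only freedom classic
    DBSCAN leaves open.

    Fitted attributes: ``labels_`` (noise = -1, clusters numbered in
    creation order) and ``core_sample_indices_``.
    """

    def __init__(self, eps: float = 0.13, min_samples: int = 5):
        self.eps = eps
        self.min_samples = min_samples

    def fit(self, X, y=None, order=None):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        X = _as_matrix(X)
        n = len(X)
        if order is None:
            order_idx = np.arange(n)
        else:
            order_idx = np.array(sorted(range(n), key=lambda i: (str(order[i]), i)))
        pos = np.empty(n, dtype=int)  # processing rank of each point
        pos[order_idx] = np.arange(n)

        dist = cdist(X, X)
        neighbor_lists = [
            sorted(np.flatnonzero(dist[i] <= self.eps), key=lambda j: pos[j]) for i in range(n)
        ]
        is_core = np.array([len(nb) >= self.min_samples for nb in neighbor_lists])

        labels = np.full(n, NOISE, dtype=int)
        cluster = 0
        for i in order_idx:
            if labels[i] != NOISE or not is_core[i]:
                continue
            labels[i] = cluster
            queue = deque([i])
            while queue:
                p = queue.popleft()
                for q in neighbor_lists[p]:
                    if labels[q] != NOISE:
                        continue
                    labels[q] = cluster
                    if is_core[q]:
                        queue.append(q)
            cluster += 1
        self.labels_ = labels
        self.core_sample_indices_ = np.flatnonzero(is_core)
        self.n_features_in_ = X.shape[1]
        return self


def dbscan(profiles, eps: float = 0.13, min_samples: int = 5) -> pd.Series:
    """Cluster ratio profiles with :class:`DeterministicDBSCAN`.

    Accepts a profile DataFrame (processing order = gene symbol) or a plain
    array (processing order = row order).  Returns labels indexed by gene.
    """
    model = DeterministicDBSCAN(eps=eps, min_samples=min_samples)
    if isinstance(profiles, pd.DataFrame) and "gene_id" in profiles.columns:
        genes = profiles["gene_id"].to_numpy()
        model.fit(profiles, order=genes)
        return pd.Series(model.labels_, index=genes, name="dbscan_label")
    model.fit(profiles)
    return pd.Series(model.labels_, name="dbscan_label")


# ---------------------------------------------------------------------------
# Venn consensus


@dataclass
class OutlierConsensus:
    """Membership of each flagged gene in the three detector sets."""

    sets: dict
    membership: pd.DataFrame
    core: set
    region_counts: dict
    region_genes: dict


def consensus_venn(centroid_set, dbscan_set, singleton_set, universe) -> OutlierConsensus:
    """Cross-tabulate the three outlier sets over a common gene universe.

    Venn regions are keyed by the sorted '&'-joined names of the detectors a
    gene belongs to exclusively (e.g. ``"centroid&dbscan"``); the core is the
    triple intersection.
    """
    universe = set(universe)
    sets = {
        "centroid": set(centroid_set),
        "dbscan": set(dbscan_set),
        "singleton": set(singleton_set),
    }
    for name, s in sets.items():
        stray = s - universe
        if stray:
            raise ValueError(f"{name} set contains genes outside the universe: {sorted(stray)[:5]}")
    flagged = sorted(sets["centroid"] | sets["dbscan"] | sets["singleton"])
    membership = pd.DataFrame(
        {name: [g in s for g in flagged] for name, s in sets.items()},
        index=pd.Index(flagged, name="gene_id"),
    )
    region_genes: dict = {}
    for gene in flagged:
        key = "&".join(name for name in ("centroid", "dbscan", "singleton") if gene in sets[name])
        region_genes.setdefault(key, []).append(gene)
    region_counts = {k: len(v) for k, v in region_genes.items()}
    core = sets["centroid"] & sets["dbscan"] & sets["singleton"]
    return OutlierConsensus(
        sets=sets,
        membership=membership,
        core=core,
        region_counts=region_counts,
        region_genes=region_genes,
    )
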