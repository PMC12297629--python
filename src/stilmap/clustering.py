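"""Spatial TIL clusters from encoded hot spot maps.

Encoder features are reduced with PCA and partitioned with K-means. The
number of clusters is chosen by a consensus vote among three internal
validity indices — Silhouette score (maximize), Davies-Bouldin index
(minimize) and Calinski-Harabasz index (maximize) — over candidate k. The
two resulting spatial TIL clusters (sTILCs) are named by their hot spot
content: the cluster whose maps carry the lower mean hot fraction is the
"TIL-cold" cluster sTILC1, the other the "TIL-hot" cluster sTILC2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .hotspot import HotspotMap

__all__ = [
    "PCAModel",
    "ConsensusVote",
    "SpatialFeatureSet",
    "fit_pca",
    "consensus_k_selection",
    "assign_stilc_names",
    "cluster_assignment_table",
]

STILC_COLD = "sTILC1"
STILC_HOT = "sTILC2"

DEFAULT_CANDIDATE_KS = (2, 3, 4, 5, 6)


@dataclass
class PCAModel:
    """Centered PCA with enough components to reach a variance target."""

    mean: np.ndarray
    components: np.ndarray  # (k_pca, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    variance_target: float

    @property
    def k_pca(self) -> int:
        return self.components.shape[0]

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.mean) @ self.components.T

    def inverse_transform(self, reduced: np.ndarray) -> np.ndarray:
        return np.asarray(reduced, dtype=float) @ self.components + self.mean


def fit_pca(
    features: np.ndarray,
    variance_target: float = 0.95,
    k_cap: int | None = None,
) -> tuple[PCAModel, np.ndarray]:
    """Fit PCA and keep the smallest k reaching the cumulative variance target.

    ``k_cap`` optionally fixes an upper bound on the number of components
    (e.g. to pin a published component count); the effective k is also capped
    at the matrix rank. Returns the model and the reduced (n x k) matrix.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca requires a 2-D matrix with at least 2 rows")
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must lie in (0, 1]")
    if np.allclose(X, X[0], atol=0.0):
        raise ValueError("rank zero: all feature rows are identical")

    full = PCA(svd_solver="full").fit(X)
    evr = full.explained_variance_ratio_
    rank = int(np.sum(full.explained_variance_ > 1e-12 * full.explained_variance_[0]))
    rank = max(rank, 1)
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, rank)
    if k_cap is not None:
        k = min(k, int(k_cap))

    model = PCAModel(
        mean=full.mean_.copy(),
        components=full.components_[:k].copy(),
        explained_variance_ratio=evr[:k].copy(),
        variance_target=variance_target,
    )
    return model, model.transform(X)


@dataclass
class ConsensusVote:
    """Per-k index values, per-metric winners, and the voted cluster number."""

    candidate_ks: tuple[int, ...]
    silhouette: dict[int, float]
    davies_bouldin: dict[int, float]
    calinski_harabasz: dict[int, float]
    winners: dict[str, int]
    selected_k: int
    labels_by_k: dict[int, np.ndarray]

    @property
    def selected_labels(self) -> np.ndarray:
        return self.labels_by_k[self.selected_k]


def resolve_vote(winners: dict[str, int]) -> int:
    """Majority vote over per-metric winning k; a three-way tie falls back to
    silhouette's winner."""
    votes = list(winners.values())
    counts = {k: votes.count(k) for k in set(votes)}
    best = max(counts.values())
    if best == 1:
        return winners["silhouette"]
    return [k for k, c in counts.items() if c == best][0]


def consensus_k_selection(
    reduced: np.ndarray,
    candidate_ks: Sequence[int] = DEFAULT_CANDIDATE_KS,
    seed: int = 0,
) -> ConsensusVote:
    """Choose k by majority vote of silhouette / Davies-Bouldin / Calinski-Harabasz.

    For each candidate k a K-means model (k-means++ seeding, 10 restarts, 300
    iteration cap, tolerance 1e-4, fixed seed) is fitted and all three indices
    are evaluated on its labels. Each metric votes for its best k (silhouette
    and Calinski-Harabasz maximize, Davies-Bouldin minimizes); the majority
    wins, and a three-way tie falls back to silhouette's winner. Candidates
    with k >= n are skipped with a warning.
    """
    X = np.asarray(reduced, dtype=float)
    n = X.shape[0]
    sil: dict[int, float] = {}
    db: dict[int, float] = {}
    ch: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    kept: list[int] = []
    for k in candidate_ks:
        if k >= n:
            warnings.warn(f"skipping k={k}: needs more than {k} samples (have {n})")
            continue
        if k < 2:
            raise ValueError("candidate k must be >= 2")
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                    tol=1e-4, random_state=seed).fit(X)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            warnings.warn(f"skipping k={k}: clustering collapsed to one cluster")
            continue
        sil[k] = float(silhouette_score(X, labels))
        db[k] = float(davies_bouldin_score(X, labels))
        ch[k] = float(calinski_harabasz_score(X, labels))
        labels_by_k[k] = labels
        kept.append(k)
    if not kept:
        raise ValueError("no candidate k was evaluable on this data")

    winners = {
        "silhouette": max(kept, key=lambda k: (sil[k], -k)),
        "davies_bouldin": min(kept, key=lambda k: (db[k], k)),
        "calinski_harabasz": max(kept, key=lambda k: (ch[k], -k)),
    }
    selected = resolve_vote(winners)

    return ConsensusVote(
        candidate_ks=tuple(kept),
        silhouette=sil,
        davies_bouldin=db,
        calinski_harabasz=ch,
        winners=winners,
        selected_k=selected,
        labels_by_k=labels_by_k,
    )


def assign_stilc_names(
    cluster_labels: np.ndarray,
    hotspot_maps: Sequence[HotspotMap],
) -> np.ndarray:
    """Name the two clusters sTILC1 (TIL-cold) / sTILC2 (TIL-hot).

    The cluster with the lower mean hot fraction across its slides' hot spot
    maps becomes sTILC1. Defined only for the two-cluster outcome; ties are
    broken toward labeling the first-indexed cluster sTILC1, with a warning.
    Invariant to cluster-id permutation and slide ordering.
    """
    labels = np.asarray(cluster_labels)
    if len(labels) != len(hotspot_maps):
        raise ValueError("cluster_labels and hotspot_maps must align per slide")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"sTILC naming requires exactly 2 clusters, got {len(uniq)}")
    hf = np.array([m.hot_fraction for m in hotspot_maps])
    means = {c: hf[labels == c].mean() for c in uniq}
    a, b = uniq
    if means[a] == means[b]:
        warnings.warn("clusters have identical mean hot fractions; "
                      f"assigning cluster {a} to {STILC_COLD} by convention")
        cold = a
    else:
        cold = a if means[a] < means[b] else b
    return np.where(labels == cold, STILC_COLD, STILC_HOT)


@dataclass
class SpatialFeatureSet:
    """Per-slide encoder features, PCA reduction, and cluster assignments."""

    slide_ids: list[str]
    raw_features: np.ndarray
    pca_model: PCAModel
    pca_components: np.ndarray
    vote: ConsensusVote
    cluster_labels: np.ndarray
    stilc_labels: np.ndarray | None = None


def cluster_assignment_table(fs: SpatialFeatureSet) -> pd.DataFrame:
    """Assignment table ``slide_id,cluster,stilc``."""
    return pd.DataFrame(
        {
            "slide_id": fs.slide_ids,
            "cluster": fs.cluster_labels,
            "stilc": fs.stilc_labels if fs.stilc_labels is not None else "",
        }
    )
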