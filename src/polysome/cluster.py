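"""Hierarchical clustering of polysome profiles and of samples.

Isoform fraction-profiles are clustered on Spearman rank-correlation
distance with Ward agglomeration; samples (gradient fractions) are
clustered on Euclidean distance with complete agglomeration.  Cluster
robustness is assessed by reclustering resampled data (bootstrap,
jitter, noise replacement) and scoring each reference cluster by its
best Jaccard similarity against the perturbed clustering, following the
scheme popularised by the R package fpc: a mean coefficient of at least
0.75 marks a stable cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin

STABLE_JACCARD = 0.75

__all__ = [
    "ClusterResult",
    "MetaProfile",
    "StabilityReport",
    "ProfileClusterer",
    "SampleClusterer",
    "spearman_distance_matrix",
    "hcluster",
    "cut_to_clusters",
    "meta_profiles",
    "jaccard_stability",
    "cluster_samples",
    "linkage_to_newick",
]


@dataclass
class ClusterResult:
    """A cut hierarchical clustering.

    Attributes
    ----------
    linkage_matrix:
        SciPy linkage (merge tree with heights).
    assignments:
        Series mapping item id -> cluster label (1..k, contiguous).
    k:
        Number of clusters.
    linkage, distance:
        Labels of the agglomeration method and the distance used.
    """

    linkage_matrix: np.ndarray
    assignments: pd.Series
    k: int
    linkage: str
    distance: str

    @property
    def labels(self) -> np.ndarray:
        return self.assignments.to_numpy()

    def members(self, label: int) -> pd.Index:
        return self.assignments.index[self.assignments == label]

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage_matrix, list(self.assignments.index))


@dataclass
class MetaProfile:
    """Mean +/- s.d. relative abundance of one cluster per fraction."""

    label: int
    mean: pd.Series
    sd: pd.Series
    n_members: int


@dataclass
class StabilityReport:
    """Per-cluster mean Jaccard coefficients per resampling scheme."""

    per_cluster: pd.DataFrame  # rows: scheme, columns: cluster label
    n_resamples: int
    dissolved: pd.DataFrame | None = None

    @property
    def stable(self) -> pd.DataFrame:
        return self.per_cluster >= STABLE_JACCARD

    def min_coefficient(self) -> float:
        return float(self.per_cluster.min().min())


def spearman_distance_matrix(rows: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation distance ``1 - rho`` between rows.

    Values lie in [0, 2]; the diagonal is zero.  Rows with no rank
    variation have undefined correlation: they are flagged with a
    warning and assigned the neutral distance 1 to every other row.
    """
    x = rows.to_numpy(dtype=float) if isinstance(rows, pd.DataFrame) else np.asarray(rows, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two columns")
    ranks = np.apply_along_axis(rankdata, 1, x)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    safe_norms = np.where(constant, 1.0, norms)
    unit = centered / safe_norms[:, None]
    rho = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - rho
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s): Spearman correlation "
            "undefined, distance set to 1",
            stacklevel=2,
        )
        d[constant, :] = 1.0
        d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def hcluster(distance_matrix: np.ndarray, linkage: str = "ward") -> np.ndarray:
    """Agglomerative clustering of a square distance matrix.

    Returns a SciPy linkage matrix.  Merging is deterministic: on equal
    heights SciPy's nearest-neighbor chain resolves ties by lowest
    index.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {d.shape}")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    condensed = squareform(d, checks=False)
    return hierarchy.linkage(condensed, method=linkage)


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel to 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cut_to_clusters(
    linkage_matrix: np.ndarray,
    k: int | None = None,
    height: float | None = None,
    ids: Sequence | None = None,
    matrix: pd.DataFrame | None = None,
    refine: bool = False,
    rho_threshold: float = 0.95,
    max_k: int = 20,
    linkage: str = "ward",
    distance: str = "spearman",
) -> ClusterResult:
    """Cut a dendrogram into clusters.

    Either a cluster count ``k`` or a cut ``height`` must be given.
    With ``refine=True`` (requires ``matrix``) the tree is instead split
    at increasing depth until every pair of cluster meta-profiles is
    distinguishable (pairwise Spearman correlation of mean profiles
    below ``rho_threshold``), emulating the judgment call of splitting
    subtrees "until clusters contain similar overall trends".
    """
    n = linkage_matrix.shape[0] + 1
    if ids is None:
        ids = matrix.index if matrix is not None else pd.RangeIndex(n)
    if len(ids) != n:
        raise ValueError("ids length does not match tree size")

    def cut(kk: int) -> np.ndarray:
        return _contiguous(hierarchy.fcluster(linkage_matrix, kk, criterion="maxclust"))

    if refine:
        if matrix is None:
            raise ValueError("refine mode needs the data matrix")
        labels = cut(2)
        for kk in range(2, min(max_k, n) + 1):
            labels = cut(kk)
            profiles = meta_profiles(matrix, pd.Series(labels, index=ids))
            means = np.vstack([p.mean.to_numpy() for p in profiles])
            if len(profiles) < 2:
                continue
            rho = 1.0 - spearman_distance_matrix(means)
            np.fill_diagonal(rho, -np.inf)
            if rho.max() < rho_threshold:
                break
    elif k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        labels = cut(k)
    elif height is not None:
        labels = _contiguous(
            hierarchy.fcluster(linkage_matrix, height, criterion="distance")
        )
    else:
        raise ValueError("either k, height, or refine=True must be given")

    return ClusterResult(
        linkage_matrix=linkage_matrix,
        assignments=pd.Series(labels, index=ids, name="cluster"),
        k=int(labels.max()),
        linkage=linkage,
        distance=distance,
    )


def meta_profiles(
    matrix: pd.DataFrame,
    assignments: pd.Series,
) -> list[MetaProfile]:
    """Mean and s.d. profile of each cluster over the fraction columns.

    s.d. uses the sample convention (ddof=1); singleton clusters report
    zero spread.  Raises on labels with no members.
    """
    profiles: list[MetaProfile] = []
    for label in sorted(pd.unique(assignments)):
        members = assignments.index[assignments == label]
        if len(members) == 0:
            raise ValueError(f"cluster {label} has no members")
        sub = matrix.loc[members]
        sd = sub.std(axis=0, ddof=1) if len(members) > 1 else sub.iloc[0] * 0.0
        profiles.append(
            MetaProfile(
                label=int(label),
                mean=sub.mean(axis=0),
                sd=sd,
                n_members=len(members),
            )
        )
    return profiles


def _best_jaccard(reference: set, new_clusters: Iterable[set]) -> float:
    best = 0.0
    for cand in new_clusters:
        inter = len(reference & cand)
        if inter == 0:
            continue
        union = len(reference | cand)
        best = max(best, inter / union)
    return best


def jaccard_stability(
    matrix: pd.DataFrame | np.ndarray,
    clusterer: Callable[[np.ndarray], np.ndarray],
    schemes: Sequence[str] = ("bootstrap", "jitter", "noise"),
    n_resamples: int = 100,
    seed: int | None = None,
    jitter_scale: float = 0.1,
    noise_rate: float = 0.05,
) -> StabilityReport:
    """Cluster-wise Jaccard stability under resampling.

    The rows of ``matrix`` are the observations being clustered;
    ``clusterer`` maps a data matrix to integer labels and must
    reproduce the reference clustering on the unperturbed data.  Three
    perturbation schemes are supported:

    - ``bootstrap``: resample observations with replacement, recluster,
      and compare memberships on the observations present in the
      resample.  Resamples in which a reference cluster has no member
      carry no information about that cluster and are excluded from its
      mean (the count of such dissolutions is reported separately).
    - ``jitter``: add Gaussian noise with s.d. ``jitter_scale`` times
      each column's s.d.
    - ``noise``: replace each observation, independently with
      probability ``noise_rate``, by a uniform draw over the column
      range.

    Each reference cluster scores, per resample, its maximum Jaccard
    similarity ``|A & B| / |A | B|`` over the clusters of the perturbed
    data; per-cluster means >= 0.75 are conventionally called stable.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    reference = np.asarray(clusterer(x))
    ref_labels = sorted(set(reference.tolist()))
    ref_sets = {lab: set(np.flatnonzero(reference == lab).tolist()) for lab in ref_labels}
    col_sd = x.std(axis=0, ddof=1)
    col_min = x.min(axis=0)
    col_span = x.max(axis=0) - col_min

    sums = {s: {lab: 0.0 for lab in ref_labels} for s in schemes}
    counts = {s: {lab: 0 for lab in ref_labels} for s in schemes}
    dissolved = {s: {lab: 0 for lab in ref_labels} for s in schemes}

    for scheme in schemes:
        if scheme not in ("bootstrap", "jitter", "noise"):
            raise ValueError(f"unknown resampling scheme {scheme!r}")
        for _ in range(n_resamples):
            if scheme == "bootstrap":
                idx = rng.integers(0, n, size=n)
                labels = np.asarray(clusterer(x[idx]))
                present = set(idx.tolist())
                new_sets = [
                    set(idx[labels == lab].tolist()) for lab in set(labels.tolist())
                ]
                for lab in ref_labels:
                    restricted = ref_sets[lab] & present
                    if not restricted:
                        dissolved[scheme][lab] += 1
                        continue
                    sums[scheme][lab] += _best_jaccard(restricted, new_sets)
                    counts[scheme][lab] += 1
            else:
                if scheme == "jitter":
                    perturbed = x + rng.normal(0.0, 1.0, size=x.shape) * (
                        jitter_scale * col_sd
                    )
                else:
                    perturbed = x.copy()
                    replace = rng.random(n) < noise_rate
                    n_rep = int(replace.sum())
                    if n_rep:
                        perturbed[replace] = col_min + rng.random(
                            (n_rep, x.shape[1])
                        ) * col_span
                labels = np.asarray(clusterer(perturbed))
                new_sets = [
                    set(np.flatnonzero(labels == lab).tolist())
                    for lab in set(labels.tolist())
                ]
                for lab in ref_labels:
                    sums[scheme][lab] += _best_jaccard(ref_sets[lab], new_sets)
                    counts[scheme][lab] += 1

    per_cluster = pd.DataFrame(
        {
            lab: {
                s: (sums[s][lab] / counts[s][lab]) if counts[s][lab] else np.nan
                for s in schemes
            }
            for lab in ref_labels
        }
    )
    dissolved_df = pd.DataFrame(
        {lab: {s: dissolved[s][lab] for s in schemes} for lab in ref_labels}
    )
    return StabilityReport(
        per_cluster=per_cluster, n_resamples=n_resamples, dissolved=dissolved_df
    )


class ProfileClusterer(BaseEstimator, ClusterMixin):
    """Hierarchical clustering of isoform polysome profiles.

    Rows of X are relative-expression profiles over the gradient
    fractions.  Distance is Spearman rank correlation (``1 - rho``) and
    agglomeration is Ward's method by default, with an optional
    refinement mode that deepens the cut until cluster meta-profiles
    are pairwise distinguishable.

    Attributes (after fit)
    ----------------------
    labels_ : ndarray of cluster labels 1..k
    linkage_matrix_ : SciPy merge tree
    result_ : :class:`ClusterResult`
    """

    def __init__(
        self,
        n_clusters: int = 8,
        metric: str = "spearman",
        linkage: str = "ward",
        refine: bool = False,
        rho_threshold: float = 0.95,
        max_k: int = 20,
    ) -> None:
        self.n_clusters = n_clusters
        self.metric = metric
        self.linkage = linkage
        self.refine = refine
        self.rho_threshold = rho_threshold
        self.max_k = max_k

    def _distances(self, x: np.ndarray) -> np.ndarray:
        if self.metric == "spearman":
            return spearman_distance_matrix(x)
        if self.metric == "euclidean":
            diff = x[:, None, :] - x[None, :, :]
            return np.sqrt((diff**2).sum(axis=2))
        if self.metric == "precomputed":
            return np.asarray(x, dtype=float)
        raise ValueError(f"unknown metric {self.metric!r}")

    def fit(self, X, y=None):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        x = frame.to_numpy(dtype=float)
        self.distance_matrix_ = self._distances(x)
        self.linkage_matrix_ = hcluster(self.distance_matrix_, self.linkage)
        self.result_ = cut_to_clusters(
            self.linkage_matrix_,
            k=None if self.refine else self.n_clusters,
            ids=frame.index,
            matrix=frame if self.refine else None,
            refine=self.refine,
            rho_threshold=self.rho_threshold,
            max_k=self.max_k,
            linkage=self.linkage,
            distance=self.metric,
        )
        self.labels_ = self.result_.labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class SampleClusterer(ProfileClusterer):
    """Clustering of gradient samples (matrix columns) rather than isoforms.

    Follows the sample-level convention: Euclidean distance between
    VST-expression column vectors with complete agglomeration.  ``fit``
    takes the isoform x sample matrix and clusters its columns.
    """

    def __init__(self, n_clusters: int = 4) -> None:
        super().__init__(n_clusters=n_clusters, metric="euclidean", linkage="complete")

    def fit(self, X, y=None):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        return super().fit(frame.T)


def cluster_samples(vst_matrix: pd.DataFrame, k: int = 4) -> ClusterResult:
    """Column dendrogram of a VST expression matrix.

    Euclidean distance, complete linkage — the sample-level analogue of
    the isoform clustering, used to check that sequenced fractions
    recapitulate the gradient order.
    """
    est = SampleClusterer(n_clusters=k).fit(vst_matrix)
    return est.result_


def linkage_to_newick(linkage_matrix: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a SciPy merge tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage_matrix)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
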