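"""Gene-linked isoform comparison: Cliff's d, U tests, bootstrap CIs.

Isoforms of the same gene that land in different polysome clusters
("gene-linked isoforms") isolate transcript features from gene-level
effects: any feature difference within such a pair is a candidate
driver of the translational difference.  Feature distributions of the
high- and low-polysome sides are compared with the nonparametric
effect size Cliff's d,

    d = (#(x_i > x_j) - #(x_i < x_j)) / (m * n),

with percentile-bootstrap confidence intervals and two-tailed
Mann-Whitney U tests.  d relates to the count-of-greater-pairs U
statistic by d = 2U/(mn) - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

__all__ = [
    "LinkedPair",
    "EffectSizeResult",
    "build_linked_sets",
    "cliffs_d",
    "mann_whitney",
    "bootstrap_ci",
    "ecdf",
    "compare_features",
]


@dataclass(frozen=True)
class LinkedPair:
    """A high/low-polysome isoform pair from one gene."""

    gene_id: str
    isoform_high: str
    isoform_low: str


@dataclass
class EffectSizeResult:
    """Cliff's d with CI and U test for one feature."""

    feature: str
    d: float
    ci_low: float
    ci_high: float
    U: float
    p: float
    m: int
    n: int
    significant: bool = False


def _as_clean_array(values: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError(f"{name} set is empty (or all missing)")
    return arr


def _greater_less_counts(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """#(x_i > y_j) and #(x_i < y_j) via sorted search (O((m+n) log n))."""
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()
    less = (len(ys) - np.searchsorted(ys, x, side="right")).sum()
    return float(greater), float(less)


def cliffs_d(x_set: Iterable[float], y_set: Iterable[float]) -> float:
    """Cliff's delta between two samples.

    Counts, over all m*n cross pairs, how often x exceeds y minus how
    often y exceeds x, scaled to [-1, 1].  Ties contribute zero.
    Positive d means the x distribution is stochastically larger.
    """
    x = _as_clean_array(x_set, "x")
    y = _as_clean_array(y_set, "y")
    greater, less = _greater_less_counts(x, y)
    return (greater - less) / (x.size * y.size)


def mann_whitney(
    x_set: Iterable[float], y_set: Iterable[float]
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Returns (U, p) where U is the count-of-greater-pairs statistic for
    x (plus one half per tie), so that d = 2U/(mn) - 1.  The exact null
    distribution is used for small tie-free samples, the tie-corrected
    normal approximation otherwise.
    """
    x = _as_clean_array(x_set, "x")
    y = _as_clean_array(y_set, "y")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # degenerate: every observation tied; U is all half-ties, p trivially 1
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < x.size + y.size
    small = max(x.size, y.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bootstrap_ci(
    x_set: Iterable[float],
    y_set: Iterable[float],
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for a two-sample statistic.

    Both samples are resampled with replacement independently; the
    interval is the (alpha/2, 1 - alpha/2) percentile pair of the
    resampled statistic (Cliff's d by default).
    """
    import warnings

    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be noisy", stacklevel=2)
    x = _as_clean_array(x_set, "x")
    y = _as_clean_array(y_set, "y")
    stat = statistic or cliffs_d
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    for b in range(n_boot):
        xb = x[rng.integers(0, x.size, x.size)]
        yb = y[rng.integers(0, y.size, y.size)]
        values[b] = stat(xb, yb)
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def ecdf(values: Iterable[float]) -> ECDF:
    """Empirical cumulative distribution function (right-continuous)."""
    return ECDF(_as_clean_array(values, "values"))


def build_linked_sets(
    assignments: pd.Series,
    high_clusters: Iterable[int],
    low_clusters: Iterable[int],
    gene_of: Mapping[str, str] | pd.Series,
) -> tuple[list[str], list[str], list[LinkedPair]]:
    """Gene-linked isoform sets between disjoint cluster-label groups.

    For every gene with at least one isoform in a high-polysome cluster
    and at least one in a low-polysome cluster, every cross pair is
    emitted, and each member isoform is added to its side's pooled set
    (so an isoform is contributed once even if it appears in several
    pairs).
    """
    high = set(high_clusters)
    low = set(low_clusters)
    if high & low:
        raise ValueError(f"cluster label sets overlap: {sorted(high & low)}")
    gene_map = gene_of if isinstance(gene_of, Mapping) else gene_of.to_dict()
    by_gene: dict[str, tuple[list[str], list[str]]] = {}
    for isoform, label in assignments.items():
        gene = gene_map.get(isoform)
        if gene is None:
            continue
        slot = by_gene.setdefault(gene, ([], []))
        if label in high:
            slot[0].append(isoform)
        elif label in low:
            slot[1].append(isoform)
    high_set: list[str] = []
    low_set: list[str] = []
    pairs: list[LinkedPair] = []
    for gene in sorted(by_gene):
        highs, lows = by_gene[gene]
        if not highs or not lows:
            continue
        high_set.extend(highs)
        low_set.extend(lows)
        for h in highs:
            for low_iso in lows:
                pairs.append(LinkedPair(gene_id=gene, isoform_high=h, isoform_low=low_iso))
    return high_set, low_set, pairs


def compare_features(
    feature_table: pd.DataFrame,
    high_set: Sequence[str],
    low_set: Sequence[str],
    features: Sequence[str] | None = None,
    alpha: float = 0.001,
    n_boot: int = 2000,
    seed: int | None = None,
) -> list[EffectSizeResult]:
    """Per-feature Cliff's d (high vs low), bootstrap CI and U test.

    Missing values are dropped per feature, so m and n can differ
    between features.  Positive d means the feature is larger among
    high-polysome isoforms.  Raw p-values are reported; ``significant``
    flags p < alpha with no multiplicity correction.
    """
    if not len(high_set) or not len(low_set):
        raise ValueError("both isoform sets must be non-empty")
    feats = list(features) if features is not None else [
        c for c in feature_table.columns if pd.api.types.is_numeric_dtype(feature_table[c])
    ]
    results: list[EffectSizeResult] = []
    ss = np.random.SeedSequence(seed)
    for feature, child in zip(feats, ss.spawn(len(feats))):
        x = feature_table.loc[feature_table.index.intersection(high_set), feature].dropna().to_numpy(dtype=float)
        y = feature_table.loc[feature_table.index.intersection(low_set), feature].dropna().to_numpy(dtype=float)
        if x.size == 0 or y.size == 0:
            continue
        d = cliffs_d(x, y)
        u, p = mann_whitney(x, y)
        lo, hi = bootstrap_ci(
            x, y, n_boot=n_boot, seed=int(child.generate_state(1)[0] % (2**31))
        )
        results.append(
            EffectSizeResult(
                feature=feature,
                d=d,
                ci_low=lo,
                ci_high=hi,
                U=u,
                p=p,
                m=int(x.size),
                n=int(y.size),
                significant=bool(p < alpha),
            )
        )
    if not results:
        raise ValueError(
            "no feature could be compared: isoform sets share no rows with the table"
        )
    return results


def results_to_frame(results: Sequence[EffectSizeResult]) -> pd.DataFrame:
    """Tabular view of :func:`compare_features` output."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "d": r.d,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "U": r.U,
                "p": r.p,
                "m": r.m,
                "n": r.n,
                "significant": r.significant,
            }
            for r in results
        ]
    )
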