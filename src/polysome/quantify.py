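"""Normalization and per-isoform translational statistics.

A polysome gradient is sequenced as nine sample types: total cytoplasmic
RNA plus eight ribosome-containing fractions (the 80S monosome, two
through seven ribosomes, and an eight-or-more pool).  This module holds
the within-sample normalizations (RPKM, TPM), the variance-stabilizing
transformation used upstream of clustering, the weighted polysome count
and the ratios derived from it (ribosome density, translation
efficiency), and the abundance filters applied before clustering.

Column naming convention for count matrices: ``<fraction>_<replicate>``
with fractions drawn from :data:`FRACTIONS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

#: The nine sample types of a fully fractionated polysome profile, in
#: gradient order: cytoplasmic RNA, the 80S monosome, two to seven
#: ribosomes, and the pooled eight-plus fraction.
FRACTIONS: tuple[str, ...] = (
    "cyto",
    "mono",
    "p2",
    "p3",
    "p4",
    "p5",
    "p6",
    "p7",
    "p8plus",
)

#: The eight ribosome-containing fractions (everything but cytoplasmic).
RIBO_FRACTIONS: tuple[str, ...] = FRACTIONS[1:]

#: Nominal ribosome load of each ribosome-containing fraction; the
#: eight-plus pool has no single nominal load (see WeightScheme).
NOMINAL_RIBOSOMES: dict[str, int] = {
    "mono": 1,
    "p2": 2,
    "p3": 3,
    "p4": 4,
    "p5": 5,
    "p6": 6,
    "p7": 7,
}


@dataclass(frozen=True)
class WeightScheme:
    """Per-fraction ribosome weights for the weighted polysome count.

    Each ribosome-containing fraction contributes its read counts
    multiplied by its (nominal) ribosome number.  The final, pooled
    eight-plus fraction has no single ribosome number: transcripts there
    carry anywhere from eight ribosomes up to a physical ceiling
    (``ceiling``, ~40 for typical ORF lengths), so its weight is the
    midpoint ``(ceiling + 8) / 2`` — 24 under the default ceiling.

    Parameters
    ----------
    ceiling:
        Assumed maximum number of ribosomes per transcript.
    include_monosome:
        If True (default) the 80S monosome contributes with weight 1,
        giving an eight-term sum; if False its weight is zero and only
        fractions with two or more ribosomes count.
    """

    ceiling: float = 40.0
    include_monosome: bool = True

    def __post_init__(self) -> None:
        if self.ceiling < 8:
            raise ValueError(f"ribosome ceiling must be >= 8, got {self.ceiling}")

    @property
    def weights(self) -> dict[str, float]:
        """Mapping fraction name -> nonnegative weight."""
        w = {f: float(n) for f, n in NOMINAL_RIBOSOMES.items()}
        if not self.include_monosome:
            w["mono"] = 0.0
        w["p8plus"] = (self.ceiling + 8.0) / 2.0
        return w

    def to_json(self) -> str:
        return json.dumps(
            {"ceiling": self.ceiling, "include_monosome": self.include_monosome}
        )

    @classmethod
    def from_json(cls, text: str) -> "WeightScheme":
        return cls(**json.loads(text))


def counts_to_rpkm(
    counts: np.ndarray | Sequence[float],
    effective_lengths: np.ndarray | Sequence[float],
    library_size: float,
) -> np.ndarray:
    """Reads per kilobase per million mapped reads.

    ``rpkm_i = counts_i * 1e9 / (length_i * library_size)``.  Effective
    length is the annotated transcript length in nucleotides (no
    fragment-length correction is applied).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    if np.any(lengths <= 0):
        raise ValueError("effective lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return counts * 1e9 / (lengths * library_size)


def rpkm_to_tpm(rpkm: np.ndarray | Sequence[float]) -> np.ndarray:
    """Transcripts per million from RPKM.

    ``tpm_i = rpkm_i * 1e6 / sum_g rpkm_g``; the output always sums to
    one million, making samples directly comparable.
    """
    rpkm = np.asarray(rpkm, dtype=float)
    if np.any(rpkm < 0):
        raise ValueError("rpkm values must be nonnegative")
    total = rpkm.sum()
    if total <= 0:
        raise ValueError("all-zero RPKM vector: TPM undefined")
    return rpkm * 1e6 / total


def polysome_count(
    profile_row: Mapping[str, float] | pd.Series,
    scheme: WeightScheme | None = None,
) -> float:
    """Weighted sum of reads over the ribosome-containing fractions.

    Each fraction's (replicate-averaged) read count is multiplied by its
    ribosome weight and summed: with the default scheme that is
    ``1*n_mono + 2*n_2 + ... + 7*n_7 + 24*n_8plus``.  The result
    estimates the total number of ribosome passages the transcript
    supports and correlates with protein output.
    """
    scheme = scheme or WeightScheme()
    total = 0.0
    for fraction, weight in scheme.weights.items():
        if fraction not in profile_row:
            raise KeyError(f"profile row is missing fraction {fraction!r}")
        total += weight * float(profile_row[fraction])
    return total


def ribosome_density(
    profile_row: Mapping[str, float] | pd.Series,
    cytoplasmic_count: float,
    scheme: WeightScheme | None = None,
) -> float:
    """Weighted polysome count divided by cytoplasmic read count."""
    if cytoplasmic_count <= 0:
        raise ValueError(
            f"ribosome density undefined for cytoplasmic count {cytoplasmic_count}"
        )
    return polysome_count(profile_row, scheme) / float(cytoplasmic_count)


def translation_efficiency(signal: float, cytoplasmic_level: float) -> float:
    """Ribosome-associated signal divided by cytoplasmic RNA level.

    Generic form of :func:`ribosome_density` for arbitrary signals such
    as ribosome-profiling counts.
    """
    if cytoplasmic_level <= 0:
        raise ValueError(
            f"translation efficiency undefined for cytoplasmic level {cytoplasmic_level}"
        )
    return float(signal) / float(cytoplasmic_level)


def _estimate_dispersion(
    counts: pd.DataFrame | np.ndarray,
    replicate_map: Mapping[str, str] | None = None,
) -> float:
    """Method-of-moments negative-binomial dispersion (size) estimate.

    Under NB noise ``var = mu + mu^2 / d``; pooling over rows (and over
    replicate groups when a map is given) gives
    ``d = sum(mu^2) / sum(var - mu)`` restricted to rows where the
    empirical variance exceeds the mean.  Falls back to a large value
    (Poisson-like) when no row shows overdispersion.
    """
    x = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    groups: list[np.ndarray]
    if replicate_map is not None and isinstance(counts, pd.DataFrame):
        by_fraction: dict[str, list[int]] = {}
        for j, col in enumerate(counts.columns):
            by_fraction.setdefault(replicate_map[col], []).append(j)
        groups = [x[:, idx] for idx in by_fraction.values() if len(idx) > 1]
        if not groups:
            groups = [x]
    else:
        groups = [x]
    num = 0.0
    den = 0.0
    for g in groups:
        mu = g.mean(axis=1)
        var = g.var(axis=1, ddof=1)
        excess = var - mu
        ok = excess > 0
        num += float((mu[ok] ** 2).sum())
        den += float(excess[ok].sum())
    if den <= 0 or num <= 0:
        return 1e6
    return float(np.clip(num / den, 0.1, 1e6))


def vst(
    counts: pd.DataFrame | np.ndarray | Sequence[float] | float,
    dispersion: float | None = None,
    replicate_map: Mapping[str, str] | None = None,
) -> pd.DataFrame | np.ndarray | float:
    """Variance-stabilizing transformation for overdispersed counts.

    Uses the analytic NB map ``2 * asinh(sqrt(x / d)) / ln 2`` where
    ``d`` is the dispersion (size) parameter of ``var = mu + mu^2/d``.
    The transform is strictly monotone, finite at zero, and approaches
    ``log2`` (plus a constant) for large counts while compressing low
    counts where Poisson noise dominates.  When ``dispersion`` is None
    it is estimated from the data by method of moments.
    """
    scalar = np.isscalar(counts)
    if isinstance(counts, pd.DataFrame):
        values = counts.to_numpy(dtype=float)
    else:
        values = np.asarray(counts, dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    if dispersion is None:
        if values.ndim < 2:
            dispersion = 1e6
        else:
            dispersion = _estimate_dispersion(
                counts if isinstance(counts, pd.DataFrame) else values,
                replicate_map,
            )
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    out = 2.0 * np.arcsinh(np.sqrt(values / dispersion)) / np.log(2.0)
    if scalar:
        return float(out)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


class VarianceStabilizer(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer wrapping :func:`vst`.

    Parameters
    ----------
    dispersion:
        NB size parameter; None estimates it at fit time by method of
        moments (using ``replicate_map`` to group replicate columns of a
        DataFrame when available).
    replicate_map:
        Optional mapping column label -> fraction type used for the
        dispersion estimate.
    """

    def __init__(
        self,
        dispersion: float | None = None,
        replicate_map: Mapping[str, str] | None = None,
    ) -> None:
        self.dispersion = dispersion
        self.replicate_map = replicate_map

    def fit(self, X, y=None):
        values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if np.any(values < 0):
            raise ValueError("counts must be nonnegative")
        if self.dispersion is not None:
            self.dispersion_ = float(self.dispersion)
        else:
            self.dispersion_ = _estimate_dispersion(
                X if isinstance(X, pd.DataFrame) else values, self.replicate_map
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "dispersion_")
        return vst(X, dispersion=self.dispersion_)


def filter_and_center(
    vst_matrix: pd.DataFrame,
    replicate_map: Mapping[str, str],
    mean_threshold: float = 1.0,
) -> pd.DataFrame:
    """Replicate-average, abundance-filter and mean-center VST values.

    Replicate columns of each fraction type are averaged; rows whose
    mean over the nine fraction types is not strictly greater than
    ``mean_threshold`` are removed; each surviving row has its mean
    subtracted, yielding relative expression values whose shape across
    the gradient — not overall abundance — drives downstream clustering.

    Returns a matrix with one column per fraction type, in gradient
    order, each retained row summing to zero mean.
    """
    missing = [c for c in vst_matrix.columns if c not in replicate_map]
    if missing:
        raise ValueError(f"replicate_map does not cover columns: {missing}")
    averaged = vst_matrix.T.groupby(
        vst_matrix.columns.map(replicate_map.__getitem__)
    ).mean().T
    order = [f for f in FRACTIONS if f in averaged.columns]
    extra = [c for c in averaged.columns if c not in FRACTIONS]
    averaged = averaged[order + extra]
    keep = averaged.mean(axis=1) > mean_threshold
    filtered = averaged.loc[keep]
    return filtered.sub(filtered.mean(axis=1), axis=0)


def threshold_by_reads(
    counts_matrix: pd.DataFrame,
    fractions: Iterable[str],
    min_reads: float = 100.0,
) -> pd.Index:
    """Isoforms with strictly more than ``min_reads`` in every named fraction.

    Column names are matched on their fraction prefix, so replicate
    columns (``p2_rep1`` ...) are each required to pass.  An empty
    fraction list is a vacuous filter: everything is retained.
    """
    fractions = list(fractions)
    if not fractions:
        return counts_matrix.index
    cols: list[str] = []
    for fraction in fractions:
        matched = [
            c
            for c in counts_matrix.columns
            if c == fraction or str(c).startswith(f"{fraction}_")
        ]
        if not matched:
            raise KeyError(f"fraction {fraction!r} not present in matrix columns")
        cols.extend(matched)
    mask = (counts_matrix[cols] > min_reads).all(axis=1)
    return counts_matrix.index[mask]
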