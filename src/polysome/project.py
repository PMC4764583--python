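"""Project external expression data onto reference polysome clusters.

Once a reference polysome-profile clustering exists, any external
transcript-level expression dataset quantified on the same annotation
can be interpreted through it: each expressed transcript inherits the
translational behavior of its reference cluster.  This module clusters
the external matrix (stage-averaged) with the same machinery used for
the reference, maps per-cell expressed transcript sets onto reference
clusters to give per-stage cluster occupancy percentages, and flags
isoform switches — genes whose isoforms both change external cluster
and sit on opposite sides of the high/low polysome divide, i.e. whose
isoform-level expression changes are predicted to change translational
output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from polysome.cluster import ClusterResult, ProfileClusterer

logger = logging.getLogger(__name__)

__all__ = [
    "StageMap",
    "IsoformSwitch",
    "cluster_external",
    "map_to_reference",
    "find_switches",
    "ReferenceProjector",
]


@dataclass
class StageMap:
    """Per-stage percentage of expressed transcripts in each cluster.

    ``mean`` and ``sd`` are stage x cluster tables; percentages within
    each cell sum to 100 before averaging across the cells of a stage,
    and the spread is the s.d. between single cells.
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    n_cells: pd.Series


@dataclass(frozen=True)
class IsoformSwitch:
    """A gene-linked isoform pair predicted to switch translational status."""

    gene_id: str
    isoform_a: str
    isoform_b: str
    external_cluster_a: int
    external_cluster_b: int
    reference_cluster_a: int
    reference_cluster_b: int
    direction: str  # low_to_high / high_to_low for a -> b


def cluster_external(
    matrix: pd.DataFrame,
    k: int = 7,
    stage_of: Mapping[str, str] | pd.Series | None = None,
) -> ClusterResult:
    """Cluster external transcript profiles across stages.

    Columns are averaged per stage when ``stage_of`` is given (cell ->
    stage); rows are then clustered exactly like reference polysome
    profiles (Spearman distance, Ward linkage).  Constant rows carry no
    rank information and are removed with a warning.
    """
    data = matrix
    if stage_of is not None:
        stage_series = (
            stage_of if isinstance(stage_of, pd.Series) else pd.Series(dict(stage_of))
        )
        data = matrix.T.groupby(matrix.columns.map(stage_series.to_dict().__getitem__)).mean().T
    constant = data.nunique(axis=1) <= 1
    if constant.any():
        logger.warning(
            "removing %d constant row(s) before external clustering", int(constant.sum())
        )
        data = data.loc[~constant]
    est = ProfileClusterer(n_clusters=k).fit(data)
    return est.result_


def map_to_reference(
    external: pd.DataFrame,
    reference_assignments: pd.Series,
    stage_of: Mapping[str, str] | pd.Series,
    expression_threshold: float = 1.0,
) -> StageMap:
    """Per-stage reference-cluster occupancy of expressed transcripts.

    For each cell (column), transcripts with expression strictly above
    ``expression_threshold`` (TPM > 1 by default) and present in the
    reference clustering are assigned their reference cluster; the
    percentage of expressed transcripts per cluster is computed per
    cell, then averaged within stages (s.d. across cells).  Transcripts
    absent from the reference clustering are excluded and logged.
    """
    stage_series = (
        stage_of if isinstance(stage_of, pd.Series) else pd.Series(dict(stage_of))
    )
    shared = external.index.intersection(reference_assignments.index)
    if shared.empty:
        raise ValueError("no shared transcript identifiers with the reference")
    dropped = len(external.index) - len(shared)
    if dropped:
        logger.info(
            "%d transcript(s) absent from the reference clustering were excluded",
            dropped,
        )
    sub = external.loc[shared]
    ref = reference_assignments.loc[shared]
    clusters = sorted(pd.unique(reference_assignments))
    per_cell = {}
    for cell in sub.columns:
        expressed = sub[cell] > expression_threshold
        n = int(expressed.sum())
        if n == 0:
            per_cell[cell] = pd.Series(np.nan, index=clusters)
            continue
        frac = ref[expressed].value_counts()
        per_cell[cell] = pd.Series(
            [100.0 * frac.get(c, 0) / n for c in clusters], index=clusters
        )
    cell_table = pd.DataFrame(per_cell).T  # cells x clusters
    stages = cell_table.index.map(stage_series.to_dict().__getitem__)
    grouped = cell_table.groupby(stages)
    mean = grouped.mean()
    sd = grouped.std(ddof=1).fillna(0.0)
    n_cells = grouped.size()
    return StageMap(mean=mean, sd=sd, n_cells=n_cells)


def find_switches(
    external_assignments: pd.Series,
    reference_assignments: pd.Series,
    high_clusters: Iterable[int],
    low_clusters: Iterable[int],
    gene_of: Mapping[str, str] | pd.Series,
) -> list[IsoformSwitch]:
    """Gene-linked isoform pairs that change translational status.

    A pair qualifies when both isoforms share a gene, fall in
    *different* external clusters (their expression behavior differs
    across the external conditions), and their reference polysome
    clusters lie on opposite sides of the high/low partition (the
    expression difference is predicted to matter for translation).
    """
    high = set(high_clusters)
    low = set(low_clusters)
    if high & low:
        raise ValueError("high and low cluster sets overlap")
    gene_map = gene_of if isinstance(gene_of, Mapping) else gene_of.to_dict()
    by_gene: dict[str, list[str]] = {}
    for iso in external_assignments.index:
        if iso in reference_assignments.index and iso in gene_map:
            by_gene.setdefault(gene_map[iso], []).append(iso)
    switches: list[IsoformSwitch] = []
    for gene in sorted(by_gene):
        isos = by_gene[gene]
        for i in range(len(isos)):
            for j in range(i + 1, len(isos)):
                a, b = isos[i], isos[j]
                ext_a, ext_b = external_assignments[a], external_assignments[b]
                if ext_a == ext_b:
                    continue
                ref_a, ref_b = reference_assignments[a], reference_assignments[b]
                if ref_a in high and ref_b in low:
                    direction = "high_to_low"
                elif ref_a in low and ref_b in high:
                    direction = "low_to_high"
                else:
                    continue
                switches.append(
                    IsoformSwitch(
                        gene_id=gene,
                        isoform_a=a,
                        isoform_b=b,
                        external_cluster_a=int(ext_a),
                        external_cluster_b=int(ext_b),
                        reference_cluster_a=int(ref_a),
                        reference_cluster_b=int(ref_b),
                        direction=direction,
                    )
                )
    return switches


def switches_to_frame(switches: Sequence[IsoformSwitch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "isoform_a": s.isoform_a,
                "isoform_b": s.isoform_b,
                "external_cluster_a": s.external_cluster_a,
                "external_cluster_b": s.external_cluster_b,
                "reference_cluster_a": s.reference_cluster_a,
                "reference_cluster_b": s.reference_cluster_b,
                "direction": s.direction,
            }
            for s in switches
        ],
        columns=[
            "gene_id",
            "isoform_a",
            "isoform_b",
            "external_cluster_a",
            "external_cluster_b",
            "reference_cluster_a",
            "reference_cluster_b",
            "direction",
        ],
    )


class ReferenceProjector(BaseEstimator):
    """Estimator-style wrapper: fit on reference assignments, transform
    an external matrix into a stage map.

    ``fit`` stores the reference clustering (a Series isoform ->
    cluster) plus the high/low partition; ``transform`` maps an
    external expression matrix (with a cell -> stage map) onto the
    reference clusters; ``find_switches`` combines an external
    clustering with the stored reference.
    """

    def __init__(self, expression_threshold: float = 1.0) -> None:
        self.expression_threshold = expression_threshold

    def fit(
        self,
        reference_assignments: pd.Series,
        high_clusters: Iterable[int] = (),
        low_clusters: Iterable[int] = (),
    ):
        self.reference_assignments_ = reference_assignments
        self.high_clusters_ = set(high_clusters)
        self.low_clusters_ = set(low_clusters)
        return self

    def transform(
        self, external: pd.DataFrame, stage_of: Mapping[str, str] | pd.Series
    ) -> StageMap:
        return map_to_reference(
            external,
            self.reference_assignments_,
            stage_of,
            expression_threshold=self.expression_threshold,
        )

    def find_switches(
        self,
        external_assignments: pd.Series,
        gene_of: Mapping[str, str] | pd.Series,
    ) -> list[IsoformSwitch]:
        return find_switches(
            external_assignments,
            self.reference_assignments_,
            self.high_clusters_,
            self.low_clusters_,
            gene_of,
        )
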