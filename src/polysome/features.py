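"""Transcript region decomposition and the isoform feature registry.

Each transcript is decomposed into its 5' leader (the sequence upstream
of the start codon), coding sequence, and 3' UTR, and a fixed registry
of 24 features with documented translational relevance is tabulated per
isoform: region lengths and GC content, exon count, 5' leader
secondary-structure proxies at the cap and in sliding 75-nt windows,
codon-usage statistics including rare-codon stretches, the AU-element
fraction of the 3' UTR, cognate and near-cognate upstream ORFs, miRNA
target-site counts and scores (optionally restricted to an expressed
miRNA set), mRNA half-life, and cytoplasmic / polysome expression.

Coordinates are GTF-style 1-based inclusive at I/O boundaries and
0-based half-open internally; minus-strand regions are extracted from
the reverse-complemented splice product.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptModel",
    "AuxTables",
    "decompose",
    "au_element_fraction",
    "codon_window_stats",
    "scan_uorfs",
    "uorf_density",
    "structure_scores",
    "nussinov_max_pairs",
    "mirna_site_stats",
    "tabulate",
    "FEATURE_COLUMNS",
    "NEAR_COGNATE_STARTS",
    "STOP_CODONS",
]

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

STOP_CODONS = ("TAA", "TAG", "TGA")

#: Near-cognate start codons scored as non-cognate uORF starts.
NEAR_COGNATE_STARTS = ("CTG", "GTG", "TTG", "ACG", "ATA", "ATT", "ATC")

#: Canonical column order of the per-isoform feature table.
FEATURE_COLUMNS = (
    "leader_length",
    "cds_length",
    "utr3_length",
    "transcript_length",
    "leader_gc",
    "cds_gc",
    "utr3_gc",
    "transcript_gc",
    "exon_count",
    "cap_structure_score",
    "min_window_structure_score",
    "mean_codon_frequency",
    "min_window_codon_frequency",
    "rare_codon_stretches",
    "au_element_fraction",
    "cognate_uorfs",
    "noncognate_uorfs",
    "mirna_site_count",
    "mirna_context_score",
    "mirna_site_count_expressed",
    "mirna_context_score_expressed",
    "half_life",
    "cytoplasmic_expression",
    "median_polysome_expression",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class TranscriptModel:
    """A transcript decomposed into leader / CDS / 3' UTR.

    Genomic intervals are 0-based half-open on the forward strand;
    region sequences are in transcript (5'->3') orientation.  For
    noncoding transcripts ``cds_span`` is None and the leader / UTR
    sequences are empty with ``coding`` False.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int] | None
    sequence: str
    leader: str
    cds: str
    utr3: str
    coding: bool = True

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if self.coding:
            if len(self.leader) + len(self.cds) + len(self.utr3) != len(self.sequence):
                raise ValueError(
                    f"{self.transcript_id}: region lengths do not sum to transcript length"
                )
            if len(self.cds) % 3 != 0:
                raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")
            if not self.cds.upper().startswith("ATG"):
                raise ValueError(f"{self.transcript_id}: CDS does not begin with ATG")
            if self.cds.upper()[-3:] not in STOP_CODONS:
                raise ValueError(f"{self.transcript_id}: CDS does not end in a stop codon")


def _splice_index(exons: Sequence[tuple[int, int]], genomic_pos: int) -> int:
    """Map a genomic position to its offset in the forward-strand splice."""
    offset = 0
    for start, end in exons:
        if start <= genomic_pos < end:
            return offset + (genomic_pos - start)
        offset += end - start
    raise ValueError(f"genomic position {genomic_pos} not inside any exon")


def decompose(
    transcript_id: str,
    gene_id: str,
    chrom: str,
    strand: str,
    exons: Sequence[tuple[int, int]],
    cds_span: tuple[int, int] | None,
    chrom_sequence: str,
    validate: bool = True,
) -> TranscriptModel:
    """Extract leader / CDS / 3' UTR sequences from genomic annotation.

    ``exons`` and ``cds_span`` are 0-based half-open genomic intervals
    (the GTF readers convert from 1-based inclusive); ``cds_span`` spans
    start codon through stop codon.  Exons must be non-overlapping; the
    CDS must lie within the exon span.  On the minus strand the spliced
    forward sequence is reverse-complemented and the leader is taken
    from the 3' genomic side.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be + or -, got {strand!r}")
    exons = sorted((int(s), int(e)) for s, e in exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 > s2:
            raise ValueError(f"{transcript_id}: overlapping exons")
    for s, e in exons:
        if not (0 <= s < e <= len(chrom_sequence)):
            raise ValueError(f"{transcript_id}: exon ({s},{e}) outside sequence")
    spliced_fwd = "".join(chrom_sequence[s:e] for s, e in exons)
    sequence = spliced_fwd if strand == "+" else reverse_complement(spliced_fwd)
    n = len(sequence)

    if cds_span is None:
        model = TranscriptModel(
            transcript_id, gene_id, chrom, strand, exons, None,
            sequence, "", "", "", coding=False,
        )
        return model

    gs, ge = int(cds_span[0]), int(cds_span[1])
    t1 = _splice_index(exons, gs)
    t2 = _splice_index(exons, ge - 1) + 1
    if strand == "+":
        leader, cds, utr3 = sequence[:t1], sequence[t1:t2], sequence[t2:]
    else:
        leader, cds, utr3 = sequence[: n - t2], sequence[n - t2 : n - t1], sequence[n - t1 :]
    model = TranscriptModel(
        transcript_id, gene_id, chrom, strand, exons, (gs, ge),
        sequence, leader, cds, utr3, coding=True,
    )
    if validate:
        model.validate()
    return model


def au_element_fraction(utr_sequence: str, min_run: int = 6) -> float:
    """Fraction of a 3' UTR covered by long A/U-only runs.

    A qualifying run is a maximal stretch of only A or U (T) longer
    than five nucleotides (>= ``min_run``); the returned value is the
    total nucleotides inside qualifying runs divided by UTR length.
    AU-rich stretches are binding platforms for destabilizing and
    translationally repressive RNA-binding proteins.
    """
    if not utr_sequence:
        raise ValueError("empty sequence: AU-element fraction undefined")
    s = utr_sequence.upper().replace("U", "T")
    if re.search(r"[^ACGT]", s):
        raise ValueError("sequence contains non-ACGT/U characters")
    covered = sum(len(m) for m in re.findall(r"[AT]+", s) if len(m) >= min_run)
    return covered / len(s)


def codon_window_stats(
    cds_sequence: str,
    usage_table: Mapping[str, float],
    window: int = 5,
    rare_quantile: float = 0.10,
    min_stretch: int = 3,
) -> tuple[float, float, int]:
    """Codon-usage statistics over a coding sequence.

    Returns ``(mean_frequency, min_window_frequency, rare_stretches)``:
    the mean usage over all codons, the minimum over sliding
    ``window``-codon means (CDSs shorter than the window use one
    full-length window), and the number of maximal runs of at least
    ``min_stretch`` consecutive codons whose usage falls below the
    ``rare_quantile`` quantile of the usage table.  Usage values are
    conventionally occurrences per thousand codons.
    """
    s = cds_sequence.upper().replace("U", "T")
    if len(s) % 3 != 0:
        raise ValueError(f"CDS length {len(s)} not divisible by 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if not codons:
        raise ValueError("empty CDS")
    try:
        freqs = np.array([usage_table[c] for c in codons], dtype=float)
    except KeyError as exc:
        raise KeyError(f"codon {exc.args[0]!r} absent from usage table") from None
    mean_freq = float(freqs.mean())
    w = min(window, len(freqs))
    window_means = np.convolve(freqs, np.ones(w) / w, mode="valid")
    min_window = float(window_means.min())
    threshold = float(np.quantile(list(usage_table.values()), rare_quantile))
    rare = freqs < threshold
    stretches = 0
    run = 0
    for flag in np.append(rare, False):
        if flag:
            run += 1
        else:
            if run >= min_stretch:
                stretches += 1
            run = 0
    return mean_freq, min_window, stretches


@dataclass(frozen=True)
class UorfCall:
    start: int
    end: int  # half-open, includes the stop codon
    start_codon: str
    cognate: bool


def scan_uorfs(
    leader_sequence: str,
    mode: str = "scan",
    table: pd.DataFrame | None = None,
    transcript_id: str | None = None,
    near_cognate: Sequence[str] = NEAR_COGNATE_STARTS,
    boundary: int | None = None,
) -> list[UorfCall]:
    """Upstream ORFs in a 5' leader.

    In ``scan`` mode every ATG (cognate) or near-cognate start with an
    in-frame stop codon before ``boundary`` (default: end of leader)
    yields a call.  In ``table`` mode, externally determined uORF
    records (columns transcript_id, start, end, start_codon) that fall
    within the leader are returned instead.
    """
    s = leader_sequence.upper().replace("U", "T")
    if mode == "table":
        if table is None:
            raise ValueError("table mode requires a uORF table")
        sub = table[table["transcript_id"] == transcript_id]
        if transcript_id is None:
            raise ValueError("table mode requires transcript_id")
        calls = []
        for _, row in sub.iterrows():
            if 0 <= int(row["start"]) < len(s):
                codon = str(row["start_codon"]).upper()
                calls.append(
                    UorfCall(int(row["start"]), int(row["end"]), codon, codon == "ATG")
                )
        return calls
    if mode != "scan":
        raise ValueError(f"unknown mode {mode!r}")
    limit = len(s) if boundary is None else min(boundary, len(s))
    near = set(c.upper() for c in near_cognate)
    calls: list[UorfCall] = []
    for i in range(0, len(s) - 2):
        codon = s[i : i + 3]
        if codon != "ATG" and codon not in near:
            continue
        for j in range(i + 3, limit - 2, 3):
            if s[j : j + 3] in STOP_CODONS:
                calls.append(UorfCall(i, j + 3, codon, codon == "ATG"))
                break
    return calls


def uorf_density(
    cluster_isoforms: Sequence[str],
    uorf_calls: Mapping[str, Sequence[UorfCall]],
) -> tuple[float, float]:
    """uORFs per 100 isoforms, split (cognate, non-cognate)."""
    if not len(cluster_isoforms):
        raise ValueError("empty cluster")
    cognate = 0
    noncognate = 0
    for iso in cluster_isoforms:
        for call in uorf_calls.get(iso, ()):
            if call.cognate:
                cognate += 1
            else:
                noncognate += 1
    scale = 100.0 / len(cluster_isoforms)
    return cognate * scale, noncognate * scale


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested base pairs (Watson-Crick plus GU wobble).

    Dynamic program over subsequences with a minimum hairpin loop of
    ``min_loop`` unpaired nucleotides.  A fast structure proxy: more
    pairable sequence implies more potential secondary structure.
    """
    s = seq.upper().replace("U", "T")
    if re.search(r"[^ACGT]", s):
        raise ValueError("sequence contains non-nucleotide characters")
    n = len(s)
    if n == 0:
        return 0
    enc = np.frombuffer(s.encode(), dtype=np.uint8)
    # pairable[a, b]: can positions a and b pair
    lut = np.zeros((256, 256), dtype=bool)
    for a, b in _PAIRS:
        lut[ord(a), ord(b)] = True
    pairable = lut[np.ix_(enc, enc)]
    # dp[i, j] = max pairs in s[i:j] (half-open); fill by span length
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 2, n + 1):
        i = np.arange(0, n - span + 1)
        j = i + span
        best = dp[i, j - 1]
        # pair last char (index j-1) with k = i+m, m in [0, span-min_loop-2]
        for m in range(0, span - min_loop - 1):
            k = i + m
            cand = dp[i, k] + 1 + dp[k + 1, j - 1]
            ok = pairable[k, j - 1]
            best = np.where(ok, np.maximum(best, cand), best)
        dp[i, j] = best
    return int(dp[0, n])


def structure_scores(
    leader_sequence: str,
    window: int = 75,
    backend: Callable[[str], float] | None = None,
) -> tuple[float, float]:
    """Secondary-structure proxy at the cap and across the leader.

    The leader is scanned in sliding windows (step 1); ``cap_score`` is
    the score of the 5'-most window and ``min_window_score`` the
    minimum over all windows.  Leaders shorter than the window are
    scored as one whole-leader window.  The default backend negates the
    maximum base-pair count (:func:`nussinov_max_pairs`) so that lower
    scores mean more structure, matching the sign convention of folding
    free energies; a thermodynamic folder can be plugged in as
    ``backend``.
    """
    if not leader_sequence:
        raise ValueError("empty leader")
    score = backend or (lambda s: -float(nussinov_max_pairs(s)))
    n = len(leader_sequence)
    if n <= window:
        value = float(score(leader_sequence))
        return value, value
    scores = [float(score(leader_sequence[i : i + window])) for i in range(n - window + 1)]
    return scores[0], min(scores)


def mirna_site_stats(
    three_utr_interval: tuple[int, int],
    site_table: pd.DataFrame,
    expressed_set: Iterable[str] | None = None,
) -> tuple[int, float, int, float]:
    """Counts and summed context scores of miRNA sites in a 3' UTR.

    ``three_utr_interval`` is 0-based half-open in transcript
    coordinates; a site counts if it overlaps the interval.  Returns
    ``(count_all, score_all, count_expressed, score_expressed)``; the
    expressed-filtered pair restricts to miRNAs in ``expressed_set``
    (and is NaN-free zero when the set is provided but empty).
    """
    required = {"site_start", "site_end", "miRNA_id", "context_score"}
    missing = required - set(site_table.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    lo, hi = three_utr_interval
    if len(site_table) == 0:
        return 0, 0.0, 0, 0.0
    starts = site_table["site_start"].to_numpy(dtype=float)
    ends = site_table["site_end"].to_numpy(dtype=float)
    overlap = (starts < hi) & (ends > lo)
    hits = site_table.loc[overlap]
    count_all = int(len(hits))
    score_all = float(hits["context_score"].sum())
    if expressed_set is None:
        return count_all, score_all, count_all, score_all
    expressed = hits[hits["miRNA_id"].isin(set(expressed_set))]
    return count_all, score_all, int(len(expressed)), float(expressed["context_score"].sum())


@dataclass
class AuxTables:
    """Auxiliary per-transcript evidence consumed by :func:`tabulate`.

    codon_usage: codon -> occurrences per thousand.
    mirna_sites: table with transcript_id, site_start, site_end,
        miRNA_id, context_score (transcript coordinates).
    half_life: transcript_id -> hours.
    uorfs: optional experimentally determined uORF table
        (transcript_id, start, end, start_codon); when present, uORF
        counting uses it instead of sequence scanning.
    expressed_mirnas: optional set restricting the expressed-filtered
        miRNA statistics.
    """

    codon_usage: Mapping[str, float]
    mirna_sites: pd.DataFrame | None = None
    half_life: Mapping[str, float] | pd.Series | None = None
    uorfs: pd.DataFrame | None = None
    expressed_mirnas: set[str] | None = None


def tabulate(
    models: Sequence[TranscriptModel],
    matrix: pd.DataFrame | None = None,
    aux: AuxTables | None = None,
    structure_backend: Callable[[str], float] | None = None,
    structure_window: int = 75,
) -> pd.DataFrame:
    """Assemble the per-isoform feature table.

    ``matrix`` is a replicate-averaged expression matrix with the nine
    fraction columns; cytoplasmic expression is its ``cyto`` column and
    median polysome expression the median over the eight
    ribosome-containing fractions.  Missing evidence (no half-life
    record, noncoding transcript) yields missing values, never zero.
    """
    from polysome.quantify import RIBO_FRACTIONS

    aux = aux or AuxTables(codon_usage={})
    half_life = (
        dict(aux.half_life) if aux.half_life is not None else {}
    )
    sites_by_tx: dict[str, pd.DataFrame] = {}
    if aux.mirna_sites is not None and len(aux.mirna_sites):
        sites_by_tx = {
            str(tx): sub for tx, sub in aux.mirna_sites.groupby("transcript_id")
        }
    empty_sites = pd.DataFrame(
        columns=["transcript_id", "site_start", "site_end", "miRNA_id", "context_score"]
    )

    rows = []
    for model in models:
        tx = model.transcript_id
        row: dict[str, float] = {c: np.nan for c in FEATURE_COLUMNS}
        row["transcript_length"] = model.length
        row["transcript_gc"] = gc_fraction(model.sequence)
        row["exon_count"] = model.exon_count
        if model.coding:
            row["leader_length"] = len(model.leader)
            row["cds_length"] = len(model.cds)
            row["utr3_length"] = len(model.utr3)
            row["leader_gc"] = gc_fraction(model.leader)
            row["cds_gc"] = gc_fraction(model.cds)
            row["utr3_gc"] = gc_fraction(model.utr3)
            if model.leader:
                cap, min_win = structure_scores(
                    model.leader, window=structure_window, backend=structure_backend
                )
                row["cap_structure_score"] = cap
                row["min_window_structure_score"] = min_win
            if aux.codon_usage and model.cds:
                mean_f, min_f, rare = codon_window_stats(model.cds, aux.codon_usage)
                row["mean_codon_frequency"] = mean_f
                row["min_window_codon_frequency"] = min_f
                row["rare_codon_stretches"] = rare
            if model.utr3:
                row["au_element_fraction"] = au_element_fraction(model.utr3)
            if model.leader:
                if aux.uorfs is not None:
                    calls = scan_uorfs(
                        model.leader, mode="table", table=aux.uorfs, transcript_id=tx
                    )
                else:
                    calls = scan_uorfs(model.leader)
                row["cognate_uorfs"] = sum(1 for c in calls if c.cognate)
                row["noncognate_uorfs"] = sum(1 for c in calls if not c.cognate)
            utr_lo = len(model.leader) + len(model.cds)
            count_a, score_a, count_e, score_e = mirna_site_stats(
                (utr_lo, model.length),
                sites_by_tx.get(tx, empty_sites),
                aux.expressed_mirnas,
            )
            row["mirna_site_count"] = count_a
            row["mirna_context_score"] = score_a
            row["mirna_site_count_expressed"] = count_e
            row["mirna_context_score_expressed"] = score_e
        if tx in half_life:
            row["half_life"] = float(half_life[tx])
        if matrix is not None and tx in matrix.index:
            if "cyto" in matrix.columns:
                row["cytoplasmic_expression"] = float(matrix.at[tx, "cyto"])
            ribo_cols = [f for f in RIBO_FRACTIONS if f in matrix.columns]
            if ribo_cols:
                row["median_polysome_expression"] = float(
                    matrix.loc[tx, ribo_cols].median()
                )
        rows.append(pd.Series(row, name=tx))
    table = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    table.index.name = "transcript_id"
    return table
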