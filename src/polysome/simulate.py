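"""Synthetic polysome-profiling data with planted ground truth.

Generates every input the analysis consumes — an isoform x fraction
count matrix with negative-binomial replicate noise, a matching toy
annotation (GTF-style models plus genome and transcript sequences) with
planted feature differences between isoforms of the same gene, the
auxiliary evidence tables, and an external stage x cell expression
matrix with planted isoform switches — together with truth tables so
downstream stages can be validated by recovery.

The generator plants distinct translational classes as *archetypes*:
relative abundance shapes across the eight ribosome-containing
fractions (80S monosome through the eight-plus pool), mirroring the
empirical picture that isoforms are predominantly either well or poorly
ribosome-associated, with a spread of intermediate behaviors.  The
cytoplasmic sample is a mixture of the ribosome-fraction signal plus a
free cytoplasmic-only term, so ribosome density is an independent
planted parameter.  Gene-linked isoform pairs spanning the high/low
divide receive the planted regulatory differences: the low-polysome
member gets a longer 3' UTR (defaults mean 1551 nt versus 982 nt), more
AU-element runs, denser miRNA sites, shorter half-life, and a cognate
uORF at a higher rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from polysome.features import (
    STOP_CODONS,
    AuxTables,
    TranscriptModel,
    decompose,
    reverse_complement,
)
from polysome.quantify import FRACTIONS

__all__ = [
    "Archetype",
    "SyntheticAnnotation",
    "ExternalDataset",
    "make_archetypes",
    "simulate_counts",
    "simulate_annotation",
    "simulate_external",
    "replicate_map_for",
]

_NT = np.array(list("ACGT"))
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]


@dataclass(frozen=True)
class Archetype:
    """A planted translational class.

    ``fraction_weights`` holds nine nonnegative reals — relative
    expected abundance in (cyto, mono, p2..p7, p8plus) — with the eight
    ribosome-containing weights normalized to sum to one.  The
    cytoplasmic weight is free: it is the mixture share of the
    ribosome-fraction signal plus a cytoplasmic-only excess, so poorly
    translated classes can carry disproportionate free mRNA.
    """

    name: str
    fraction_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.fraction_weights, dtype=float)
        if w.shape != (9,):
            raise ValueError("fraction_weights must have 9 entries")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        ribo = w[1:]
        if ribo.sum() <= 0:
            raise ValueError("at least one ribosome-fraction weight must be positive")
        if not np.isclose(ribo.sum(), 1.0, atol=1e-8):
            raise ValueError("ribosome-fraction weights must sum to 1")

    @property
    def ribo_weights(self) -> np.ndarray:
        return np.asarray(self.fraction_weights[1:], dtype=float)

    @property
    def cyto_weight(self) -> float:
        return float(self.fraction_weights[0])

    @property
    def mean_ribosome_load(self) -> float:
        """Expected ribosomes per transcript under this shape (8+ read as 24)."""
        loads = np.array([1, 2, 3, 4, 5, 6, 7, 24], dtype=float)
        return float((self.ribo_weights * loads).sum())


# Shape library (relative abundance over mono, p2..p7, p8plus) spanning
# high-polysome-skewed, mid, monosome-skewed and low-polysome classes;
# all pairwise Spearman correlations of the vectors are below 0.95, and
# the first two span the high/low extremes so small k remains maximally
# contrasted.
_SHAPES: list[tuple[str, list[float]]] = [
    ("high_peak", [0.02, 0.04, 0.06, 0.08, 0.40, 0.75, 1.00, 0.30]),
    ("low_peak", [0.22, 1.00, 0.45, 0.25, 0.06, 0.03, 0.04, 0.02]),
    ("mid_high", [0.03, 0.07, 0.12, 0.18, 1.00, 0.80, 0.45, 0.20]),
    ("low_mid", [0.10, 0.45, 1.00, 0.45, 0.08, 0.04, 0.03, 0.06]),
    ("mid", [0.06, 0.15, 0.45, 1.00, 0.25, 0.10, 0.05, 0.03]),
    ("monosome", [1.00, 0.12, 0.05, 0.03, 0.02, 0.02, 0.02, 0.04]),
    ("plateau_high", [0.20, 0.09, 0.11, 0.14, 0.60, 0.90, 0.95, 1.00]),
    ("bimodal", [0.45, 1.00, 0.50, 0.25, 0.30, 0.70, 0.90, 0.55]),
    ("ramp_up", [0.20, 0.30, 0.40, 0.50, 0.62, 0.75, 0.88, 1.00]),
    ("ramp_down", [1.00, 0.88, 0.75, 0.62, 0.50, 0.40, 0.30, 0.20]),
    ("ends_up", [0.95, 0.85, 0.80, 0.78, 0.80, 0.85, 0.90, 1.00]),
    ("broad_low", [0.45, 0.80, 1.00, 0.90, 0.60, 0.35, 0.20, 0.50]),
]

# Default population share of each class among simulated isoforms.  The
# population is deliberately bimodal — most isoforms are either well or
# poorly ribosome-associated, with a distinct monosome-dominated pool
# (short ORFs, noncoding-like species) — which is what makes the 80S
# sample cluster apart from both low- and high-polysome fractions.
_POPULATION_SHARES: dict[str, float] = {
    "high_peak": 0.16,
    "low_peak": 0.14,
    "mid_high": 0.12,
    "low_mid": 0.12,
    "mid": 0.12,
    "monosome": 0.20,
    "plateau_high": 0.10,
    "bimodal": 0.04,
    "ramp_up": 0.05,
    "ramp_down": 0.05,
    "ends_up": 0.05,
    "broad_low": 0.05,
}


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.stats import spearmanr

    return float(spearmanr(a, b).statistic)


def make_archetypes(k: int, max_rho: float = 0.95) -> list[Archetype]:
    """``k`` distinct fraction-distribution archetypes.

    Shapes are drawn from a fixed library ordered so small ``k`` spans
    the high/low extremes first (k=2 gives one class peaked in the
    five-to-eight-plus fractions and one peaked at the 80S to
    two-ribosome end).  Construction verifies that all pairwise
    Spearman correlations of the ribosome weight vectors are below
    ``max_rho``.
    """
    if not 2 <= k <= len(_SHAPES):
        raise ValueError(f"k must be between 2 and {len(_SHAPES)}, got {k}")
    chosen = _SHAPES[:k]
    ribo = [np.asarray(w, dtype=float) / np.sum(w) for _, w in chosen]
    for i in range(k):
        for j in range(i + 1, k):
            rho = _spearman(ribo[i], ribo[j])
            if rho >= max_rho:
                raise RuntimeError(
                    f"archetypes {chosen[i][0]} and {chosen[j][0]} are too "
                    f"similar (Spearman rho={rho:.3f})"
                )
    loads = np.array([1, 2, 3, 4, 5, 6, 7, 24], dtype=float)
    out = []
    for (name, _), w in zip(chosen, ribo):
        load = float((w * loads).sum())
        # cytoplasmic excess shrinks with ribosome load: well-translated
        # mRNAs are mostly ribosome-engaged, poorly translated ones pool
        # as free cytoplasmic mRNA
        cyto = 0.5 + 1.2 * np.exp(-load / 6.0)
        out.append(Archetype(name=name, fraction_weights=(cyto, *w.tolist())))
    return out


def split_high_low(archetypes: Sequence[Archetype]) -> tuple[list[str], list[str]]:
    """Partition archetype names into high- and low-polysome halves by load."""
    ranked = sorted(archetypes, key=lambda a: a.mean_ribosome_load, reverse=True)
    half = len(ranked) // 2
    high = [a.name for a in ranked[:half]]
    low = [a.name for a in ranked[half:]]
    return high, low


def replicate_map_for(columns: Sequence[str]) -> dict[str, str]:
    """Map ``<fraction>_<rep>`` column labels to their fraction type."""
    out = {}
    for col in columns:
        fraction = str(col).rsplit("_", 1)[0]
        if fraction not in FRACTIONS:
            raise ValueError(f"column {col!r} has no recognizable fraction prefix")
        out[col] = fraction
    return out


def simulate_counts(
    archetypes: Sequence[Archetype],
    n_genes: int = 200,
    isoforms_per_gene: Mapping[int, float] | None = None,
    depth: float = 1e6,
    dispersion: float = 10.0,
    n_replicates: int = 2,
    seed: int | None = None,
    abundance_sigma: float = 1.0,
    archetype_probs: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an isoform x sample count matrix with planted classes.

    Each isoform draws a relative abundance (log-normal, scale
    ``abundance_sigma``) and an archetype; its expected count in
    ribosome fraction f is ``8 * depth * p_i * w_f`` (so an average
    sample totals ~``depth`` reads) and its cytoplasmic expectation is
    the archetype's cytoplasmic weight times the same base.  Replicates
    share expectations; observed counts are negative-binomial with size
    ``dispersion`` (large dispersion approaches Poisson).

    Returns ``(counts, truth)``: counts with columns
    ``<fraction>_rep<r>`` over the nine fraction types, and a truth
    table with gene, archetype and planted feature classes per isoform.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if not archetypes:
        raise ValueError("need at least one archetype")
    rng = np.random.default_rng(seed)
    iso_dist = isoforms_per_gene or {2: 0.5, 3: 0.3, 4: 0.2}
    ks = np.array(sorted(iso_dist))
    probs = np.array([iso_dist[k] for k in ks], dtype=float)
    probs = probs / probs.sum()

    by_name = {a.name: a for a in archetypes}
    high_names, low_names = split_high_low(archetypes)
    names = [a.name for a in archetypes]
    shares = archetype_probs or {
        n: _POPULATION_SHARES.get(n, 1.0 / len(names)) for n in names
    }
    arch_p = np.array([shares[n] for n in names], dtype=float)
    arch_p = arch_p / arch_p.sum()

    records = []
    for g in range(n_genes):
        gene = f"G{g + 1:04d}"
        n_iso = int(rng.choice(ks, p=probs))
        arch_idx = rng.choice(len(archetypes), size=n_iso, p=arch_p)
        for t in range(n_iso):
            arch = names[arch_idx[t]]
            side = "low" if arch in low_names else "high"
            records.append(
                {
                    "isoform_id": f"{gene}.T{t + 1}",
                    "gene_id": gene,
                    "archetype": arch,
                    "translational_side": side,
                    "utr3_class": "long" if side == "low" else "short",
                    "uorf_config": "cognate"
                    if rng.random() < (0.35 if side == "low" else 0.10)
                    else "none",
                    "au_class": "high" if side == "low" else "low",
                }
            )
    truth = pd.DataFrame.from_records(records).set_index("isoform_id")

    n_iso_total = len(truth)
    abundance = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_iso_total)
    p = abundance / abundance.sum()
    ribo_w = np.vstack([by_name[a].ribo_weights for a in truth["archetype"]])
    cyto_w = np.array([by_name[a].cyto_weight for a in truth["archetype"]])
    base = 8.0 * depth * p
    mu = np.column_stack([base * cyto_w, ribo_w * base[:, None]])  # 9 fraction types

    columns = []
    data = []
    for rep in range(1, n_replicates + 1):
        draw = rng.negative_binomial(
            dispersion, dispersion / (dispersion + np.where(mu > 0, mu, 1e-12))
        )
        draw = np.where(mu > 0, draw, 0)
        data.append(draw)
        columns.extend(f"{f}_rep{rep}" for f in FRACTIONS)
    # interleave so columns group by replicate then fraction -> reorder to
    # fraction-major for readability
    counts = pd.DataFrame(
        np.concatenate(data, axis=1), index=truth.index, columns=columns
    )
    ordered = [f"{f}_rep{r}" for f in FRACTIONS for r in range(1, n_replicates + 1)]
    counts = counts[ordered].astype(np.int64)
    counts.index.name = "isoform_id"
    return counts, truth


@dataclass
class SyntheticAnnotation:
    """Toy annotation bundle: models, sequences, GTF records, evidence."""

    models: list[TranscriptModel]
    genome: dict[str, str]
    gtf: pd.DataFrame
    aux: AuxTables
    planted_uorfs: pd.DataFrame


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _strip_starts(seq: str, rng: np.random.Generator) -> str:
    """Remove ATG triplets (any frame) so uORF planting stays controlled."""
    s = list(seq)
    for i in range(len(s) - 2):
        if s[i] == "A" and s[i + 1] == "T" and s[i + 2] == "G":
            s[i + 2] = "C"
    return "".join(s)


def _random_cds(rng: np.random.Generator, n_codons: int, usage_probs: np.ndarray) -> str:
    codons = rng.choice(_SENSE_CODONS, size=n_codons, p=usage_probs)
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(codons) + stop


def _insert_au_runs(seq: str, n_runs: int, rng: np.random.Generator) -> str:
    s = seq
    for _ in range(n_runs):
        run_len = int(rng.integers(6, 13))
        run = "".join(np.array(["A", "T"])[rng.integers(0, 2, size=run_len)])
        pos = int(rng.integers(0, max(len(s) - run_len, 1)))
        s = s[:pos] + run + s[pos + run_len :]
    return s


def simulate_annotation(
    truth: pd.DataFrame,
    seed: int | None = None,
    utr3_mean_low: float = 1551.0,
    utr3_mean_high: float = 982.0,
    utr3_cv: float = 0.25,
    leader_length_range: tuple[int, int] = (60, 110),
    cds_codon_range: tuple[int, int] = (50, 150),
    intron_length_range: tuple[int, int] = (50, 200),
    n_mirnas: int = 30,
) -> SyntheticAnnotation:
    """Toy genome, transcript models and evidence tables realizing ``truth``.

    Isoforms flagged ``utr3_class == 'long'`` draw 3' UTR lengths around
    ``utr3_mean_low`` (gamma, CV ``utr3_cv``), the rest around
    ``utr3_mean_high``; long-UTR isoforms also receive denser AU runs,
    more miRNA sites, shorter half-lives, and planted cognate uORFs per
    ``uorf_config``.  Every gene gets its own contig; isoforms are laid
    out sequentially (no exon sharing — splice-graph realism is out of
    scope) with one to three exons each, on a per-gene random strand.
    CDS sequences always begin ATG, end in a stop, and have length
    divisible by three.
    """
    required = {"gene_id", "utr3_class", "uorf_config", "au_class"}
    if not required <= set(truth.columns):
        raise ValueError(f"truth table must have columns {sorted(required)}")
    if truth["gene_id"].isna().any():
        raise ValueError("isoform without gene in truth table")
    rng = np.random.default_rng(seed)

    # deterministic synthetic codon-usage table (per-thousand, sums to 1000)
    usage_raw = rng.gamma(2.0, 1.0, size=len(_CODONS))
    usage = dict(zip(_CODONS, (usage_raw / usage_raw.sum() * 1000.0).tolist()))
    sense_probs = np.array([usage[c] for c in _SENSE_CODONS])
    sense_probs = sense_probs / sense_probs.sum()

    mirna_pool = [f"miR-{i + 1:03d}" for i in range(n_mirnas)]
    expressed = set(mirna_pool[: n_mirnas // 2])

    models: list[TranscriptModel] = []
    gtf_rows: list[dict] = []
    site_rows: list[dict] = []
    half_rows: list[dict] = []
    uorf_rows: list[dict] = []
    genome: dict[str, str] = {}

    for gene, sub in truth.groupby("gene_id", sort=True):
        chrom = f"chr_{gene}"
        strand = "+" if rng.random() < 0.5 else "-"
        contig_parts: list[str] = []
        cursor = 0

        for isoform_id, row in sub.iterrows():
            long_utr = row["utr3_class"] == "long"
            leader_len = int(rng.integers(*leader_length_range))
            leader = _strip_starts(_random_seq(rng, leader_len), rng)
            if row["uorf_config"] == "cognate":
                cassette = (
                    "ATG"
                    + "".join(rng.choice(_SENSE_CODONS, size=int(rng.integers(2, 5))))
                    + STOP_CODONS[rng.integers(0, 3)]
                )
                pos = int(rng.integers(0, max(leader_len - len(cassette) - 3, 1)))
                leader = leader[:pos] + cassette + leader[pos + len(cassette) :]
                uorf_rows.append(
                    {
                        "transcript_id": isoform_id,
                        "start": pos,
                        "end": pos + len(cassette),
                        "start_codon": "ATG",
                    }
                )
            cds = _random_cds(rng, int(rng.integers(*cds_codon_range)), sense_probs)
            mean_utr = utr3_mean_low if long_utr else utr3_mean_high
            shape = 1.0 / utr3_cv**2
            utr_len = max(int(rng.gamma(shape, mean_utr / shape)), 30)
            utr3 = _random_seq(rng, utr_len)
            au_rate = utr_len / 300.0 if row.get("au_class") == "high" else utr_len / 900.0
            utr3 = _insert_au_runs(utr3, int(rng.poisson(au_rate)), rng)
            transcript = leader + cds + utr3

            # exon layout over the forward-strand splice product
            fwd = transcript if strand == "+" else reverse_complement(transcript)
            n_exons = int(rng.integers(1, 4))
            cuts = sorted(
                rng.choice(np.arange(1, len(fwd)), size=n_exons - 1, replace=False).tolist()
            )
            bounds = [0, *cuts, len(fwd)]
            pieces = [fwd[a:b] for a, b in zip(bounds, bounds[1:])]
            spacer = _random_seq(rng, 25)
            contig_parts.append(spacer)
            cursor += len(spacer)
            exons: list[tuple[int, int]] = []
            for p_idx, piece in enumerate(pieces):
                start = cursor
                contig_parts.append(piece)
                cursor += len(piece)
                exons.append((start, cursor))
                if p_idx < len(pieces) - 1:
                    intron = _random_seq(rng, int(rng.integers(*intron_length_range)))
                    contig_parts.append(intron)
                    cursor += len(intron)

            # CDS span in forward-splice coordinates
            if strand == "+":
                f1, f2 = len(leader), len(leader) + len(cds)
            else:
                f1 = len(transcript) - (len(leader) + len(cds))
                f2 = len(transcript) - len(leader)
            cds_g1 = _splice_to_genome(exons, f1)
            cds_g2 = _splice_to_genome(exons, f2 - 1) + 1

            gtf_rows.append(
                {
                    "chrom": chrom,
                    "strand": strand,
                    "gene_id": gene,
                    "transcript_id": isoform_id,
                    "exons": list(exons),
                    "cds_span": (cds_g1, cds_g2),
                }
            )
            n_sites = int(
                rng.poisson(utr_len / (400.0 if long_utr else 900.0))
            )
            utr_lo = len(leader) + len(cds)
            for _ in range(n_sites):
                start = int(rng.integers(utr_lo, utr_lo + max(utr_len - 8, 1)))
                site_rows.append(
                    {
                        "transcript_id": isoform_id,
                        "site_start": start,
                        "site_end": start + 8,
                        "miRNA_id": mirna_pool[int(rng.integers(0, n_mirnas))],
                        "context_score": float(-rng.uniform(0.05, 0.5)),
                    }
                )
            base_half_life = float(rng.lognormal(np.log(8.0), 0.4))
            half_rows.append(
                {
                    "transcript_id": isoform_id,
                    "hours": base_half_life * (0.6 if long_utr else 1.0),
                }
            )

        genome[chrom] = "".join(contig_parts)

    # decompose from the genomic layout to guarantee mutual consistency
    for row in gtf_rows:
        models.append(
            decompose(
                row["transcript_id"],
                row["gene_id"],
                row["chrom"],
                row["strand"],
                row["exons"],
                row["cds_span"],
                genome[row["chrom"]],
            )
        )

    gtf = pd.DataFrame(gtf_rows)
    sites = pd.DataFrame(
        site_rows,
        columns=["transcript_id", "site_start", "site_end", "miRNA_id", "context_score"],
    )
    half_life = pd.DataFrame(half_rows).set_index("transcript_id")["hours"]
    planted_uorfs = pd.DataFrame(
        uorf_rows, columns=["transcript_id", "start", "end", "start_codon"]
    )
    aux = AuxTables(
        codon_usage=usage,
        mirna_sites=sites,
        half_life=half_life,
        uorfs=None,
        expressed_mirnas=expressed,
    )
    return SyntheticAnnotation(
        models=models, genome=genome, gtf=gtf, aux=aux, planted_uorfs=planted_uorfs
    )


def _splice_to_genome(exons: Sequence[tuple[int, int]], splice_pos: int) -> int:
    offset = 0
    for start, end in exons:
        size = end - start
        if splice_pos < offset + size:
            return start + (splice_pos - offset)
        offset += size
    raise ValueError(f"splice position {splice_pos} beyond transcript")


@dataclass
class ExternalDataset:
    """External stage x cell expression with planted isoform switches."""

    tpm: pd.DataFrame  # transcripts x cells
    samples: pd.DataFrame  # cell -> stage
    switches: pd.DataFrame  # gene, isoform_low, isoform_high, direction


def simulate_external(
    truth: pd.DataFrame,
    n_stages: int = 7,
    cells_per_stage: int = 4,
    switch_rate: float = 0.1,
    seed: int | None = None,
    noise_sigma: float = 0.3,
    dominant_share: float = 0.75,
) -> ExternalDataset:
    """Stage-resolved external expression with planted isoform switches.

    Genes holding a gene-linked high/low archetype pair are eligible;
    each switches with probability ``switch_rate``, meaning its dominant
    isoform flips between the low-polysome member (early stages) and
    the high-polysome member (late stages), direction chosen at random.
    Non-switching genes keep a fixed dominant isoform.  Cells draw
    log-normal expression noise and columns are TPM-normalized.
    """
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    if not 0.0 <= switch_rate <= 1.0:
        raise ValueError(f"switch_rate must be in [0, 1], got {switch_rate}")
    rng = np.random.default_rng(seed)
    isoforms = truth.index.to_list()
    side = truth["translational_side"]

    switch_rows = []
    dominant: dict[str, dict[int, str]] = {}  # gene -> stage -> dominant isoform
    stages = list(range(n_stages))
    for gene, sub in truth.groupby("gene_id", sort=True):
        highs = sub.index[side.loc[sub.index] == "high"].to_list()
        lows = sub.index[side.loc[sub.index] == "low"].to_list()
        eligible = bool(highs and lows)
        if eligible and rng.random() < switch_rate:
            iso_low, iso_high = lows[0], highs[0]
            low_to_high = rng.random() < 0.5
            early, late = (iso_low, iso_high) if low_to_high else (iso_high, iso_low)
            half = n_stages // 2
            dominant[gene] = {
                s: (early if s < half else late) for s in stages
            }
            switch_rows.append(
                {
                    "gene_id": gene,
                    "isoform_low": iso_low,
                    "isoform_high": iso_high,
                    "direction": "low_to_high" if low_to_high else "high_to_low",
                }
            )
        else:
            dom = sub.index[int(rng.integers(0, len(sub)))]
            dominant[gene] = {s: dom for s in stages}

    # per-gene developmental trajectory: isoforms of a non-switching gene
    # share the gene's temporal shape (and hence co-cluster); switch genes
    # deviate through their share flip
    # strictly sloped trajectories (no flat segments) so expected stage
    # ranks are unambiguous and same-shape isoforms co-cluster under
    # rank-correlation distance
    t = np.linspace(0.0, 1.0, n_stages)
    patterns = np.vstack(
        [
            1.0 + 2.0 * t,
            3.0 - 2.0 * t,
            0.5 + 3.0 * np.exp(-(((t - 0.30) / 0.22) ** 2)) + 0.3 - 0.3 * t,
            3.2 - 2.8 * np.exp(-(((t - 0.50) / 0.30) ** 2)) + 0.3 * t,
            0.5 + 3.0 * np.exp(-(((t - 0.70) / 0.22) ** 2)) + 0.15 * t,
        ]
    )
    genes_unique = truth["gene_id"].unique()
    gene_base = {
        gene: float(rng.lognormal(np.log(50.0), 1.0)) for gene in genes_unique
    }
    gene_pattern = {
        gene: patterns[int(rng.integers(0, len(patterns)))] for gene in genes_unique
    }
    gene_expr = {
        gene: gene_base[gene] * gene_pattern[gene] for gene in genes_unique
    }
    minor_share = (1.0 - dominant_share)

    cells = []
    columns = {}
    for s in stages:
        for c in range(cells_per_stage):
            cell = f"stage{s + 1}_c{c + 1}"
            cells.append((cell, f"stage{s + 1}"))
            expr = np.zeros(len(isoforms))
            for idx, iso in enumerate(isoforms):
                gene = truth.at[iso, "gene_id"]
                n_iso = int((truth["gene_id"] == gene).sum())
                if dominant[gene][s] == iso:
                    share = dominant_share
                else:
                    share = minor_share / max(n_iso - 1, 1)
                expr[idx] = (
                    gene_expr[gene][s] * share * rng.lognormal(0.0, noise_sigma)
                )
            columns[cell] = expr * 1e6 / expr.sum()
    tpm = pd.DataFrame(columns, index=pd.Index(isoforms, name="isoform_id"))
    samples = pd.DataFrame(cells, columns=["cell", "stage"]).set_index("cell")
    switches = pd.DataFrame(
        switch_rows, columns=["gene_id", "isoform_low", "isoform_high", "direction"]
    )
    return ExternalDataset(tpm=tpm, samples=samples, switches=switches)
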