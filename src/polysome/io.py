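"""Readers and writers for the pipeline's on-disk formats.

Tabular data is TSV with a header row; missing values are empty fields,
never zero.  Annotation is GTF (1-based inclusive coordinates,
converted to 0-based half-open internally) and FASTA.  Every output
directory carries a JSON manifest recording parameters, seeds and input
checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "read_counts",
    "write_counts",
    "read_table",
    "write_table",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "write_manifest",
]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Isoform x sample count matrix from TSV (first column = isoform id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate isoform ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample labels in {path}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df


def write_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "isoform_id")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    """Generic TSV with header; tolerant of CRLF line endings."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, na_rep="")


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Parse a GTF into one record per transcript.

    Returns a DataFrame with columns chrom, strand, gene_id,
    transcript_id, exons (list of 0-based half-open intervals) and
    cds_span (0-based half-open genomic span covering start through
    stop codon, or None).  Exon/CDS features are grouped by their
    ``transcript_id`` attribute; a transcript declared on two different
    chromosomes or strands — the signature of a duplicated id — is an
    error naming the offending line.
    """
    transcripts: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed GTF line ({exc})")
            if feat.featuretype not in ("exon", "CDS", "stop_codon", "transcript"):
                continue
            tid = feat.attributes.get("transcript_id", [None])[0]
            gid = feat.attributes.get("gene_id", [None])[0]
            if tid is None or gid is None:
                raise ValueError(
                    f"{path}:{lineno}: missing transcript_id/gene_id attribute"
                )
            rec = transcripts.setdefault(
                tid,
                {
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "gene_id": gid,
                    "transcript_id": tid,
                    "exons": [],
                    "cds_parts": [],
                },
            )
            if rec["chrom"] != feat.seqid or rec["strand"] != feat.strand:
                raise ValueError(
                    f"{path}:{lineno}: transcript_id {tid!r} appears on "
                    "multiple chromosomes/strands (duplicate id?)"
                )
            interval = (feat.start - 1, feat.end)  # to 0-based half-open
            if feat.featuretype == "exon":
                if interval in rec["exons"]:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate exon for transcript {tid!r}"
                    )
                rec["exons"].append(interval)
            elif feat.featuretype in ("CDS", "stop_codon"):
                rec["cds_parts"].append(interval)
    rows = []
    for tid, rec in transcripts.items():
        exons = sorted(rec.pop("exons"))
        parts = rec.pop("cds_parts")
        rec["exons"] = exons
        rec["cds_span"] = (
            (min(s for s, _ in parts), max(e for _, e in parts)) if parts else None
        )
        rows.append(rec)
    return pd.DataFrame(
        rows, columns=["chrom", "strand", "gene_id", "transcript_id", "exons", "cds_span"]
    )


def write_gtf(records: pd.DataFrame, path: str | Path, source: str = "polysome") -> None:
    """Write transcript records (as produced by the generator) as GTF.

    CDS segments are clipped to exons so coordinates stay consistent
    for multi-exon coding regions.
    """
    with open(path, "w") as out:
        for _, rec in records.iterrows():
            attrs = (
                f'gene_id "{rec["gene_id"]}"; transcript_id "{rec["transcript_id"]}";'
            )
            exons = sorted(rec["exons"])
            tx_start = min(s for s, _ in exons) + 1
            tx_end = max(e for _, e in exons)
            out.write(
                f"{rec['chrom']}\t{source}\ttranscript\t{tx_start}\t{tx_end}\t.\t"
                f"{rec['strand']}\t.\t{attrs}\n"
            )
            for s, e in exons:
                out.write(
                    f"{rec['chrom']}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                    f"{rec['strand']}\t.\t{attrs}\n"
                )
            if rec["cds_span"] is not None:
                cs, ce = rec["cds_span"]
                for s, e in exons:
                    lo, hi = max(s, cs), min(e, ce)
                    if lo < hi:
                        out.write(
                            f"{rec['chrom']}\t{source}\tCDS\t{lo + 1}\t{hi}\t.\t"
                            f"{rec['strand']}\t.\t{attrs}\n"
                        )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    parameters: Mapping,
    inputs: Sequence[str | Path] = (),
    name: str = "manifest.json",
) -> Path:
    """Provenance manifest: parameters plus input checksums."""
    from polysome import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "parameters": dict(parameters),
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()
        },
    }
    path = out_dir / name
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
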