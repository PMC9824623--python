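"""Readers and writers for the external formats the pipeline touches.

All intervals are 0-based, half-open (BED convention).  GFF3 input, which is
1-based inclusive, is converted on read.  Sequences are upper-cased DNA over
``{A, C, G, T, N}``; anything else is rejected at parse time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "PeakRecord",
    "GeneModel",
    "ExpressionRecord",
    "read_fasta",
    "write_fasta",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gff3_genes",
    "read_expression_table",
    "write_expression_table",
    "write_predictions",
    "read_predictions",
]

VALID_BASES = frozenset("ACGTN")

PREDICTION_COLUMNS = (
    "chrom",
    "start",
    "end",
    "strand",
    "m_H1",
    "m_H2",
    "m_ignorance",
    "decision_score",
)


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (chromosome, contig or promoter)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeakRecord:
    """One ENCODE narrowPeak (BED6+4) interval.

    ``summit_offset`` is the offset of the point-source summit from ``start``;
    -1 means the summit was not called.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    signal_value: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"peak {self.name!r}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"peak {self.name!r}: invalid strand {self.strand!r}")
        if self.summit_offset >= self.end - self.start:
            raise ValueError(
                f"peak {self.name!r}: summit offset {self.summit_offset} outside "
                f"{self.end - self.start} bp interval"
            )
        if self.summit_offset < -1:
            raise ValueError(f"peak {self.name!r}: summit offset < -1")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def summit(self) -> int:
        """Absolute summit position; interval midpoint when no summit was called."""
        if self.summit_offset >= 0:
            return self.start + self.summit_offset
        return self.start + self.width // 2


@dataclass(frozen=True)
class GeneModel:
    """Start-codon anchor of one gene.

    ``cds_start`` is the 0-based genomic position of the A of the ATG on the
    coding strand (for '-' genes this is the highest coordinate of the CDS).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.cds_start < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative cds_start")


@dataclass(frozen=True)
class ExpressionRecord:
    """Gene-level log2 fold-change under auxin treatment."""

    gene_id: str
    log2_fc: float

    def __post_init__(self) -> None:
        fc = float(self.log2_fc)
        if fc != fc or fc in (float("inf"), float("-inf")):
            raise ValueError(f"gene {self.gene_id!r}: non-finite log2_fc")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into validated, upper-cased records (order preserved)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} in {path} has no sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[SequenceRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(path: str | os.PathLike) -> list[PeakRecord]:
    """Read an ENCODE narrowPeak (BED6+4) file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak requires 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                peak = PeakRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    score=int(fields[4]),
                    strand=fields[5],
                    signal_value=float(fields[6]),
                    p_value=float(fields[7]),
                    q_value=float(fields[8]),
                    summit_offset=int(fields[9]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    return peaks


def write_narrowpeak(path: str | os.PathLike, peaks: Iterable[PeakRecord]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        p.chrom,
                        p.start,
                        p.end,
                        p.name,
                        p.score,
                        p.strand,
                        p.signal_value,
                        p.p_value,
                        p.q_value,
                        p.summit_offset,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 (gene/CDS features only)


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        item = item.strip()
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Extract start-codon anchors from GFF3 gene/CDS features.

    CDS features whose Parent resolves to a gene (directly, or through a
    transcript id that extends the gene id) refine the anchor; genes without
    CDS use their own 5' end.  1-based GFF coordinates become 0-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: dict[str, dict] = {}
    cds: list[tuple[str, int, int]] = []  # (parent, start0, end_excl)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 requires 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in {"gene", "CDS"}:
                continue
            start0, end_excl = int(start) - 1, int(end)
            if start0 < 0 or start0 >= end_excl:
                raise ValueError(f"{path}:{lineno}: invalid coordinates")
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if not gid:
                    raise ValueError(f"{path}:{lineno}: gene without ID attribute")
                if strand not in {"+", "-"}:
                    raise ValueError(f"{path}:{lineno}: gene {gid!r} unstranded")
                genes[gid] = {"chrom": chrom, "strand": strand, "start": start0, "end": end_excl}
            else:
                parent = a.get("Parent", a.get("ID", ""))
                cds.append((parent, start0, end_excl))
    models = []
    for gid, g in genes.items():
        spans = [
            (s, e)
            for parent, s, e in cds
            if parent == gid or parent.startswith(gid + ".") or parent.startswith(gid + "_")
        ]
        if spans:
            lo = min(s for s, _ in spans)
            hi = max(e for _, e in spans)
        else:
            lo, hi = g["start"], g["end"]
        cds_start = lo if g["strand"] == "+" else hi - 1
        models.append(GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"], cds_start=cds_start))
    return models


# ---------------------------------------------------------------------------
# Expression table


def read_expression_table(path: str | os.PathLike) -> list[ExpressionRecord]:
    """Read a TSV with header columns ``gene_id`` and ``log2_fc``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "log2_fc"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicated gene ids {dups!r}")
    fc = pd.to_numeric(df["log2_fc"], errors="coerce")
    if fc.isna().any():
        bad = df.loc[fc.isna(), "gene_id"].tolist()
        raise ValueError(f"{path}: non-numeric log2_fc for genes {bad!r}")
    return [ExpressionRecord(g, float(v)) for g, v in zip(df["gene_id"], fc)]


def write_expression_table(path: str | os.PathLike, records: Iterable[ExpressionRecord]) -> None:
    df = pd.DataFrame(
        {"gene_id": [r.gene_id for r in records], "log2_fc": [r.log2_fc for r in records]}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Predictions


def write_predictions(path: str | os.PathLike, rows: Sequence[dict]) -> None:
    """Write per-candidate fused masses and decision scores as TSV.

    The first three columns are BED-compatible (0-based half-open).  An empty
    row list yields a header-only file.
    """
    df = pd.DataFrame(list(rows), columns=PREDICTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_predictions(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing prediction columns {sorted(missing)!r}")
    return df
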