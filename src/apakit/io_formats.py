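"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are BED-style 0-based half-open; strand is ``+`` or
``-``.  Every downstream module consumes the containers defined here, never
raw files.  Readers reject malformed input with :class:`ParseError` rather
than silently coercing it.

Formats
-------
* gene x sample matrices as tab-delimited text ("NA", "" or "nan" = missing),
* GDC-dialect MAF mutation tables,
* BED6 intervals (optionally with extra numeric columns, used for per-replicate
  CLIP window counts),
* FASTA (via Biopython; ``U`` normalized to ``T``, sequences upper-cased).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING_TOKENS = ("NA", "", "nan")

VALID_TAGS = ("expression_tpm", "utr_metric")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval (0-based start, exclusive end)."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}: must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint, in genomic coordinates."""
        return (self.start + self.end - 1) // 2


@dataclass
class GeneSampleMatrix:
    """A gene x sample matrix of real values with a semantic tag.

    ``data`` is a pandas DataFrame indexed by gene with sample columns; NaN
    marks missing.  ``tag`` is ``expression_tpm`` or ``utr_metric``.  UTR
    matrices additionally carry a ``dialect``: ``length_like`` (DaPars/PDUI
    style, larger = longer 3'UTR) or ``red_log_ratio``
    (log2(distal/proximal), larger = more distal poly(A)-site use).
    """

    data: pd.DataFrame
    tag: str
    dialect: str | None = None

    def __post_init__(self) -> None:
        if self.tag not in VALID_TAGS:
            raise ValueError(f"unknown tag {self.tag!r}; expected one of {VALID_TAGS}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample identifiers: {dupes[:5]}")
        if self.tag == "expression_tpm":
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("expression_tpm values must be >= 0")
        if self.dialect is not None and self.dialect not in ("length_like", "red_log_ratio"):
            raise ValueError(f"unknown UTR-metric dialect {self.dialect!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class MAFRecord:
    """One mutation call: sample barcode, gene symbol, GDC variant class."""

    sample_barcode: str
    gene_symbol: str
    variant_classification: str

    def __post_init__(self) -> None:
        if not self.sample_barcode or not self.gene_symbol:
            raise ValueError("MAF record requires non-empty barcode and gene symbol")


@dataclass(frozen=True)
class BedRecord:
    """A BED6 line; ``extra`` holds any numeric columns 7..n (e.g. replicate counts)."""

    interval: GenomicInterval
    name: str
    score: float
    extra: tuple[float, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, tag: str, dialect: str | None = None) -> GeneSampleMatrix:
    """Read a tab-delimited gene x sample matrix.

    First column = gene IDs, header row = sample IDs.  Missing values may be
    encoded as ``NA``, empty, or ``nan``.  Duplicate gene IDs and non-numeric
    cells raise :class:`ParseError` naming the offending row/column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, comment="#",
            na_values=list(MISSING_TOKENS), keep_default_na=False, dtype=str,
        )
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(f"{path}: cannot parse matrix: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene IDs: {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        g = bad.index[bad.any(axis=1)][0]
        s = bad.columns[bad.loc[g]][0]
        raise ParseError(f"{path}: non-numeric cell at gene {g!r}, sample {s!r}: {df.loc[g, s]!r}")
    return GeneSampleMatrix(numeric.astype(float), tag=tag, dialect=dialect)


def write_matrix(matrix: GeneSampleMatrix, path: str | Path, comment: str | None = None) -> None:
    """Write a matrix as tab-delimited text; missing values become ``NA``."""
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        out = matrix.data.copy()
        out.index.name = "gene"
        out.to_csv(fh, sep="\t", na_rep="NA", float_format="%.12g")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

_MAF_REQUIRED = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


def read_maf(path: str | Path) -> list[MAFRecord]:
    """Read a GDC-dialect MAF table into records, order preserved.

    Requires the Hugo_Symbol, Variant_Classification and Tumor_Sample_Barcode
    columns; extra columns are ignored, ``#`` comment lines skipped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: MAF missing required column(s): {missing}")
    return [
        MAFRecord(
            sample_barcode=row.Tumor_Sample_Barcode,
            gene_symbol=row.Hugo_Symbol,
            variant_classification=row.Variant_Classification,
        )
        for row in df.itertuples()
    ]


def write_maf(records: Iterable[MAFRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "Hugo_Symbol": [r.gene_symbol for r in records],
            "Variant_Classification": [r.variant_classification for r in records],
            "Tumor_Sample_Barcode": [r.sample_barcode for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# MAF round-trip note: write_maf emits only the three required columns, which
# is the whole data model read_maf exposes.


# ---------------------------------------------------------------------------
# BED6 (+ numeric extras)
# ---------------------------------------------------------------------------

def read_bed6(path: str | Path) -> list[BedRecord]:
    """Read BED6 lines (chrom start end name score strand [extra numeric...])."""
    records: list[BedRecord] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}")
            try:
                interval = GenomicInterval(
                    contig=fields[0], start=int(fields[1]), end=int(fields[2]), strand=fields[5]
                )
                score = float(fields[4])
                extra = tuple(float(x) for x in fields[6:])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(BedRecord(interval=interval, name=fields[3], score=score, extra=extra))
    return records


def write_bed6(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [
                r.interval.contig, str(r.interval.start), str(r.interval.end),
                r.name, f"{r.score:g}", r.interval.strand,
            ]
            cols.extend(f"{x:g}" for x in r.extra)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_FASTA_ALPHABET = set("ACGTUN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> sequence mapping.

    Sequences are upper-cased with U normalized to T; characters outside
    ACGTUN and duplicate IDs raise :class:`ParseError`.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        illegal = set(seq) - _FASTA_ALPHABET
        if illegal:
            raise ParseError(f"{path}: record {rec.id!r} has illegal character(s) {sorted(illegal)}")
        out[rec.id] = seq.replace("U", "T")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None) -> None:
    """Write a results table as TSV with a ``#`` header comment recording parameters."""
    from . import __version__

    with open(path, "w") as fh:
        items = "" if not params else " " + " ".join(f"{k}={v}" for k, v in params.items())
        fh.write(f"# apakit {__version__}{items}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], keep_default_na=True)
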