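"""Readers, writers and core record types for every external table the pipeline touches.

Supported formats
-----------------
* bedMethyl-style per-site modification pileups (two tab-separated dialects,
  see :func:`read_pileup`),
* BED3/BED6 binding intervals,
* differential-expression result tables (TSV with gene / log2FC / FDR columns),
* read-level modification tables (TSV),
* GMT gene-set files.

All internal coordinates are 0-based half-open; conversion to and from 1-based
conventions happens only at I/O edges.  Every reader transparently accepts
gzip-compressed input (detected by the ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "SiteRecord",
    "ReadLevelRecord",
    "DEResult",
    "BindingInterval",
    "ParseError",
    "SchemaError",
    "ValidationError",
    "read_pileup",
    "write_pileup",
    "read_de_table",
    "write_de_table",
    "read_binding_bed",
    "write_binding_bed",
    "read_read_level_table",
    "write_read_level_table",
    "read_gmt",
]


class ParseError(ValueError):
    """A row of an input file could not be parsed; carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """A parsed value violates a documented invariant."""


_STRANDS = {"+", "-"}


@dataclass(frozen=True, slots=True)
class SiteRecord:
    """One per-site, per-replicate modification count (one bedMethyl row).

    ``level`` (modified-read fraction, the m6A/A stoichiometry) is defined only
    when ``valid_cov > 0``; otherwise it is ``None``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    mod_code: str
    valid_cov: int
    n_mod: int
    sample_id: str
    condition: str

    def __post_init__(self) -> None:
        if self.end != self.start + 1:
            raise ValidationError(
                f"site interval must be a single base, got [{self.start},{self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"unknown strand {self.strand!r}")
        if self.valid_cov < 0 or self.n_mod < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_mod > self.valid_cov:
            raise ValidationError(
                f"n_mod ({self.n_mod}) exceeds valid_cov ({self.valid_cov})"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        """Site identity used throughout the pipeline: (chrom, start, strand)."""
        return (self.chrom, self.start, self.strand)

    @property
    def level(self) -> float | None:
        if self.valid_cov == 0:
            return None
        return self.n_mod / self.valid_cov


@dataclass(frozen=True, slots=True)
class ReadLevelRecord:
    """Per-read modification summary on one transcript."""

    read_id: str
    transcript_id: str
    n_called_A: int
    n_mod: int

    def __post_init__(self) -> None:
        if self.n_called_A < 0:
            raise ValidationError("n_called_A must be non-negative")
        if self.n_mod < 0 or self.n_mod > self.n_called_A:
            raise ValidationError("n_mod must satisfy 0 <= n_mod <= n_called_A")


@dataclass(frozen=True, slots=True)
class DEResult:
    """One gene's differential-expression result in one cell line."""

    gene_id: str
    log2fc: float
    fdr: float
    cell_line: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0) or math.isnan(self.fdr):
            raise ValidationError(f"fdr outside [0,1]: {self.fdr!r}")


@dataclass(frozen=True, slots=True)
class BindingInterval:
    """A reader-protein binding interval (BED convention, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    source_label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"start ({self.start}) must be < end ({self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"unknown strand {self.strand!r}")


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_pileup(
    path,
    sample_id: str,
    condition: str,
    mod_code_filter: str = "a",
) -> list[SiteRecord]:
    """Read a bedMethyl-style modification pileup.

    Two tab-separated dialects are recognised per row:

    * **count dialect** (modkit's 18-column output, detected as >= 12 columns):
      column 10 is valid coverage and column 12 the modified-read count;
    * **percent dialect** (exactly 11 columns): column 10 is valid coverage and
      column 11 the percent modified, from which
      ``n_mod = round(percent * valid_cov / 100)``.  This reconstruction is
      lossy and documented as such.

    Rows whose modification code (column 4) differs from ``mod_code_filter``
    are skipped, not errors.  Malformed rows raise :class:`ParseError` naming
    the line number.
    """
    records: list[SiteRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(path, lineno, f"expected >= 11 columns, got {len(fields)}")
            if fields[3] != mod_code_filter:
                continue
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            strand = fields[5]
            if strand not in _STRANDS:
                raise ParseError(path, lineno, f"unknown strand symbol {strand!r}")
            try:
                valid_cov = int(fields[9])
            except ValueError:
                raise ParseError(path, lineno, "non-integer valid coverage") from None
            if len(fields) >= 12:
                try:
                    n_mod = int(fields[11])
                except ValueError:
                    raise ParseError(path, lineno, "non-integer modified count") from None
            else:
                try:
                    percent = float(fields[10])
                except ValueError:
                    raise ParseError(path, lineno, "non-numeric percent modified") from None
                n_mod = int(percent * valid_cov / 100.0 + 0.5)
            try:
                records.append(
                    SiteRecord(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        strand=strand,
                        mod_code=fields[3],
                        valid_cov=valid_cov,
                        n_mod=n_mod,
                        sample_id=sample_id,
                        condition=condition,
                    )
                )
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return records


def write_pileup(records: Iterable[SiteRecord], path) -> None:
    """Write records in the 18-column count dialect.

    Counts and coordinates round-trip bit-exactly through :func:`read_pileup`.
    """
    with _open_text(path, "wt") as out:
        for rec in sorted(records, key=lambda r: (r.chrom, r.start, r.strand)):
            percent = 0.0 if rec.valid_cov == 0 else 100.0 * rec.n_mod / rec.valid_cov
            n_canonical = rec.valid_cov - rec.n_mod
            fields = [
                rec.chrom,
                str(rec.start),
                str(rec.end),
                rec.mod_code,
                str(rec.valid_cov),
                rec.strand,
                str(rec.start),
                str(rec.end),
                "255,0,0",
                str(rec.valid_cov),
                f"{percent:.2f}",
                str(rec.n_mod),
                str(n_canonical),
                "0",
                "0",
                "0",
                "0",
                "0",
            ]
            out.write("\t".join(fields) + "\n")


# Case-insensitive header synonyms for DE tables; extend via ``column_map``.
_DE_GENE_NAMES = {"gene", "gene_id", "genes", "symbol", "gene_name"}
_DE_LOG2FC_NAMES = {"log2fc", "logfc", "log2foldchange", "log2_fc"}
_DE_FDR_NAMES = {"fdr", "adj.p.val", "padj", "qvalue", "adj_p_val"}


def read_de_table(
    path,
    cell_line: str,
    column_map: dict[str, str] | None = None,
) -> list[DEResult]:
    """Read a differential-expression TSV into :class:`DEResult` records.

    The header must name at least a gene, a log2FC and an FDR column
    (case-insensitive; ``column_map`` may map ``{"gene": ..., "log2fc": ...,
    "fdr": ...}`` to explicit header names).  A duplicated gene id is an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lower = {str(c).lower(): c for c in df.columns}

    def find(role: str, synonyms: set[str]):
        if column_map and role in column_map:
            name = column_map[role]
            if name not in df.columns:
                raise SchemaError(f"mapped column {name!r} for {role!r} not in header")
            return name
        for syn in synonyms:
            if syn in lower:
                return lower[syn]
        raise SchemaError(f"no column found for {role!r} (header: {list(df.columns)})")

    gene_col = find("gene", _DE_GENE_NAMES)
    fc_col = find("log2fc", _DE_LOG2FC_NAMES)
    fdr_col = find("fdr", _DE_FDR_NAMES)

    dup = df[gene_col][df[gene_col].duplicated()]
    if len(dup) > 0:
        raise ValidationError(f"duplicate gene_id in {path}: {sorted(set(dup))[:5]}")
    return [
        DEResult(
            gene_id=str(gene),
            log2fc=float(fc),
            fdr=float(fdr),
            cell_line=cell_line,
        )
        for gene, fc, fdr in zip(df[gene_col], df[fc_col], df[fdr_col])
    ]


def write_de_table(results: Iterable[DEResult], path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.log2fc, r.fdr) for r in results],
        columns=["gene", "log2FC", "FDR"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_binding_bed(path, source_label: str) -> list[BindingInterval]:
    """Read BED3+ intervals (0-based half-open).  Strand "." is permitted
    (BED3 rows have no strand column and get ".")."""
    intervals: list[BindingInterval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                intervals.append(
                    BindingInterval(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        strand=strand,
                        source_label=source_label,
                    )
                )
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return intervals


def write_binding_bed(intervals: Iterable[BindingInterval], path) -> None:
    with _open_text(path, "wt") as out:
        for iv in intervals:
            out.write(
                "\t".join(
                    [iv.chrom, str(iv.start), str(iv.end), iv.source_label, "0", iv.strand]
                )
                + "\n"
            )


_READ_LEVEL_HEADER = ["read_id", "transcript_id", "n_called_A", "n_mod"]


def read_read_level_table(path) -> list[ReadLevelRecord]:
    records: list[ReadLevelRecord] = []
    with _open_text(path) as handle:
        header: list[str] | None = None
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != _READ_LEVEL_HEADER:
                    raise SchemaError(
                        f"expected header {_READ_LEVEL_HEADER}, got {header}"
                    )
                continue
            try:
                records.append(
                    ReadLevelRecord(
                        read_id=fields[0],
                        transcript_id=fields[1],
                        n_called_A=int(fields[2]),
                        n_mod=int(fields[3]),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return records


def write_read_level_table(records: Iterable[ReadLevelRecord], path) -> None:
    with _open_text(path, "wt") as out:
        out.write("\t".join(_READ_LEVEL_HEADER) + "\n")
        for rec in records:
            out.write(
                f"{rec.read_id}\t{rec.transcript_id}\t{rec.n_called_A}\t{rec.n_mod}\n"
            )


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file: name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "GMT rows need name, description, genes")
            sets[fields[0]] = set(fields[2:])
    return sets
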