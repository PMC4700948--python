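"""Tabular I/O for the X-linkage / dosage-compensation pipeline.

Every downstream stage consumes only the domain records defined here:
per-scaffold male/female genomic coverage, per-gene male/female expression
(FPKM) with an optional differential-expression p-value, pairwise alignment
hits, and microsatellite-marker primer hits.

Input layouts vary between the tools that produce them (SoapCoverage-style
coverage tables, Cuffdiff-style gene expression tables, BLAST ``-outfmt 6``
hit tables), so each reader is driven by a :class:`TableDialect` naming the
column positions, header presence and comment prefix.  Built-in dialects
cover the common layouts; callers may pass their own.

Parsing never silently drops a data row: a malformed row either aborts the
read with a :class:`TableParseError` listing every bad line, or — with
``collect_errors=True`` — is returned alongside the good records so that
``rows_in == records_out + errors_out``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "CoverageRecord",
    "GeneExpression",
    "HitRecord",
    "MarkerHit",
    "TableDialect",
    "SOAP_COVERAGE",
    "CUFFDIFF_GENES",
    "BLAST6",
    "MARKER_HITS",
    "RowError",
    "TableFormatError",
    "TableParseError",
    "read_coverage_table",
    "read_expression_table",
    "read_hit_table",
    "read_marker_table",
    "read_gene_locations",
    "write_coverage_table",
    "write_expression_table",
    "write_hit_table",
    "write_marker_table",
    "write_gene_locations",
]

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "none", "-", "."}


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageRecord:
    """Mean per-base male and female genomic read depth of one scaffold."""

    scaffold_id: str
    male_coverage: float
    female_coverage: float

    def __post_init__(self) -> None:
        for label, value in (("male", self.male_coverage), ("female", self.female_coverage)):
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"{label} coverage of {self.scaffold_id!r} must be finite and >= 0, "
                    f"got {value!r}"
                )


@dataclass(frozen=True)
class GeneExpression:
    """Per-gene male/female FPKM and (optionally) a DE-test p-value.

    FPKM values are taken as produced upstream (already length- and
    library-size-normalized); no renormalization happens anywhere in the
    pipeline.  ``de_pvalue`` is ``None`` when the differential-expression
    test was not run or not reported for the gene.
    """

    gene_id: str
    scaffold_id: str
    male_fpkm: float
    female_fpkm: float
    de_pvalue: float | None = None

    def __post_init__(self) -> None:
        for label, value in (("male", self.male_fpkm), ("female", self.female_fpkm)):
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"{label} FPKM of {self.gene_id!r} must be finite and >= 0, got {value!r}"
                )
        if self.de_pvalue is not None and not (0.0 <= self.de_pvalue <= 1.0):
            raise ValueError(
                f"de_pvalue of {self.gene_id!r} must lie in [0, 1], got {self.de_pvalue!r}"
            )


@dataclass(frozen=True)
class HitRecord:
    """One local alignment hit (query -> target) with its score.

    The same (query, target) pair may appear repeatedly — local aligners
    report one row per high-scoring segment pair.
    """

    query_id: str
    target_id: str
    score: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError(f"hit score {self.query_id!r}->{self.target_id!r} must be finite")
        if self.evalue is not None and (math.isnan(self.evalue) or self.evalue < 0):
            raise ValueError(f"e-value of {self.query_id!r}->{self.target_id!r} must be >= 0")


_PRIMER_ENDS = ("forward", "reverse")
_MARKER_CLASSES = ("X", "autosome")


@dataclass(frozen=True)
class MarkerHit:
    """A microsatellite-marker primer mapped to a genomic scaffold.

    ``marker_class`` is the published linkage of the marker (X or autosome);
    scaffolds inherit it when the marker is accepted.
    """

    marker_id: str
    primer_end: str
    scaffold_id: str
    evalue: float
    marker_class: str

    def __post_init__(self) -> None:
        if self.primer_end not in _PRIMER_ENDS:
            raise ValueError(f"primer_end must be one of {_PRIMER_ENDS}, got {self.primer_end!r}")
        if self.marker_class not in _MARKER_CLASSES:
            raise ValueError(
                f"marker_class must be one of {_MARKER_CLASSES}, got {self.marker_class!r}"
            )
        if math.isnan(self.evalue) or self.evalue < 0:
            raise ValueError(f"e-value of marker {self.marker_id!r} must be >= 0")


# ---------------------------------------------------------------------------
# dialects and the generic row engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableDialect:
    """Named column layout of a delimited text table.

    ``columns`` maps record field names to 0-based column indices.  Optional
    fields simply omit their entry.  ``header`` marks a single leading
    header row (after any comment lines) to be skipped on read and emitted
    on write.
    """

    name: str
    columns: Mapping[str, int]
    header: bool = False
    comment: str = "#"
    sep: str = "\t"

    def require(self, fields: Sequence[str]) -> None:
        missing = [f for f in fields if f not in self.columns]
        if missing:
            raise TableFormatError(
                f"dialect {self.name!r} lacks required column(s): {', '.join(missing)}"
            )

    @property
    def width(self) -> int:
        return max(self.columns.values()) + 1


#: SoapCoverage-style per-scaffold coverage: scaffold, male depth, female depth.
SOAP_COVERAGE = TableDialect(
    "soap-coverage",
    {"scaffold_id": 0, "male_coverage": 1, "female_coverage": 2},
)

#: Cuffdiff-style gene table: gene, scaffold, male FPKM, female FPKM, DE p-value.
CUFFDIFF_GENES = TableDialect(
    "cuffdiff-genes",
    {"gene_id": 0, "scaffold_id": 1, "male_fpkm": 2, "female_fpkm": 3, "de_pvalue": 4},
    header=True,
)

#: BLAST tabular (-outfmt 6) / BLAT-derived: query, target, ..., e-value, bit score.
BLAST6 = TableDialect(
    "blast-outfmt6",
    {"query_id": 0, "target_id": 1, "evalue": 10, "score": 11},
)

#: Marker-primer hit table: marker, primer end, scaffold, e-value, marker class.
MARKER_HITS = TableDialect(
    "marker-hits",
    {"marker_id": 0, "primer_end": 1, "scaffold_id": 2, "evalue": 3, "marker_class": 4},
    header=True,
)


@dataclass(frozen=True)
class RowError:
    """One rejected data row: its 1-based line number and what was wrong."""

    line_no: int
    message: str
    raw: str


class TableFormatError(ValueError):
    """The file/dialect combination cannot be parsed at all (e.g. missing column)."""


class TableParseError(ValueError):
    """One or more data rows were malformed; carries every :class:`RowError`."""

    def __init__(self, path: str | Path, errors: Sequence[RowError]):
        self.path = str(path)
        self.errors = list(errors)
        lines = "; ".join(f"line {e.line_no}: {e.message}" for e in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{self.path}: {len(self.errors)} malformed row(s): {lines}{more}")


def _iter_rows(path: str | Path, dialect: TableDialect) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, split fields) for each data row."""
    header_pending = dialect.header
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            if dialect.comment and line.startswith(dialect.comment):
                continue
            if header_pending:
                header_pending = False
                continue
            yield line_no, [f.strip() for f in line.split(dialect.sep)]


def _read_table(
    path: str | Path,
    dialect: TableDialect,
    required: Sequence[str],
    build: Callable[[list[str]], object],
    collect_errors: bool,
    what: str,
):
    dialect.require(required)
    records: list = []
    errors: list[RowError] = []
    n_rows = 0
    for line_no, fields in _iter_rows(path, dialect):
        n_rows += 1
        if len(fields) < dialect.width:
            errors.append(
                RowError(line_no, f"expected >= {dialect.width} fields, got {len(fields)}",
                         dialect.sep.join(fields))
            )
            continue
        try:
            records.append(build(fields))
        except (ValueError, TypeError) as exc:
            errors.append(RowError(line_no, str(exc), dialect.sep.join(fields)))
    if n_rows == 0:
        logger.warning("%s: no data rows in %s", what, path)
    if errors and not collect_errors:
        raise TableParseError(path, errors)
    if collect_errors:
        return records, errors
    return records


def _get(fields: list[str], dialect: TableDialect, name: str) -> str:
    return fields[dialect.columns[name]]

def _float(fields: list[str], dialect: TableDialect, name: str) -> float:
    raw = _get(fields, dialect, name)
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"non-numeric {name}: {raw!r}") from None

def _opt_float(fields: list[str], dialect: TableDialect, name: str) -> float | None:
    if name not in dialect.columns or dialect.columns[name] >= len(fields):
        return None
    raw = _get(fields, dialect, name)
    if raw.lower() in _MISSING_TOKENS:
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"non-numeric {name}: {raw!r}") from None


def _check_unique(records: Iterable, key: Callable, what: str) -> None:
    seen: set = set()
    dups: list = []
    for r in records:
        k = key(r)
        if k in seen:
            dups.append(k)
        seen.add(k)
    if dups:
        raise ValueError(f"duplicated {what}(s): {', '.join(map(str, sorted(set(dups))))}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_coverage_table(
    path: str | Path,
    dialect: TableDialect = SOAP_COVERAGE,
    collect_errors: bool = False,
):
    """Read per-scaffold male/female coverage into :class:`CoverageRecord` s.

    Scaffold ids must be unique.  With ``collect_errors=True`` returns
    ``(records, row_errors)`` instead of raising on malformed rows.
    """
    def build(fields: list[str]) -> CoverageRecord:
        return CoverageRecord(
            scaffold_id=_get(fields, dialect, "scaffold_id"),
            male_coverage=_float(fields, dialect, "male_coverage"),
            female_coverage=_float(fields, dialect, "female_coverage"),
        )

    out = _read_table(path, dialect, ["scaffold_id", "male_coverage", "female_coverage"],
                      build, collect_errors, "coverage table")
    records = out[0] if collect_errors else out
    _check_unique(records, lambda r: r.scaffold_id, "scaffold_id")
    return out


def read_expression_table(
    path: str | Path,
    dialect: TableDialect = CUFFDIFF_GENES,
    collect_errors: bool = False,
):
    """Read per-gene FPKM (+ optional DE p-value) into :class:`GeneExpression` s."""
    def build(fields: list[str]) -> GeneExpression:
        return GeneExpression(
            gene_id=_get(fields, dialect, "gene_id"),
            scaffold_id=_get(fields, dialect, "scaffold_id"),
            male_fpkm=_float(fields, dialect, "male_fpkm"),
            female_fpkm=_float(fields, dialect, "female_fpkm"),
            de_pvalue=_opt_float(fields, dialect, "de_pvalue"),
        )

    out = _read_table(path, dialect, ["gene_id", "scaffold_id", "male_fpkm", "female_fpkm"],
                      build, collect_errors, "expression table")
    records = out[0] if collect_errors else out
    _check_unique(records, lambda r: r.gene_id, "gene_id")
    return out


def read_hit_table(
    path: str | Path,
    dialect: TableDialect = BLAST6,
    collect_errors: bool = False,
):
    """Read an alignment hit table (BLAST -outfmt 6 style) into :class:`HitRecord` s."""
    def build(fields: list[str]) -> HitRecord:
        return HitRecord(
            query_id=_get(fields, dialect, "query_id"),
            target_id=_get(fields, dialect, "target_id"),
            score=_float(fields, dialect, "score"),
            evalue=_opt_float(fields, dialect, "evalue"),
        )

    return _read_table(path, dialect, ["query_id", "target_id", "score"],
                       build, collect_errors, "hit table")


def read_marker_table(
    path: str | Path,
    dialect: TableDialect = MARKER_HITS,
    collect_errors: bool = False,
):
    """Read marker-primer scaffold hits into :class:`MarkerHit` s."""
    def build(fields: list[str]) -> MarkerHit:
        return MarkerHit(
            marker_id=_get(fields, dialect, "marker_id"),
            primer_end=_get(fields, dialect, "primer_end").lower(),
            scaffold_id=_get(fields, dialect, "scaffold_id"),
            evalue=_float(fields, dialect, "evalue"),
            marker_class=_get(fields, dialect, "marker_class"),
        )

    return _read_table(path, dialect, ["marker_id", "primer_end", "scaffold_id",
                                       "evalue", "marker_class"],
                       build, collect_errors, "marker table")


# ---------------------------------------------------------------------------
# GTF gene locations
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"|gene_id\s+([^";\s]+)')


class GtfError(ValueError):
    """GTF could not be reduced to a one-scaffold-per-gene map."""


def read_gene_locations(path: str | Path, collect_errors: bool = False):
    """Map each gene in a GTF annotation to the scaffold carrying it.

    Only the seqname column and the ``gene_id`` attribute are consumed
    (coordinates are irrelevant here: linkage is a property of the
    scaffold, so gene -> scaffold identity is all downstream stages need).
    A gene whose features sit on more than one scaffold has no single
    linkage and is rejected with an error naming every such gene.
    """
    scaffolds_of: dict[str, set[str]] = {}
    errors: list[RowError] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                errors.append(RowError(line_no, f"expected 9 GTF fields, got {len(fields)}", line))
                continue
            m = _GENE_ID_RE.search(fields[8])
            if m is None:
                errors.append(RowError(line_no, "no gene_id in attribute block", line))
                continue
            gene_id = m.group(1) or m.group(2)
            scaffolds_of.setdefault(gene_id, set()).add(fields[0])
    if errors and not collect_errors:
        raise TableParseError(path, errors)
    multi = sorted(g for g, s in scaffolds_of.items() if len(s) > 1)
    if multi:
        raise GtfError(
            f"{path}: gene(s) with features on multiple scaffolds: {', '.join(multi)}"
        )
    locations = {g: next(iter(s)) for g, s in scaffolds_of.items()}
    if collect_errors:
        return locations, errors
    return locations


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip representation
    return str(value)


def _write_table(records, path, dialect: TableDialect, field_names: Sequence[str]) -> None:
    dialect.require([f for f in field_names if f in dialect.columns])
    width = dialect.width
    with open(path, "w", encoding="utf-8") as fh:
        if dialect.header:
            header = ["."] * width
            for name, idx in dialect.columns.items():
                header[idx] = name
            fh.write(dialect.sep.join(header) + "\n")
        for rec in records:
            row = ["."] * width
            for name in field_names:
                if name in dialect.columns:
                    row[dialect.columns[name]] = _fmt(getattr(rec, name))
            fh.write(dialect.sep.join(row) + "\n")


def write_coverage_table(records, path, dialect: TableDialect = SOAP_COVERAGE) -> None:
    _write_table(records, path, dialect, ["scaffold_id", "male_coverage", "female_coverage"])


def write_expression_table(records, path, dialect: TableDialect = CUFFDIFF_GENES) -> None:
    _write_table(records, path, dialect,
                 ["gene_id", "scaffold_id", "male_fpkm", "female_fpkm", "de_pvalue"])


def write_hit_table(records, path, dialect: TableDialect = BLAST6) -> None:
    _write_table(records, path, dialect, ["query_id", "target_id", "score", "evalue"])


def write_marker_table(records, path, dialect: TableDialect = MARKER_HITS) -> None:
    _write_table(records, path, dialect,
                 ["marker_id", "primer_end", "scaffold_id", "evalue", "marker_class"])


def write_gene_locations(locations: Mapping[str, str], path) -> None:
    """Write a gene -> scaffold map as a minimal single-exon-per-gene GTF."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene_id in locations:
            scaffold = locations[gene_id]
            fh.write(
                f'{scaffold}\themix\texon\t1\t100\t.\t+\t.\tgene_id "{gene_id}"; '
                f'transcript_id "{gene_id}.t1";\n'
            )
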