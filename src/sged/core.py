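"""Core SGED data model: site coordinates, groups, tables, and table algebra.

SGED (site/group extended data) is a CSV/TSV dialect whose first column
holds one or more *site coordinates* wrapped in square brackets and
separated by semicolons, e.g. ``[14]`` or ``[A:ARG14;A:ARG21]``.  The
remaining columns carry arbitrary per-group annotations (statistics,
p-values, amino acids, ...).  Lines starting with ``#`` are comments and
are preserved as table metadata.

Coordinates come in three referentials:

* plain 1-based positions in a sequence or alignment (``14``),
* structure residues, ``CHAIN:RESNAME RESNUM [ICODE]`` written without
  spaces (``A:ARG14``, ``A:GLY35A``) — chain identifiers longer than one
  character are allowed (mmCIF),
* labelled positions ``label:pos`` used by concatenated-alignment indices
  (``geneB:12``).

Attribute values are kept as the exact strings read from the file: a
probability printed as ``0.71`` is written back as ``0.71``, never
reformatted.  Missing values use the literal token ``NA``.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field

NA_TOKEN = "NA"

__all__ = [
    "NA_TOKEN",
    "SgedError",
    "SgedParseError",
    "SiteCoordinate",
    "Group",
    "SgedRecord",
    "SgedTable",
    "parse_sged",
    "write_sged",
    "group_rows",
    "ungroup_rows",
    "merge_tables",
]


class SgedError(ValueError):
    """Base class for SGED data errors."""


class SgedParseError(SgedError):
    """Malformed SGED input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# CHAIN ":" RESNAME RESNUMBER [ICODE]; resname is 1-3 letters so that
# labelled positions like "aln2:15" (digits only after the colon) never
# collide with the structure-residue grammar.
_STRUCT_RE = re.compile(r"^([A-Za-z0-9]+):([A-Za-z]{1,3})(-?\d+)([A-Za-z])?$")
_LABEL_RE = re.compile(r"^([^;\[\]\s]+):(\d+)$")
_POSITION_RE = re.compile(r"^\d+$")


@dataclass(frozen=True)
class SiteCoordinate:
    """A single site in one of three coordinate referentials.

    ``kind`` is one of ``"position"`` (plain 1-based sequence/alignment
    position), ``"structure_residue"`` (chain + residue name + residue
    number + optional insertion code) or ``"labeled_position"`` (a position
    qualified by a source label, used by concatenation indices).
    """

    kind: str
    position: int | None = None
    chain_id: str | None = None
    residue_name: str | None = None
    residue_number: int | None = None
    insertion_code: str = ""
    label: str | None = None

    POSITION = "position"
    STRUCTURE = "structure_residue"
    LABELED = "labeled_position"

    @classmethod
    def from_position(cls, position: int) -> "SiteCoordinate":
        position = int(position)
        if position < 1:
            raise SgedError(f"positions are 1-based, got {position}")
        return cls(kind=cls.POSITION, position=position)

    @classmethod
    def from_residue(
        cls,
        chain_id: str,
        residue_name: str,
        residue_number: int,
        insertion_code: str = "",
    ) -> "SiteCoordinate":
        return cls(
            kind=cls.STRUCTURE,
            chain_id=str(chain_id),
            residue_name=str(residue_name).upper(),
            residue_number=int(residue_number),
            insertion_code=str(insertion_code or ""),
        )

    @classmethod
    def from_label(cls, label: str, position: int) -> "SiteCoordinate":
        position = int(position)
        if position < 1:
            raise SgedError(f"positions are 1-based, got {position}")
        return cls(kind=cls.LABELED, label=str(label), position=position)

    @classmethod
    def parse(cls, text: str) -> "SiteCoordinate":
        text = text.strip()
        if not text:
            raise SgedError("empty coordinate")
        if _POSITION_RE.match(text):
            return cls.from_position(int(text))
        m = _STRUCT_RE.match(text)
        if m:
            chain, name, number, icode = m.groups()
            return cls.from_residue(chain, name, int(number), icode or "")
        m = _LABEL_RE.match(text)
        if m:
            return cls.from_label(m.group(1), int(m.group(2)))
        raise SgedError(f"cannot parse coordinate {text!r}")

    def __str__(self) -> str:
        if self.kind == self.POSITION:
            return str(self.position)
        if self.kind == self.STRUCTURE:
            return (
                f"{self.chain_id}:{self.residue_name}"
                f"{self.residue_number}{self.insertion_code}"
            )
        return f"{self.label}:{self.position}"


@dataclass(frozen=True)
class Group:
    """An ordered, non-empty tuple of coordinates treated as one unit.

    Members may be ``None`` to represent an unmapped (``NA``) coordinate
    inside a translated group.
    """

    coordinates: tuple

    def __post_init__(self):
        if not self.coordinates:
            raise SgedError("a group must contain at least one coordinate")

    @classmethod
    def of(cls, *coords) -> "Group":
        return cls(tuple(coords))

    @classmethod
    def parse(cls, text: str) -> "Group":
        text = text.strip()
        if not (text.startswith("[") and text.endswith("]")):
            raise SgedError(f"group string {text!r} is not bracketed")
        inner = text[1:-1]
        if "[" in inner or "]" in inner:
            raise SgedError(f"unbalanced brackets in group string {text!r}")
        if not inner.strip():
            raise SgedError(f"empty group {text!r}")
        coords = []
        for part in inner.split(";"):
            part = part.strip()
            if part == NA_TOKEN:
                coords.append(None)
            else:
                coords.append(SiteCoordinate.parse(part))
        return cls(tuple(coords))

    def __str__(self) -> str:
        return "[" + ";".join(NA_TOKEN if c is None else str(c) for c in self.coordinates) + "]"

    def __len__(self) -> int:
        return len(self.coordinates)

    def __iter__(self):
        return iter(self.coordinates)


@dataclass
class SgedRecord:
    """One table row: a group plus its named attribute values (as strings)."""

    group: Group
    attributes: dict = field(default_factory=dict)

    def copy(self) -> "SgedRecord":
        return SgedRecord(self.group, dict(self.attributes))


_DELIMS = {"TSV": "\t", "CSV": ","}


@dataclass
class SgedTable:
    """An in-memory SGED file: header, records, preserved comments, dialect."""

    header: list
    records: list = field(default_factory=list)
    comments: list = field(default_factory=list)
    dialect: str = "TSV"

    def __post_init__(self):
        if not self.header:
            raise SgedError("SGED table needs at least the group column")
        if self.dialect not in _DELIMS:
            raise SgedError(f"unknown dialect {self.dialect!r}")

    @property
    def group_column(self) -> str:
        return self.header[0]

    def validate(self) -> None:
        cols = self.header[1:]
        for i, rec in enumerate(self.records):
            if list(rec.attributes.keys()) != cols:
                raise SgedError(
                    f"record {i}: attribute keys {list(rec.attributes)} "
                    f"do not match header {cols}"
                )

    def column(self, name: str) -> list:
        """Values of one attribute column, as the stored strings."""
        if name == self.group_column:
            return [str(r.group) for r in self.records]
        if name not in self.header:
            raise SgedError(f"unknown column {name!r}")
        return [r.attributes[name] for r in self.records]

    def to_frame(self):
        """A pandas DataFrame view (group column as canonical strings)."""
        import pandas as pd

        data = {self.group_column: [str(r.group) for r in self.records]}
        for name in self.header[1:]:
            data[name] = [r.attributes[name] for r in self.records]
        return pd.DataFrame(data)

    def copy(self) -> "SgedTable":
        return SgedTable(
            list(self.header),
            [r.copy() for r in self.records],
            list(self.comments),
            self.dialect,
        )

    def __len__(self) -> int:
        return len(self.records)


def _detect_dialect(header_line: str) -> str:
    if "\t" in header_line:
        return "TSV"
    if "," in header_line:
        return "CSV"
    return "TSV"  # single column


def parse_sged(text: str, dialect: str = "auto") -> SgedTable:
    """Parse SGED text into a table.

    ``dialect`` is ``"CSV"``, ``"TSV"`` or ``"auto"`` (inspect the header:
    tab wins over comma).  Comment lines (leading ``#``) anywhere in the
    file are collected in order and excluded from the records.
    """
    if dialect not in ("auto", "CSV", "TSV"):
        raise SgedError(f"unknown dialect {dialect!r}")
    comments: list = []
    header: list | None = None
    records: list = []
    delim = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if raw.startswith("#"):
            comments.append(raw)
            continue
        if not raw.strip():
            continue
        if header is None:
            if dialect == "auto":
                dialect = _detect_dialect(raw)
            delim = _DELIMS[dialect]
            header = [f.strip() for f in next(csv.reader([raw], delimiter=delim))]
            continue
        fields = [f.strip() for f in next(csv.reader([raw], delimiter=delim))]
        if len(fields) != len(header):
            raise SgedParseError(
                f"expected {len(header)} fields, got {len(fields)}", line=lineno
            )
        try:
            group = Group.parse(fields[0])
        except SgedError as exc:
            raise SgedParseError(str(exc), line=lineno) from exc
        records.append(SgedRecord(group, dict(zip(header[1:], fields[1:]))))
    if header is None:
        raise SgedParseError("no header line found")
    return SgedTable(header, records, comments, dialect)


def write_sged(table: SgedTable, dialect: str | None = None) -> str:
    """Serialize a table: comments first, then header, then one line per record.

    Group strings are never quoted — the brackets make them unambiguous
    (semicolon is the only separator inside them).  Attribute strings are
    emitted verbatim.
    """
    dialect = dialect or table.dialect
    if dialect not in _DELIMS:
        raise SgedError(f"unknown dialect {dialect!r}")
    delim = _DELIMS[dialect]
    table.validate()
    lines = list(table.comments)
    lines.append(delim.join(table.header))
    for rec in table.records:
        lines.append(delim.join([str(rec.group)] + [rec.attributes[c] for c in table.header[1:]]))
    return "\n".join(lines) + "\n"


def group_rows(table: SgedTable, column: str | None = None) -> SgedTable:
    """Combine all sites listed in ``column`` into a single one-record group.

    ``column`` defaults to the group column.  The output keeps only the
    ``Group`` column; coordinates are concatenated in input order.  Rows
    whose named column is ``NA`` are skipped with a warning.
    """
    if column is None:
        column = table.group_column
    if column not in table.header:
        raise SgedError(f"unknown column {column!r}")
    coords: list = []
    for i, rec in enumerate(table.records):
        value = str(rec.group) if column == table.group_column else rec.attributes[column]
        if value == NA_TOKEN:
            warnings.warn(f"record {i}: column {column!r} is NA, skipped", stacklevel=2)
            continue
        coords.extend(Group.parse(value).coordinates)
    if not coords:
        raise SgedError(f"no coordinates found in column {column!r}")
    record = SgedRecord(Group(tuple(coords)), {})
    return SgedTable(["Group"], [record], list(table.comments), table.dialect)


def ungroup_rows(table: SgedTable) -> SgedTable:
    """Dissociate groups: one output record per coordinate.

    Attribute values are copied onto every derived row; order follows the
    original records and, within each record, the group's coordinate order.
    ``NA`` members are dropped with a warning.
    """
    out: list = []
    for i, rec in enumerate(table.records):
        for coord in rec.group:
            if coord is None:
                warnings.warn(f"record {i}: NA coordinate skipped", stacklevel=2)
                continue
            out.append(SgedRecord(Group.of(coord), dict(rec.attributes)))
    return SgedTable(list(table.header), out, list(table.comments), table.dialect)


def _check_unique(table: SgedTable, which: str) -> dict:
    seen: dict = {}
    for rec in table.records:
        key = str(rec.group)
        if key in seen:
            raise SgedError(f"duplicate group key {key} in {which} table")
        seen[key] = rec
    return seen


def merge_tables(
    a: SgedTable,
    b: SgedTable,
    join: str = "inner",
    allow_duplicates: bool = False,
    suffix: str = "_2",
) -> SgedTable:
    """Relational join of two tables on group identity (element-wise coordinates).

    ``join`` is ``inner``, ``left`` or ``outer``.  b's non-group columns are
    appended; a name collision gets ``suffix`` (repeated until unique).
    Duplicate group keys are an error unless ``allow_duplicates`` requests a
    many-to-many join.
    """
    if join not in ("inner", "left", "outer"):
        raise SgedError(f"unknown join type {join!r}")
    if not allow_duplicates:
        _check_unique(a, "left")
        _check_unique(b, "right")
    b_map: dict = {}
    for rec in b.records:
        b_map.setdefault(str(rec.group), []).append(rec)

    rename = {}
    for name in b.header[1:]:
        new = name
        while new in a.header or new in rename.values():
            new = new + suffix
        rename[name] = new
    header = list(a.header) + list(rename.values())

    out: list = []
    for rec in a.records:
        matches = b_map.get(str(rec.group), [])
        if matches:
            for m in matches:
                attrs = dict(rec.attributes)
                for name in b.header[1:]:
                    attrs[rename[name]] = m.attributes[name]
                out.append(SgedRecord(rec.group, attrs))
        elif join in ("left", "outer"):
            attrs = dict(rec.attributes)
            for name in b.header[1:]:
                attrs[rename[name]] = NA_TOKEN
            out.append(SgedRecord(rec.group, attrs))
    if join == "outer":
        a_keys = {str(r.group) for r in a.records}
        for rec in b.records:
            if str(rec.group) not in a_keys:
                attrs = {c: NA_TOKEN for c in a.header[1:]}
                for name in b.header[1:]:
                    attrs[rename[name]] = rec.attributes[name]
                out.append(SgedRecord(rec.group, attrs))
    comments = list(a.comments) + list(b.comments)
    return SgedTable(header, out, comments, a.dialect)
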