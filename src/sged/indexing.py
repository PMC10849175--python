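"""Coordinate indices among alignments, sequences, and 3D structures.

A :class:`CoordinateIndex` maps source coordinates to target coordinates
(or to ``NA`` when a source site has no counterpart).  Three builders are
provided:

* ``build_alignment_index`` — alignment columns → ungapped positions of one
  reference sequence;
* ``build_concat_index`` — columns of a concatenated super-alignment →
  (source alignment, local column);
* ``build_structure_index`` — alignment columns → residues of the
  best-matching chain among a set of candidate structures, found by
  globally aligning every alignment sequence against every chain sequence
  and keeping the highest-scoring pair (coverage breaks ties, then input
  order).

Pairwise alignment is delegated to Biopython's ``PairwiseAligner`` (affine
gaps, end gaps penalised, BLOSUM62 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Group, NA_TOKEN, SgedError, SgedRecord, SgedTable, SiteCoordinate

__all__ = [
    "CoordinateIndex",
    "PairwiseAlignment",
    "build_alignment_index",
    "build_concat_index",
    "pairwise_global_align",
    "build_structure_index",
    "translate_coords",
]


@dataclass
class CoordinateIndex:
    """Mapping source coordinate → target coordinate or ``None`` (NA).

    The mapping must be injective on its non-NA entries so that it can be
    inverted.  ``metadata`` is an ordered name → value dictionary written
    as ``# name: value`` comment lines in the serialized two-column file.
    """

    entries: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        seen = set()
        for tgt in self.entries.values():
            if tgt is None:
                continue
            if tgt in seen:
                raise SgedError(f"index is not injective: target {tgt} repeated")
            seen.add(tgt)

    def __getitem__(self, coord: SiteCoordinate):
        if coord not in self.entries:
            raise SgedError(f"coordinate {coord} absent from index")
        return self.entries[coord]

    def __len__(self) -> int:
        return len(self.entries)

    def invert(self) -> "CoordinateIndex":
        self.validate()
        inv = {v: k for k, v in self.entries.items() if v is not None}
        meta = dict(self.metadata)
        src, tgt = meta.get("source"), meta.get("target")
        if src is not None or tgt is not None:
            meta["source"], meta["target"] = tgt or "", src or ""
        return CoordinateIndex(inv, meta)

    def to_text(self) -> str:
        lines = ["# SGED coordinate index"]
        for k, v in self.metadata.items():
            lines.append(f"# {k}: {v}")
        for src, tgt in self.entries.items():
            lines.append(f"{src}\t{NA_TOKEN if tgt is None else tgt}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CoordinateIndex":
        entries: dict = {}
        metadata: dict = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            if not raw.strip():
                continue
            if raw.startswith("#"):
                body = raw.lstrip("#").strip()
                if ":" in body and not body.startswith("SGED"):
                    name, _, value = body.partition(":")
                    metadata[name.strip()] = value.strip()
                continue
            parts = raw.split("\t")
            if len(parts) != 2:
                raise SgedError(f"line {lineno}: index rows have two tab-separated fields")
            src = SiteCoordinate.parse(parts[0])
            tgt = None if parts[1].strip() == NA_TOKEN else SiteCoordinate.parse(parts[1])
            entries[src] = tgt
        return cls(entries, metadata)


def _records(alignment):
    """Accept a Biopython MultipleSeqAlignment or any iterable of SeqRecords."""
    return list(alignment)


def _ungap(seq: str) -> str:
    return seq.replace("-", "").replace(".", "")


def build_alignment_index(alignment, reference: str) -> CoordinateIndex:
    """Map 1-based alignment columns to ungapped positions of ``reference``.

    Columns where the reference sequence has a gap map to ``NA``.
    """
    records = _records(alignment)
    match = [r for r in records if r.id == reference]
    if not match:
        raise SgedError(f"sequence {reference!r} not found in alignment")
    seq = str(match[0].seq)
    entries: dict = {}
    pos = 0
    for col, ch in enumerate(seq, start=1):
        if ch in "-.":
            entries[SiteCoordinate.from_position(col)] = None
        else:
            pos += 1
            entries[SiteCoordinate.from_position(col)] = SiteCoordinate.from_position(pos)
    return CoordinateIndex(entries, {"source": "alignment", "target": f"sequence:{reference}"})


def build_concat_index(alignments, names=None) -> CoordinateIndex:
    """Map columns of a concatenated super-alignment back to their source.

    Targets are labelled positions ``name:column``.  Offsets are the
    cumulative alignment lengths, in the given order.
    """
    alignments = list(alignments)
    if not alignments:
        raise SgedError("need at least one alignment to concatenate")
    if names is None:
        names = [f"aln{i + 1}" for i in range(len(alignments))]
    names = list(names)
    if len(names) != len(alignments):
        raise SgedError("one name per alignment is required")
    entries: dict = {}
    offset = 0
    for aln, name in zip(alignments, names):
        length = aln.get_alignment_length() if hasattr(aln, "get_alignment_length") else int(aln)
        for local in range(1, length + 1):
            entries[SiteCoordinate.from_position(offset + local)] = SiteCoordinate.from_label(
                name, local
            )
        offset += length
    return CoordinateIndex(entries, {"source": "concatenated", "target": ",".join(names)})


@dataclass
class PairwiseAlignment:
    """A scored global alignment of two residue sequences."""

    aligned_a: str
    aligned_b: str
    score: float
    identities: int
    coverage: int  # aligned non-gap residue pairs

    def position_map(self) -> dict:
        """1-based position in a → 1-based position in b over aligned pairs."""
        mapping: dict = {}
        ia = ib = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
            if ca != "-" and cb != "-":
                mapping[ia] = ib
        return mapping


def pairwise_global_align(
    a: str,
    b: str,
    gap_open: float = -10.0,
    gap_extend: float | None = None,
    matrix=None,
) -> PairwiseAlignment:
    """Optimal global alignment of two amino-acid sequences.

    Affine gap model (``gap_extend`` defaults to ``gap_open / 2``), end gaps
    penalised, BLOSUM62 scores by default.  Characters outside the matrix
    alphabet are treated as ``X``.  Among co-optimal alignments the
    aligner's first traceback path is returned (deterministic, "high-road"
    preference of the underlying dynamic program).
    """
    if not a or not b:
        raise SgedError("cannot align an empty sequence")
    if gap_extend is None:
        gap_extend = gap_open / 2.0
    from Bio import Align
    from Bio.Align import substitution_matrices

    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    alphabet = set(str(matrix.alphabet))
    ca = "".join(ch if ch in alphabet else "X" for ch in a.upper())
    cb = "".join(ch if ch in alphabet else "X" for ch in b.upper())

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(ca, cb)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    identities = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    coverage = sum(1 for x, y in zip(s1, s2) if x != "-" and y != "-")
    return PairwiseAlignment(s1, s2, float(aln.score), identities, coverage)


def _chain_has_internal_gaps(residues) -> bool:
    numbers = sorted({r.number for r in residues})
    return any(b - a > 1 for a, b in zip(numbers, numbers[1:]))


def build_structure_index(
    alignment,
    structures,
    gap_open: float = -10.0,
    gap_extend: float | None = None,
    matrix=None,
    exclude_incomplete: bool = False,
) -> CoordinateIndex:
    """Map alignment columns onto the best-matching structure chain.

    Every alignment sequence is globally aligned against the resolved-residue
    sequence of every polymer chain of every candidate structure; the
    highest-scoring (sequence, chain) pair wins, with higher coverage as the
    tie-break and input order after that.  With ``exclude_incomplete``,
    chains whose residue numbering has internal gaps (missing residues
    between the first and last observed) are not considered.

    The returned index maps each 1-based alignment column to a
    structure-residue coordinate of the selected chain, or to ``NA`` when
    the column has no structural counterpart.
    """
    records = _records(alignment)
    if not records:
        raise SgedError("alignment is empty")
    candidates = []
    for st in structures:
        for chain in st.chains:
            poly = chain.polymer_residues()
            if not poly:
                continue
            if exclude_incomplete and _chain_has_internal_gaps(poly):
                continue
            candidates.append((st, chain, poly, chain.sequence()))
    if not candidates:
        raise SgedError("no usable structure: no candidate chain left")

    best = None
    for rec in records:
        seq = _ungap(str(rec.seq))
        if not seq:
            continue
        for st, chain, poly, chain_seq in candidates:
            aln = pairwise_global_align(seq, chain_seq, gap_open, gap_extend, matrix)
            key = (aln.score, aln.coverage)
            if best is None or key > best[0]:
                best = (key, rec, st, chain, poly, aln)
    if best is None:
        raise SgedError("no usable structure: all alignment sequences are empty")
    (score, coverage), rec, st, chain, poly, aln = best

    col_to_seq = build_alignment_index(records, rec.id)
    seq_to_chain = aln.position_map()
    entries: dict = {}
    for col_coord, seq_coord in col_to_seq.entries.items():
        tgt = None
        if seq_coord is not None:
            chain_pos = seq_to_chain.get(seq_coord.position)
            if chain_pos is not None:
                res = poly[chain_pos - 1]
                tgt = SiteCoordinate.from_residue(chain.id, res.name, res.number, res.icode)
        entries[col_coord] = tgt
    metadata = {
        "source": "alignment",
        "target": f"structure:{st.id} chain:{chain.id}",
        "sequence": rec.id,
        "structure": st.id,
        "chain": chain.id,
        "score": f"{score:g}",
        "coverage": str(coverage),
    }
    return CoordinateIndex(entries, metadata)


def translate_coords(table: SgedTable, index: CoordinateIndex, new_column: str) -> SgedTable:
    """Add a column with each group translated through ``index``.

    The new column is inserted right after the group column; all other
    columns, values and record order are untouched.  A group member mapped
    to ``NA`` by the index renders as ``NA`` inside the translated group; a
    member absent from the index altogether is an error.
    """
    if new_column in table.header:
        raise SgedError(f"column {new_column!r} already exists")
    header = [table.header[0], new_column] + list(table.header[1:])
    out_records = []
    for rec in table.records:
        translated = []
        for coord in rec.group:
            if coord is None:
                translated.append(None)
                continue
            translated.append(index[coord])  # raises if absent from the index
        value = str(Group(tuple(translated)))
        attrs = {new_column: value}
        attrs.update(rec.attributes)
        out_records.append(SgedRecord(rec.group, attrs))
    return SgedTable(header, out_records, list(table.comments), table.dialect)
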