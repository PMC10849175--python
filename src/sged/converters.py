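"""Converters producing SGED tables from external inputs.

Currently covered: site tables from codeml site-model output files (the
"mlc" file written by PAML's codeml, NEB/BEB sections) and residue lists
extracted from 3D structures.
"""

from __future__ import annotations

import re

from .core import Group, SgedError, SgedRecord, SgedTable, SiteCoordinate

__all__ = ["paml_to_sged", "structure_residue_list"]

# A site row of a codeml "Positively selected sites" table:
#     "   14 R      0.859*        3.74 +- 1.84"
# Significance stars stick to the probability; trailing columns (posterior
# mean of omega) are ignored.
_SITE_RE = re.compile(r"^\s*(\d+)\s+([A-Za-z*-])\s+(\d+\.\d+|\d+)(\*{0,2})(\s+.*)?$")

_SECTION_HEADERS = {
    "bayesian": "Bayes Empirical Bayes",
    "naive": "Naive Empirical Bayes",
}


def paml_to_sged(mlc_text: str, method: str = "bayesian", threshold: float = 0.0) -> SgedTable:
    """Convert a codeml site-model result file to an SGED table.

    ``method`` selects the empirical-Bayes flavour: ``"bayesian"`` reads the
    BEB section, ``"naive"`` the NEB section.  One record is produced per
    site whose posterior probability of the positive-selection class is at
    least ``threshold``; columns are ``Group``, ``amino_acid`` and
    ``probability``.  Positions are kept verbatim (they refer to the
    reference sequence used by codeml) and so is the probability text
    (``0.71`` stays ``0.71``).
    """
    if method not in _SECTION_HEADERS:
        raise SgedError(f"unknown method {method!r}; use 'bayesian' or 'naive'")
    wanted = _SECTION_HEADERS[method]
    other = {v for k, v in _SECTION_HEADERS.items() if k != method}

    lines = mlc_text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if wanted in line:
            start = i + 1
            break
    if start is None:
        raise SgedError(
            f"no '{wanted}' section found for method {method!r} in codeml output"
        )

    records = []
    for line in lines[start:]:
        if any(h in line for h in other) or line.startswith("The grid"):
            break
        m = _SITE_RE.match(line)
        if not m:
            continue
        pos, aa, prob, _stars, _rest = m.groups()
        if float(prob) >= threshold:
            group = Group.of(SiteCoordinate.from_position(int(pos)))
            records.append(SgedRecord(group, {"amino_acid": aa, "probability": prob}))
    return SgedTable(["Group", "amino_acid", "probability"], records)


def structure_residue_list(structure, chains=None, include_hetero: bool = False) -> SgedTable:
    """List the residues of a structure as single-site SGED records.

    One record per polymer residue (waters are dropped at load time,
    other hetero groups are excluded unless ``include_hetero``), group
    string ``[chain:RESNAMEnum]``, in chain-then-residue order.
    ``chains`` optionally restricts to a set of chain identifiers; a
    requested chain that does not exist is an error.
    """
    if chains is not None:
        chains = set(chains)
        known = {c.id for c in structure.chains}
        missing = chains - known
        if missing:
            raise SgedError(
                f"chain(s) {sorted(missing)} not found in structure {structure.id!r}"
            )
    records = []
    for chain in structure.chains:
        if chains is not None and chain.id not in chains:
            continue
        for res in chain.residues:
            if res.hetero and not include_hetero:
                continue
            coord = SiteCoordinate.from_residue(chain.id, res.name, res.number, res.icode)
            records.append(SgedRecord(Group.of(coord), {}))
    return SgedTable(["Group"], records)
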