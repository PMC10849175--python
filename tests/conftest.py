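"""Shared fixtures: printed worked-example tables and synthetic structures."""

from __future__ import annotations

import pytest

import sged
from sged.fixtures import (
    FixtureSpec,
    POSITIVE_SELECTION_EXAMPLE_SITES,
    make_structure_fixture,
)

# Residue names of the positively selected lysozyme sites on the matched
# structure chain (chain A of PDB entry 134L).
LYSOZYME_SITE_RESIDUES = {
    14: "ARG", 21: "ARG", 23: "ILE", 41: "ARG", 50: "ARG", 87: "ASP", 126: "GLN",
}


def possel_text() -> str:
    lines = ["Group\tamino_acid\tprobability"]
    for pos, aa, prob in POSITIVE_SELECTION_EXAMPLE_SITES:
        lines.append(f"[{pos}]\t{aa}\t{prob}")
    return "\n".join(lines) + "\n"


def translated_text() -> str:
    lines = ["Group\tPDB\tamino_acid\tprobability"]
    for pos, aa, prob in POSITIVE_SELECTION_EXAMPLE_SITES:
        res = LYSOZYME_SITE_RESIDUES[pos]
        lines.append(f"[{pos}]\t[A:{res}{pos}]\t{aa}\t{prob}")
    return "\n".join(lines) + "\n"


def grouped_text() -> str:
    inner = ";".join(
        f"A:{LYSOZYME_SITE_RESIDUES[pos]}{pos}"
        for pos, _, _ in POSITIVE_SELECTION_EXAMPLE_SITES
    )
    return f"Group\n[{inner}]\n"


def lysozyme_index() -> sged.CoordinateIndex:
    """Alignment-position → structure-residue index over the example sites."""
    entries = {}
    for pos, _, _ in POSITIVE_SELECTION_EXAMPLE_SITES:
        entries[sged.SiteCoordinate.from_position(pos)] = sged.SiteCoordinate.from_residue(
            "A", LYSOZYME_SITE_RESIDUES[pos], pos
        )
    return sged.CoordinateIndex(entries, {"source": "alignment", "target": "134L chain A"})


@pytest.fixture(scope="session")
def line_structure():
    """10 Cα atoms on a line at 3.8 Å spacing: all distances analytic."""
    text = make_structure_fixture(FixtureSpec(n_residues=10, geometry="extended-line", seed=1))
    return sged.read_structure_text(text, "PDB", name="line10")


@pytest.fixture(scope="session")
def globule_structure():
    """A compact 60-residue synthetic globule with full backbone atoms."""
    text = make_structure_fixture(
        FixtureSpec(n_residues=60, geometry="random-globule", seed=3)
    )
    return sged.read_structure_text(text, "PDB", name="globule60")


@pytest.fixture(scope="session")
def shell_structure():
    """One residue buried inside a spherical shell of 41 others."""
    text = make_structure_fixture(
        FixtureSpec(n_residues=42, geometry="shell-buried", seed=0)
    )
    return sged.read_structure_text(text, "PDB", name="shell42")


def residue_coord(structure, chain_id: str, number: int) -> sged.SiteCoordinate:
    res = structure.chain(chain_id).residues[number - 1]
    assert res.number == number
    return sged.SiteCoordinate.from_residue(chain_id, res.name, res.number, res.icode)
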