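"""Deterministic synthetic fixtures: structures, alignments, codeml output.

Everything here is generated from a seed so that tests and example
pipelines run offline and regenerate byte-identically.  Geometries are
chosen so ground truth is analytic:

* ``extended-line`` — Cα atoms on a straight line at a fixed spacing, so
  every pairwise distance is ``|i − j| × spacing``;
* ``helix`` — Cα atoms on an ideal α-helix (2.3 Å radius, 1.5 Å rise,
  100° twist per residue);
* ``random-globule`` — a self-avoiding random walk at 3.8 Å steps confined
  to a sphere, decorated with backbone + Cβ atoms, giving a compact fold
  with buried and exposed residues;
* ``shell-buried`` — one central residue enclosed by a spherical shell of
  residues, so the central residue's solvent accessibility is ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SgedError

__all__ = [
    "FixtureSpec",
    "AMINO_ACIDS_3",
    "POSITIVE_SELECTION_EXAMPLE_SITES",
    "make_structure_fixture",
    "make_alignment_fixture",
    "make_paml_mlc",
    "random_protein_sequence",
]

AMINO_ACIDS_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_AA1 = "".join(AMINO_ACIDS_3)

# The classic primate-lysozyme positive-selection demonstration data
# (codeml site models): sites of the positive-selection class with
# posterior probability ≥ 0.7 under the Bayes empirical Bayes computation.
POSITIVE_SELECTION_EXAMPLE_SITES = [
    (14, "R", "0.859"),
    (21, "R", "0.858"),
    (23, "I", "0.853"),
    (41, "R", "0.71"),
    (50, "R", "0.704"),
    (87, "D", "0.869"),
    (126, "Q", "0.71"),
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic structure fixture."""

    n_residues: int = 10
    geometry: str = "extended-line"  # extended-line | helix | random-globule | shell-buried
    seed: int = 0
    chain_id: str = "A"
    spacing: float = 3.8  # Å between consecutive Cα on the line / walk
    sequence: str | None = None  # one-letter codes; random if None
    shell_radius: float = 5.5  # Å, shell-buried geometry


def random_protein_sequence(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_AA1), size=n))


def _ca_positions(spec: FixtureSpec) -> np.ndarray:
    n = spec.n_residues
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "extended-line":
        return np.array([[i * spec.spacing, 0.0, 0.0] for i in range(n)])
    if spec.geometry == "helix":
        radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
        return np.array(
            [
                [radius * np.cos(i * twist), radius * np.sin(i * twist), i * rise]
                for i in range(n)
            ]
        )
    if spec.geometry == "random-globule":
        radius = max(2.0 * spec.spacing, 0.95 * spec.spacing * n ** (1.0 / 3.0))
        coords = [np.zeros(3)]
        for _ in range(1, n):
            best = None
            for _try in range(300):
                step = rng.normal(size=3)
                step *= spec.spacing / np.linalg.norm(step)
                cand = coords[-1] + step
                if np.linalg.norm(cand) > radius:
                    continue
                prev = np.array(coords[:-1]) if len(coords) > 1 else None
                clash = (
                    prev is not None
                    and np.min(np.linalg.norm(prev - cand, axis=1)) < 3.5
                )
                if not clash:
                    best = cand
                    break
                if best is None:
                    best = cand  # least-bad fallback if every try clashes
            if best is None:  # all tries left the sphere: step back inwards
                direction = -coords[-1] / max(np.linalg.norm(coords[-1]), 1e-9)
                best = coords[-1] + spec.spacing * direction
            coords.append(best)
        return np.array(coords)
    if spec.geometry == "shell-buried":
        # central residue at the origin, the rest on a Fibonacci sphere
        m = n - 1
        if m < 12:
            raise SgedError("shell-buried geometry needs at least 13 residues")
        golden = np.pi * (3.0 - np.sqrt(5.0))
        pts = []
        for i in range(m):
            z = 1.0 - 2.0 * (i + 0.5) / m
            r = np.sqrt(max(0.0, 1.0 - z * z))
            theta = golden * i
            pts.append(
                spec.shell_radius * np.array([r * np.cos(theta), r * np.sin(theta), z])
            )
        return np.vstack([np.zeros(3), pts])
    raise SgedError(f"unknown fixture geometry {spec.geometry!r}")


def _decorate(ca: np.ndarray, rng, sequence: str) -> list:
    """Backbone-like atoms (N, CA, C, O, CB; no CB for Gly) per Cα position."""
    atoms_per_res = []
    for pos, aa in zip(ca, sequence):
        u, v, w = rng.normal(size=(3, 3))
        u /= np.linalg.norm(u)
        v -= v @ u * u
        v /= np.linalg.norm(v)
        w -= w @ u * u + w @ v * v
        w /= np.linalg.norm(w)
        c = pos + 1.52 * v
        atoms = [
            ("N", "N", pos + 1.46 * u),
            ("CA", "C", pos),
            ("C", "C", c),
            ("O", "O", c + 1.23 * w),
        ]
        if aa.upper() != "G":
            atoms.append(("CB", "C", pos + 1.53 * (-0.6 * u - 0.8 * v)))
        atoms_per_res.append(atoms)
    return atoms_per_res


def _build_gemmi(spec: FixtureSpec, ca: np.ndarray, atoms_per_res: list):
    import gemmi

    seq = spec.sequence or random_protein_sequence(spec.n_residues, spec.seed)
    if len(seq) != spec.n_residues:
        raise SgedError("sequence length must equal n_residues")
    st = gemmi.Structure()
    st.name = f"synthetic-{spec.geometry}"
    model = gemmi.Model("1")
    chain = gemmi.Chain(spec.chain_id)
    serial = 1
    for i, atoms in enumerate(atoms_per_res):
        res = gemmi.Residue()
        res.name = AMINO_ACIDS_3.get(seq[i].upper(), "GLY")
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "A"
        for name, element, pos in atoms:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(element)
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            at.b_iso = 0.0
            at.serial = serial
            serial += 1
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def make_structure_fixture(spec: FixtureSpec, format: str = "PDB") -> str:
    """Write a synthetic coordinate file (PDB or mmCIF text) with known geometry.

    Line and helix geometries carry Cα atoms only (distance statistics);
    globule and shell geometries carry backbone + Cβ atoms so that surface
    computations are meaningful.  Deterministic given the spec's seed.
    """
    ca = _ca_positions(spec)
    rng = np.random.default_rng(spec.seed + 1)
    seq = spec.sequence or random_protein_sequence(spec.n_residues, spec.seed)
    if spec.geometry in ("random-globule",):
        atoms_per_res = _decorate(ca, rng, seq)
    else:
        atoms_per_res = [[("CA", "C", pos)] for pos in ca]
    st = _build_gemmi(spec, ca, atoms_per_res)
    if format == "PDB":
        return st.make_pdb_string()
    if format == "mmCIF":
        return st.make_mmcif_document().as_string()
    raise SgedError(f"unknown structure format {format!r}")


def make_alignment_fixture(
    n_seqs: int = 4,
    n_columns: int = 30,
    gap_fraction: float = 0.2,
    seed: int = 0,
):
    """An alignment with planted gaps plus the true column → position maps.

    Returns ``(fasta_text, truth)`` where ``truth[name][col]`` (1-based
    columns) is the ungapped 1-based position of that column in sequence
    ``name``, or ``None`` where the sequence has a gap.
    """
    rng = np.random.default_rng(seed)
    names = [f"seq{i + 1}" for i in range(n_seqs)]
    rows = {}
    truth = {}
    for name in names:
        chars = []
        mapping = {}
        pos = 0
        for col in range(1, n_columns + 1):
            if rng.random() < gap_fraction:
                chars.append("-")
                mapping[col] = None
            else:
                pos += 1
                chars.append(str(rng.choice(list(_AA1))))
                mapping[col] = pos
        rows[name] = "".join(chars)
        truth[name] = mapping
    fasta = "".join(f">{name}\n{rows[name]}\n" for name in names)
    return fasta, truth


def make_paml_mlc(beb_sites=None, neb_sites=None, reference_name: str = "sequence_1") -> str:
    """A synthetic codeml-style "mlc" site-model output (layout mimic only).

    ``beb_sites`` / ``neb_sites`` are lists of ``(position, amino_acid,
    probability_text)``; the Bayes empirical Bayes section defaults to the
    classic lysozyme example sites.  Only the site tables carry meaning —
    the surrounding text is a synthetic stand-in for a real codeml run.
    """
    if beb_sites is None:
        beb_sites = POSITIVE_SELECTION_EXAMPLE_SITES
    if neb_sites is None:
        neb_sites = beb_sites

    def site_block(sites):
        lines = []
        for pos, aa, prob in sites:
            p = float(prob)
            stars = "**" if p > 0.99 else "*" if p > 0.95 else ""
            lines.append(f"{pos:>6} {aa}      {prob}{stars}")
        return "\n".join(lines)

    return f"""CODONML (synthetic fixture) lnL = -1043.0
Model 2: PositiveSelection

Naive Empirical Bayes (NEB) analysis
Positively selected sites (*: P>95%; **: P>99%)
(amino acids refer to 1st sequence: {reference_name})

            Pr(w>1)

{site_block(neb_sites)}

Bayes Empirical Bayes (BEB) analysis (Yang, Wong & Nielsen 2005)
Positively selected sites (*: P>95%; **: P>99%)
(amino acids refer to 1st sequence: {reference_name})

            Pr(w>1)     post mean +- SE for w

{site_block(beb_sites)}

The grid (synthetic)
"""
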