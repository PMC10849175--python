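"""Structure model and per-residue / per-group structural statistics.

Structures are read with gemmi (PDB and mmCIF) into a small chain →
residue → atom model.  Statistics over residue groups:

* ``alpha_dist`` — mean/min/max pairwise Cα distance (Å);
* ``rsa_per_residue`` — relative solvent accessibility, either through the
  external DSSP program (which also yields a secondary-structure class) or
  through a built-in rolling-probe (Shrake–Rupley) surface computation,
  normalised by the theoretical maximum accessible areas of Tien et al.
  (2013), capped at 1;
* ``count_clusters`` — number of spatial clusters in a group, i.e. flat
  clusters of a single-linkage (nearest-neighbour) hierarchical tree cut at
  a distance threshold;
* ``residue_depth`` — mean atom depth below the molecular surface via the
  external MSMS program (optional feature);
* ``structure_infos`` — append any of the above as SGED columns.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

from .core import Group, NA_TOKEN, SgedError, SgedTable, SiteCoordinate

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "StructureDataError",
    "BackendUnavailableError",
    "FeatureUnavailableError",
    "MAX_ASA",
    "AlphaDistances",
    "ResidueMeasures",
    "AccessibilityResult",
    "load_structure",
    "read_structure_text",
    "alpha_dist",
    "rsa_per_residue",
    "count_clusters",
    "residue_depth",
    "structure_infos",
]


class StructureDataError(SgedError):
    """A coordinate does not resolve in the structure, or data is missing."""


class BackendUnavailableError(SgedError):
    """The requested accessibility backend cannot run."""


class FeatureUnavailableError(SgedError):
    """An optional external-program feature is not available."""


@dataclass
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    name: str
    number: int
    icode: str = ""
    atoms: list = field(default_factory=list)
    hetero: bool = False

    @property
    def is_polymer(self) -> bool:
        return not self.hetero

    def atom(self, name: str):
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        import gemmi

        info = gemmi.find_tabulated_residue(self.name)
        if info is not None and info.is_amino_acid():
            letter = info.one_letter_code.upper()
            return letter if letter.isalpha() else "X"
        return "X"


@dataclass
class Chain:
    id: str
    residues: list = field(default_factory=list)

    def polymer_residues(self) -> list:
        return [r for r in self.residues if r.is_polymer]

    def sequence(self) -> str:
        """One-letter sequence of the resolved polymer residues."""
        return "".join(r.one_letter for r in self.polymer_residues())


@dataclass
class StructureModel:
    id: str
    chains: list = field(default_factory=list)
    source_path: str | None = None

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise StructureDataError(f"chain {chain_id!r} not found in structure {self.id!r}")

    def residue(self, coord: SiteCoordinate) -> Residue:
        """Resolve a structure-residue coordinate to exactly one residue."""
        if coord.kind != SiteCoordinate.STRUCTURE:
            raise StructureDataError(
                f"coordinate {coord} is not a structure-residue coordinate"
            )
        chain = self.chain(coord.chain_id)
        for res in chain.residues:
            if res.number == coord.residue_number and res.icode == coord.insertion_code:
                if res.name.upper() != coord.residue_name.upper():
                    raise StructureDataError(
                        f"residue {coord} has name {res.name!r} in structure {self.id!r}"
                    )
                return res
        raise StructureDataError(f"residue {coord} not found in structure {self.id!r}")


def _pick_altlocs(atoms: list) -> list:
    """Keep one atom per atom name: highest occupancy, ties to the first seen."""
    best: dict = {}
    order: list = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def _from_gemmi(st) -> StructureModel:
    import gemmi

    st.setup_entities()
    st.remove_hydrogens()
    st.remove_waters()
    model = st[0]  # first model only
    chains = []
    for ch in model:
        residues = []
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            hetero = not (info is not None and info.is_amino_acid())
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    x=a.pos.x,
                    y=a.pos.y,
                    z=a.pos.z,
                    occupancy=a.occ,
                    altloc=a.altloc,
                )
                for a in res
            ]
            atoms = _pick_altlocs(atoms)
            seqid = res.seqid
            residues.append(
                Residue(
                    name=res.name,
                    number=seqid.num,
                    icode=(seqid.icode or "").strip(),
                    atoms=atoms,
                    hetero=hetero,
                )
            )
        if residues:
            chains.append(Chain(id=ch.name, residues=residues))
    return StructureModel(id=st.name or "", chains=chains)


def load_structure(path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` is ``"PDB"``, ``"mmCIF"`` or ``None`` (detect from content).
    Only the first model of multi-model files is kept; waters and hydrogens
    are dropped; alternate locations are resolved to the highest-occupancy
    conformer (ties: first encountered).
    """
    import gemmi

    fmts = {
        "PDB": gemmi.CoorFormat.Pdb,
        "mmCIF": gemmi.CoorFormat.Mmcif,
        None: gemmi.CoorFormat.Detect,
    }
    if format not in fmts:
        raise SgedError(f"unknown structure format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmts[format])
    except (RuntimeError, ValueError) as exc:
        raise SgedError(f"cannot parse structure file {path}: {exc}") from exc
    model = _from_gemmi(st)
    model.source_path = str(path)
    if not model.id:
        model.id = str(path)
    return model


def read_structure_text(text: str, format: str = "PDB", name: str = "") -> StructureModel:
    """Parse PDB or mmCIF content given as a string."""
    import gemmi

    if format == "PDB":
        st = gemmi.read_pdb_string(text)
    elif format == "mmCIF":
        doc = gemmi.cif.read_string(text)
        st = gemmi.make_structure_from_block(doc.sole_block())
    else:
        raise SgedError(f"unknown structure format {format!r}")
    model = _from_gemmi(st)
    if name:
        model.id = name
    return model


@dataclass
class AlphaDistances:
    mean: float
    min: float
    max: float


def _resolve_group(group: Group, structure: StructureModel) -> list:
    residues = []
    for coord in group:
        if coord is None:
            raise StructureDataError("group contains an NA coordinate")
        residues.append(structure.residue(coord))
    return residues


def _ca_coords(group: Group, structure: StructureModel) -> np.ndarray:
    coords = []
    for coord, res in zip(group, _resolve_group(group, structure)):
        ca = res.atom("CA")
        if ca is None:
            raise StructureDataError(f"residue {coord} has no Cα atom")
        coords.append(ca.coord)
    return np.array(coords)


def alpha_dist(group: Group, structure: StructureModel) -> AlphaDistances:
    """Mean/min/max Euclidean Cα–Cα distance over all unordered pairs (Å)."""
    coords = _ca_coords(group, structure)
    if len(coords) < 2:
        raise StructureDataError("alpha_dist needs a group of at least two residues")
    d = pdist(coords)
    return AlphaDistances(mean=float(d.mean()), min=float(d.min()), max=float(d.max()))


def count_clusters(
    group: Group, structure: StructureModel, threshold: float, distance: str = "ca"
) -> int:
    """Number of clusters in a group under single linkage cut at ``threshold``.

    Equivalently: connected components of the graph whose edges join residue
    pairs at distance ≤ threshold.  ``distance`` is ``"ca"`` (Cα–Cα, the
    default, consistent with ``alpha_dist``) or ``"min"`` (minimal
    inter-atomic distance).
    """
    residues = _resolve_group(group, structure)
    n = len(residues)
    if n == 1:
        return 1
    if distance == "ca":
        d = pdist(_ca_coords(group, structure))
    elif distance == "min":
        coords = [np.array([a.coord for a in r.atoms]) for r in residues]
        d = np.array(
            [
                cdist(coords[i], coords[j]).min()
                for i in range(n)
                for j in range(i + 1, n)
            ]
        )
    else:
        raise SgedError(f"unknown distance mode {distance!r}")
    tree = linkage(d, method="single")
    labels = fcluster(tree, t=threshold, criterion="distance")
    return int(len(set(labels)))


# Theoretical maximum accessible surface areas (Å²) per residue, from
# Tien et al. 2013 (PLoS ONE 8:e80635), used to turn absolute areas into
# relative solvent accessibilities.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class ResidueMeasures:
    rsa: float | None = None
    secondary_structure: str | None = None
    depth: float | None = None


@dataclass
class AccessibilityResult:
    per_residue: dict  # (chain_id, residue_number, icode) -> ResidueMeasures
    backend: str

    def get(self, coord: SiteCoordinate) -> ResidueMeasures | None:
        return self.per_residue.get(
            (coord.chain_id, coord.residue_number, coord.insertion_code)
        )


def _dssp_executable() -> str | None:
    for name in ("mkdssp", "dssp"):
        exe = shutil.which(name)
        if exe:
            return exe
    return None


def _rsa_internal(structure: StructureModel, probe_radius: float, point_number: int) -> AccessibilityResult:
    import biotite.structure as bst

    atoms = []
    owner = []
    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                atoms.append((chain.id, res, a))
                owner.append((chain.id, res.number, res.icode))
    n = len(atoms)
    if n == 0:
        raise StructureDataError("structure has no atoms")
    arr = bst.AtomArray(n)
    arr.coord = np.array([[a.x, a.y, a.z] for _, _, a in atoms])
    arr.chain_id = np.array([c for c, _, _ in atoms])
    arr.res_id = np.array([r.number for _, r, _ in atoms])
    arr.res_name = np.array([r.name for _, r, _ in atoms])
    arr.atom_name = np.array([a.name for _, _, a in atoms])
    arr.element = np.array([a.element.upper() for _, _, a in atoms])
    arr.hetero = np.array([r.hetero for _, r, _ in atoms])
    try:
        area = bst.sasa(
            arr, probe_radius=probe_radius, point_number=point_number, vdw_radii="ProtOr"
        )
    except KeyError:
        # atoms unknown to the united-atom radius set: fall back to element radii
        area = bst.sasa(
            arr, probe_radius=probe_radius, point_number=point_number, vdw_radii="Single"
        )
    if np.isnan(area).any():
        area2 = bst.sasa(
            arr, probe_radius=probe_radius, point_number=point_number, vdw_radii="Single"
        )
        area = np.where(np.isnan(area), area2, area)
    totals: dict = {}
    for key, a in zip(owner, area):
        totals[key] = totals.get(key, 0.0) + float(np.nan_to_num(a))
    measures: dict = {}
    for chain in structure.chains:
        for res in chain.residues:
            key = (chain.id, res.number, res.icode)
            max_area = MAX_ASA.get(res.name.upper())
            if max_area is None or res.hetero:
                measures[key] = ResidueMeasures(rsa=None)
            else:
                measures[key] = ResidueMeasures(rsa=min(1.0, totals.get(key, 0.0) / max_area))
    return AccessibilityResult(per_residue=measures, backend="internal")


def _rsa_dssp(structure: StructureModel) -> AccessibilityResult:
    exe = _dssp_executable()
    if exe is None:
        raise BackendUnavailableError(
            "DSSP executable (mkdssp/dssp) not found on PATH; "
            "use backend='internal' for the built-in surface computation"
        )
    if structure.source_path is None:
        raise BackendUnavailableError(
            "DSSP backend needs a structure loaded from a file (source_path is unset)"
        )
    from Bio.PDB import MMCIFParser, PDBParser
    from Bio.PDB.DSSP import DSSP

    path = structure.source_path
    if path.lower().endswith(".cif"):
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    model = parser.get_structure(structure.id or "s", path)[0]
    dssp = DSSP(model, path, dssp=exe)
    measures: dict = {}
    for (chain_id, res_id), row in zip(dssp.keys(), (dssp[k] for k in dssp.keys())):
        _, number, icode = res_id
        ss = row[2]
        rsa = row[3]
        measures[(chain_id, number, icode.strip())] = ResidueMeasures(
            rsa=None if rsa == "NA" else min(1.0, float(rsa)),
            secondary_structure=None if ss == "-" else ss,
        )
    return AccessibilityResult(per_residue=measures, backend="dssp")


def rsa_per_residue(
    structure: StructureModel,
    backend: str = "auto",
    probe_radius: float = 1.4,
    point_number: int = 500,
) -> AccessibilityResult:
    """Relative solvent accessibility for every residue of the structure.

    ``backend``: ``"dssp"`` requires the external DSSP program and also
    yields a secondary-structure class per residue; ``"internal"`` uses the
    built-in Shrake–Rupley surface computation (probe 1.4 Å by default,
    united-atom radii) and leaves the secondary structure unset;
    ``"auto"`` picks DSSP when installed, the internal backend otherwise.
    RSA = accessible area / maximum reference area, capped at 1; residues
    without a reference area (non-standard, hetero) get ``None``.
    """
    if backend == "auto":
        backend = "dssp" if _dssp_executable() else "internal"
    if backend == "dssp":
        return _rsa_dssp(structure)
    if backend == "internal":
        return _rsa_internal(structure, probe_radius, point_number)
    raise SgedError(f"unknown accessibility backend {backend!r}")


def residue_depth(group: Group, structure: StructureModel, msms_path: str | None = None) -> dict:
    """Mean atom depth (Å) below the molecular surface, per group residue.

    Requires Michel Sanner's MSMS program; without it a
    :class:`FeatureUnavailableError` is raised (the feature is optional).
    """
    exe = msms_path or shutil.which("msms")
    if exe is None:
        raise FeatureUnavailableError(
            "residue depth requires the external MSMS program, which was not found"
        )
    if structure.source_path is None:
        raise FeatureUnavailableError("residue depth needs a structure loaded from a file")
    from Bio.PDB import PDBParser
    from Bio.PDB.ResidueDepth import ResidueDepth

    model = PDBParser(QUIET=True).get_structure(structure.id or "s", structure.source_path)[0]
    rd = ResidueDepth(model, msms_exec=exe)
    depths: dict = {}
    for coord in group:
        res = structure.residue(coord)  # validates the coordinate
        key = (coord.chain_id, (" ", coord.residue_number, coord.insertion_code or " "))
        if key not in rd:
            raise StructureDataError(f"no depth value for residue {coord}")
        depths[coord] = float(rd[key][0])
        del res
    return depths


_KNOWN_MEASURES = ("AlphaDist", "DSSP", "DSSPsum", "NbClusters")


def _fmt(value: float, digits: int = 4) -> str:
    return f"{value:.{digits}f}"


def structure_infos(
    table: SgedTable,
    structure: StructureModel,
    measures,
    backend: str = "auto",
    cluster_threshold: float | None = None,
    probe_radius: float = 1.4,
) -> SgedTable:
    """Append structural statistics as new columns to an SGED table.

    ``measures`` is a list of tokens:

    * ``"AlphaDist"`` → ``AlphaDistMean``, ``AlphaDistMin``, ``AlphaDistMax``
      (Å; groups must have ≥ 2 residues);
    * ``"DSSP"`` → per-residue ``Rsa`` (fraction) and ``SecStruct``,
      semicolon-joined over group members;
    * ``"DSSPsum"`` → group summary ``RsaMean`` (percent) and
      ``SecStructCount``;
    * ``"NbClusters"`` → single-linkage cluster count at
      ``cluster_threshold`` Å.

    Existing columns and record order are preserved; an empty measure list
    returns the table unchanged.  The accessibility backend actually used
    is recorded in a comment line.
    """
    measures = list(measures)
    for m in measures:
        if m not in _KNOWN_MEASURES:
            raise SgedError(f"unknown measure {m!r}; known: {_KNOWN_MEASURES}")
    out = table.copy()
    if not measures:
        return out
    access = None
    if "DSSP" in measures or "DSSPsum" in measures:
        access = rsa_per_residue(structure, backend=backend, probe_radius=probe_radius)
        out.comments.append(f"# accessibility backend: {access.backend}")
    if "NbClusters" in measures and cluster_threshold is None:
        raise SgedError("measure 'NbClusters' requires a cluster distance threshold")

    new_cols: list = []
    for m in measures:
        if m == "AlphaDist":
            new_cols += ["AlphaDistMean", "AlphaDistMin", "AlphaDistMax"]
        elif m == "DSSP":
            new_cols += ["Rsa", "SecStruct"]
        elif m == "DSSPsum":
            new_cols += ["RsaMean", "SecStructCount"]
        elif m == "NbClusters":
            new_cols += ["NbClusters"]
    for c in new_cols:
        if c in out.header:
            raise SgedError(f"column {c!r} already present in table")
    out.header = out.header + new_cols

    for rec in out.records:
        values: dict = {}
        for m in measures:
            if m == "AlphaDist":
                d = alpha_dist(rec.group, structure)
                values["AlphaDistMean"] = _fmt(d.mean)
                values["AlphaDistMin"] = _fmt(d.min)
                values["AlphaDistMax"] = _fmt(d.max)
            elif m == "DSSP":
                rsas, sss = [], []
                for coord in rec.group:
                    if coord is None:
                        raise StructureDataError("group contains an NA coordinate")
                    structure.residue(coord)  # raise a clear error if unresolvable
                    meas = access.get(coord)
                    if meas is None or meas.rsa is None:
                        rsas.append(NA_TOKEN)
                    else:
                        rsas.append(_fmt(meas.rsa))
                    sss.append(
                        meas.secondary_structure
                        if meas is not None and meas.secondary_structure
                        else NA_TOKEN
                    )
                values["Rsa"] = ";".join(rsas)
                values["SecStruct"] = ";".join(sss)
            elif m == "DSSPsum":
                rsas, sss = [], []
                for coord in rec.group:
                    if coord is None:
                        raise StructureDataError("group contains an NA coordinate")
                    structure.residue(coord)
                    meas = access.get(coord)
                    if meas is not None and meas.rsa is not None:
                        rsas.append(meas.rsa)
                    if meas is not None and meas.secondary_structure:
                        sss.append(meas.secondary_structure)
                values["RsaMean"] = (
                    _fmt(100.0 * float(np.mean(rsas)), 2) if rsas else NA_TOKEN
                )
                if sss:
                    counts = {}
                    for s in sss:
                        counts[s] = counts.get(s, 0) + 1
                    values["SecStructCount"] = ";".join(
                        f"{k}={v}" for k, v in sorted(counts.items())
                    )
                else:
                    values["SecStructCount"] = NA_TOKEN
            elif m == "NbClusters":
                values["NbClusters"] = str(
                    count_clusters(rec.group, structure, cluster_threshold)
                )
        rec.attributes.update(values)
    return out
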