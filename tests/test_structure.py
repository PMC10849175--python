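"""Structure loading and group statistics: Cα distances, clusters, RSA, depth."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

import sged
from sged.core import Group, SgedError, parse_sged
from sged.fixtures import FixtureSpec, make_structure_fixture
from sged.structure import (
    BackendUnavailableError,
    FeatureUnavailableError,
    StructureDataError,
    StructureModel,
    _dssp_executable,
)

from conftest import residue_coord


def group_of(structure, numbers, chain="A"):
    return Group(tuple(residue_coord(structure, chain, n) for n in numbers))


# -------------------------------------------------------------------- loading

def test_load_pdb_fixture(tmp_path):
    text = make_structure_fixture(FixtureSpec(n_residues=3, geometry="extended-line", seed=2))
    path = tmp_path / "three.pdb"
    path.write_text(text)
    model = sged.load_structure(path, format="PDB")
    assert len(model.chains) == 1
    assert len(model.chains[0].residues) == 3
    assert model.source_path == str(path)


def test_pdb_and_mmcif_give_identical_models():
    spec = FixtureSpec(n_residues=8, geometry="random-globule", seed=5)
    m_pdb = sged.read_structure_text(make_structure_fixture(spec, "PDB"), "PDB")
    m_cif = sged.read_structure_text(make_structure_fixture(spec, "mmCIF"), "mmCIF")
    assert [c.id for c in m_pdb.chains] == [c.id for c in m_cif.chains]
    for ra, rb in zip(m_pdb.chains[0].residues, m_cif.chains[0].residues):
        assert (ra.name, ra.number) == (rb.name, rb.number)
        for aa, ab in zip(ra.atoms, rb.atoms):
            assert aa.name == ab.name
            assert np.allclose(aa.coord, ab.coord, atol=1e-3)


def test_altloc_keeps_highest_occupancy():
    text = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C  \n"
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C  \n"
        "ATOM      3  CA  ALA A   2       9.000   0.000   0.000  1.00  0.00           C  \n"
        "END\n"
    )
    model = sged.read_structure_text(text, "PDB")
    res1 = model.chains[0].residues[0]
    assert len(res1.atoms) == 1
    assert res1.atom("CA").x == pytest.approx(5.0)


def test_waters_dropped_and_hetero_flagged():
    text = (
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C  \n"
        "HETATM    2  C1  XYZ A 200       9.000   0.000   0.000  1.00  0.00           C  \n"
        "HETATM    3  O   HOH A 300       2.000   0.000   0.000  1.00  0.00           O  \n"
        "END\n"
    )
    model = sged.read_structure_text(text, "PDB")
    residues = [r for c in model.chains for r in c.residues]
    assert sorted(r.name for r in residues) == ["ALA", "XYZ"]
    flags = {r.name: r.hetero for r in residues}
    assert flags == {"ALA": False, "XYZ": True}


def test_unresolvable_coordinate_raises(line_structure):
    with pytest.raises(StructureDataError):
        line_structure.residue(sged.SiteCoordinate.from_residue("A", "ARG", 999))
    with pytest.raises(StructureDataError):
        line_structure.chain("Q")


# ----------------------------------------------------------------- alpha_dist

def test_alpha_dist_3_4_5_triangle():
    text = (
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C  \n"
        "ATOM      2  CA  GLY A   2       3.000   4.000   0.000  1.00  0.00           C  \n"
        "END\n"
    )
    model = sged.read_structure_text(text, "PDB")
    d = sged.alpha_dist(group_of(model, [1, 2]), model)
    assert d.mean == d.min == d.max == pytest.approx(5.0)


def test_alpha_dist_line_endpoints(line_structure):
    d = sged.alpha_dist(group_of(line_structure, [1, 10]), line_structure)
    assert d.mean == pytest.approx(9 * 3.8)


def test_alpha_dist_matches_brute_force_enumeration(globule_structure):
    rng = np.random.default_rng(0)
    coords_by_num = {
        r.number: r.atom("CA").coord for r in globule_structure.chains[0].residues
    }
    for _ in range(10):
        numbers = rng.choice(60, size=5, replace=False) + 1
        group = group_of(globule_structure, numbers)
        d = sged.alpha_dist(group, globule_structure)
        pairs = [
            float(np.linalg.norm(coords_by_num[a] - coords_by_num[b]))
            for a, b in itertools.combinations(numbers, 2)
        ]
        assert d.mean == pytest.approx(np.mean(pairs))
        assert d.min == pytest.approx(np.min(pairs))
        assert d.max == pytest.approx(np.max(pairs))


def test_alpha_dist_rigid_motion_invariance_and_scaling(globule_structure):
    import copy

    group = group_of(globule_structure, [3, 12, 25, 40])
    base = sged.alpha_dist(group, globule_structure)

    # rotate + translate every atom
    theta = 0.8
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    shift = np.array([10.0, -4.0, 2.5])
    moved = copy.deepcopy(globule_structure)
    scaled = copy.deepcopy(globule_structure)
    for model, transform in ((moved, lambda p: rot @ p + shift), (scaled, lambda p: 2.0 * p)):
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.x, atom.y, atom.z = transform(atom.coord)
    after = sged.alpha_dist(group, moved)
    assert after.mean == pytest.approx(base.mean)
    assert after.max == pytest.approx(base.max)
    doubled = sged.alpha_dist(group, scaled)
    assert doubled.mean == pytest.approx(2 * base.mean)


def test_alpha_dist_errors(line_structure, globule_structure):
    with pytest.raises(StructureDataError):  # singleton: no pairs
        sged.alpha_dist(group_of(line_structure, [1]), line_structure)
    # a residue without CA
    text = (
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C  \n"
        "ATOM      2  CB  ALA A   2       3.000   0.000   0.000  1.00  0.00           C  \n"
        "END\n"
    )
    model = sged.read_structure_text(text, "PDB")
    with pytest.raises(StructureDataError, match="A:ALA2"):
        sged.alpha_dist(group_of(model, [1, 2]), model)


# ------------------------------------------------------------- count_clusters

def test_cluster_count_thresholds_on_line(line_structure):
    group = group_of(line_structure, range(1, 11))
    assert sged.count_clusters(group, line_structure, threshold=4.0) == 1
    assert sged.count_clusters(group, line_structure, threshold=3.0) == 10
    assert sged.count_clusters(group_of(line_structure, [5]), line_structure, 1.0) == 1


def test_cluster_count_matches_graph_components_oracle(globule_structure):
    """Single-linkage flat clusters equal connected components of the
    distance-threshold graph (networkx oracle)."""
    import networkx as nx

    rng = np.random.default_rng(1)
    for trial in range(8):
        numbers = rng.choice(60, size=6, replace=False) + 1
        group = group_of(globule_structure, numbers)
        coords = np.array(
            [globule_structure.residue(c).atom("CA").coord for c in group]
        )
        threshold = float(rng.uniform(4, 25))
        g = nx.Graph()
        g.add_nodes_from(range(6))
        for i, j in itertools.combinations(range(6), 2):
            if np.linalg.norm(coords[i] - coords[j]) <= threshold:
                g.add_edge(i, j)
        expected = nx.number_connected_components(g)
        assert sged.count_clusters(group, globule_structure, threshold) == expected


def test_cluster_count_monotone_in_threshold(globule_structure):
    group = group_of(globule_structure, [2, 9, 17, 33, 48, 60])
    counts = [
        sged.count_clusters(group, globule_structure, t) for t in (1, 5, 10, 20, 40)
    ]
    assert counts == sorted(counts, reverse=True)
    d = sged.alpha_dist(group, globule_structure)
    assert sged.count_clusters(group, globule_structure, d.max) == 1
    assert sged.count_clusters(group, globule_structure, d.min - 1e-6) == 6


# ---------------------------------------------------------------------- RSA

def test_isolated_residue_is_fully_exposed():
    spec = FixtureSpec(n_residues=1, geometry="random-globule", seed=0, sequence="A")
    model = sged.read_structure_text(make_structure_fixture(spec), "PDB")
    acc = sged.rsa_per_residue(model, backend="internal")
    assert acc.per_residue[("A", 1, "")].rsa == pytest.approx(1.0)


def test_enclosed_residue_is_buried(shell_structure):
    acc = sged.rsa_per_residue(shell_structure, backend="internal")
    assert acc.per_residue[("A", 1, "")].rsa == pytest.approx(0.0, abs=0.02)
    surface = [m.rsa for key, m in acc.per_residue.items() if key[1] != 1]
    assert min(surface) > 0.05  # every shell residue is clearly more exposed


def _oracle_sasa(structure, n_points=400, probe=1.4, seed=0):
    """Independent Monte-Carlo sphere-sampling surface area per residue."""
    radii = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
    atoms, owner = [], []
    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                atoms.append((a.coord, radii.get(a.element.upper(), 1.7) + probe))
                owner.append((chain.id, res.number, res.icode))
    centers = np.array([c for c, _ in atoms])
    radii_arr = np.array([r for _, r in atoms])
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    per_residue: dict = {}
    for i, ((center, radius), key) in enumerate(zip(atoms, owner)):
        sphere = center + radius * pts
        d = np.linalg.norm(sphere[:, None, :] - centers[None, :, :], axis=2)
        d[:, i] = np.inf
        exposed = np.all(d >= radii_arr[None, :], axis=1)
        area = 4 * np.pi * radius**2 * exposed.mean()
        per_residue[key] = per_residue.get(key, 0.0) + area
    return per_residue


def test_internal_rsa_ranks_residues_like_sampling_oracle(globule_structure):
    acc = sged.rsa_per_residue(globule_structure, backend="internal")
    oracle = _oracle_sasa(globule_structure)
    keys = sorted(oracle)
    ours = [acc.per_residue[k].rsa for k in keys]
    theirs = [oracle[k] for k in keys]
    rho = spearmanr(ours, theirs).statistic
    assert rho > 0.9


def test_dssp_backend_unavailable_suggests_internal(globule_structure):
    if _dssp_executable() is not None:
        pytest.skip("DSSP installed; unavailability path not exercisable")
    with pytest.raises(BackendUnavailableError, match="internal"):
        sged.rsa_per_residue(globule_structure, backend="dssp")


def test_depth_feature_disabled_without_msms(globule_structure):
    import shutil

    if shutil.which("msms"):
        pytest.skip("MSMS installed; unavailability path not exercisable")
    group = group_of(globule_structure, [1, 2])
    with pytest.raises(FeatureUnavailableError, match="MSMS"):
        sged.residue_depth(group, globule_structure)


# ------------------------------------------------------------ structure_infos

def test_structure_infos_appends_without_touching_input(globule_structure):
    table = parse_sged(
        "Group\tstat\n"
        "[A:%s]\t0.5\n" % f"{globule_structure.chains[0].residues[0].name}1"
    )
    out = sged.structure_infos(
        table, globule_structure, ["DSSP"], backend="internal"
    )
    assert out.header == ["Group", "stat", "Rsa", "SecStruct"]
    assert len(out) == len(table)
    assert out.column("stat") == table.column("stat")
    assert table.header == ["Group", "stat"]  # input untouched
    assert float(out.records[0].attributes["Rsa"]) >= 0.0


def test_structure_infos_empty_measures_is_identity(globule_structure):
    table = parse_sged("Group\n[A:%s1]\n" % globule_structure.chains[0].residues[0].name)
    out = sged.structure_infos(table, globule_structure, [])
    assert out.header == table.header
    assert [r.group for r in out.records] == [r.group for r in table.records]


def test_structure_infos_group_summary_columns(globule_structure):
    group = group_of(globule_structure, [5, 12, 30, 44])
    table = sged.SgedTable(["Group"], [sged.SgedRecord(group, {})])
    out = sged.structure_infos(
        table,
        globule_structure,
        ["AlphaDist", "DSSPsum", "NbClusters"],
        backend="internal",
        cluster_threshold=10.0,
    )
    rec = out.records[0]
    d = sged.alpha_dist(group, globule_structure)
    assert float(rec.attributes["AlphaDistMean"]) == pytest.approx(d.mean, abs=1e-3)
    assert float(rec.attributes["AlphaDistMin"]) == pytest.approx(d.min, abs=1e-3)
    assert float(rec.attributes["AlphaDistMax"]) == pytest.approx(d.max, abs=1e-3)
    acc = sged.rsa_per_residue(globule_structure, backend="internal")
    expected_rsa = 100 * np.mean([acc.get(c).rsa for c in group])
    assert float(rec.attributes["RsaMean"]) == pytest.approx(expected_rsa, abs=0.01)
    assert rec.attributes["NbClusters"] == str(
        sged.count_clusters(group, globule_structure, 10.0)
    )
    assert any(c.startswith("# accessibility backend") for c in out.comments)


def test_structure_infos_per_residue_on_residue_list(globule_structure):
    table = sged.structure_residue_list(globule_structure)
    out = sged.structure_infos(table, globule_structure, ["DSSP"], backend="internal")
    assert len(out) == 60
    values = [float(v) for v in out.column("Rsa")]
    assert all(0.0 <= v <= 1.0 for v in values)


def test_structure_infos_unknown_measure_and_bad_coordinate(globule_structure):
    table = parse_sged("Group\n[A:ARG999]\n")
    with pytest.raises(SgedError):
        sged.structure_infos(table, globule_structure, ["Nope"])
    with pytest.raises(StructureDataError, match="A:ARG999"):
        sged.structure_infos(table, globule_structure, ["AlphaDist"])
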