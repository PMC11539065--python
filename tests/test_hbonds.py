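"""Hydrogen-bond detection, counting, clustering and occupancy."""
import numpy as np
import pandas as pd
import pytest

from fabsolv.hbonds import (
    ANGLE_DHA_LINEARITY,
    ANGLE_HDA,
    DIST_DONOR_ACCEPTOR,
    DIST_HYDROGEN_ACCEPTOR,
    FAB_CRITERIA,
    GLY_GLY_CRITERIA,
    HBondCriteria,
    classify_clusters,
    count_hbonds_by_class,
    detect_hbonds,
    hbond_occupancy,
    site_occupancy,
    summarize_counts,
)
from fabsolv.model import ConformationEnsemble, MolecularSystem
from fabsolv.selection import select

from oracles import brute_force_hbonds, random_water_box


def _three_atom_system(acceptor_x):
    """Collinear D–H···A along x: donor at origin, H at 0.1 nm."""
    return MolecularSystem(
        names=["N", "H", "O"],
        elements=["N", "H", "O"],
        residue_ids=[1, 1, 2],
        residue_names=["GLY", "GLY", "HOH"],
        chain_ids=["G", "G", "W"],
        positions=[[0, 0, 0], [0.1, 0, 0], [acceptor_x, 0, 0]],
        molecule_index=[0, 0, 1],
        molecule_species=["glycine", "water"],
        h_parent=[-1, 0, -1],
    )


def test_collinear_bond_detected():
    system = _three_atom_system(0.3)
    recs = detect_hbonds(system, system.positions, select(system, "all"),
                         select(system, "all"), FAB_CRITERIA)
    assert len(recs) == 1
    rec = recs[0]
    assert (rec.donor_atom_id, rec.hydrogen_atom_id, rec.acceptor_atom_id) == (1, 2, 3)
    assert rec.distance == pytest.approx(0.3)
    assert rec.angle == pytest.approx(0.0, abs=1e-9)
    assert rec.partner_classes == ("glycine", "water")


def test_distance_beyond_cutoff_rejected():
    system = _three_atom_system(0.4)
    recs = detect_hbonds(system, system.positions, select(system, "all"),
                         select(system, "all"), FAB_CRITERIA)
    assert recs == []


def test_printed_gly_gly_criterion_is_tighter():
    # at 0.3 nm D–A the 0.22 nm printed cutoff excludes the pair; the
    # hydrogen–acceptor reinterpretation (H–A = 0.2 nm) admits it
    system = _three_atom_system(0.3)
    sel = select(system, "all")
    assert detect_hbonds(system, system.positions, sel, sel,
                         GLY_GLY_CRITERIA) == []
    reinterpreted = HBondCriteria(0.22, DIST_HYDROGEN_ACCEPTOR, 30.0, ANGLE_HDA)
    assert len(detect_hbonds(system, system.positions, sel, sel,
                             reinterpreted)) == 1


def test_donor_without_hydrogen_warns():
    system = _three_atom_system(0.3)
    system.h_parent[1] = -1
    system._assign_donors_acceptors()
    with pytest.warns(UserWarning, match="without bonded hydrogens"):
        recs = detect_hbonds(system, system.positions, select(system, "all"),
                             select(system, "all"), FAB_CRITERIA)
    assert recs == []


@pytest.mark.parametrize("dist_def", [DIST_DONOR_ACCEPTOR, DIST_HYDROGEN_ACCEPTOR])
@pytest.mark.parametrize("angle_def", [ANGLE_HDA, ANGLE_DHA_LINEARITY])
def test_oracle_equivalence_random_systems(dist_def, angle_def):
    criteria = HBondCriteria(0.35, dist_def, 30.0, angle_def)
    for seed in range(8):
        system = random_water_box(50, 2.0, seed)
        got = {
            (r.donor_atom_id, r.hydrogen_atom_id, r.acceptor_atom_id)
            for r in detect_hbonds(system, system.positions,
                                   select(system, "all"), select(system, "all"),
                                   criteria, exclude_same_molecule=True)
        }
        assert got == brute_force_hbonds(system, system.positions, criteria,
                                         exclude_same_molecule=True)


def test_rigid_transform_and_wrap_invariance(rng):
    system = random_water_box(40, 2.0, 99)
    sel = select(system, "all")

    def keyset(coords):
        return {
            (r.donor_atom_id, r.hydrogen_atom_id, r.acceptor_atom_id)
            for r in detect_hbonds(system, coords, sel, sel, FAB_CRITERIA,
                                   exclude_same_molecule=True)
        }

    base = keyset(system.positions)
    # arbitrary translation (exercises periodic wrapping too)
    assert keyset(system.positions + np.array([5.3, -7.1, 0.9])) == base
    theta = 0.7
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0],
        [np.sin(theta), np.cos(theta), 0],
        [0, 0, 1],
    ])
    assert keyset(system.positions @ rot.T) == base


def test_count_by_class_constructed_frame():
    # one glycine donating to protein O, three waters donating to protein O
    pos, names, elements, resids, resnames, chains = [], [], [], [], [], []
    mol_index, mol_species, h_parent = [], [], []

    def add(mol_atoms, species, resname, chain):
        mol = len(mol_species)
        mol_species.append(species)
        for name, elem, xyz, hp in mol_atoms:
            h_parent.append(len(names) + hp if hp is not None else -1)
            names.append(name)
            elements.append(elem)
            resids.append(mol + 1)
            resnames.append(resname)
            chains.append(chain)
            mol_index.append(mol)
            pos.append(xyz)

    # protein: 4 acceptor oxygens far apart
    add([("O", "O", [2.0 * k, 0, 0], None) for k in range(4)],
        "protein", "ALA", "A")
    add([("N", "N", [0.0, 0.3, 0], None), ("H1", "H", [0.0, 0.2, 0], -1)],
        "glycine", "GLY", "G")
    for k in range(3):
        x = 2.0 * (k + 1)
        add([("O", "O", [x, 0.3, 0], None), ("H1", "H", [x, 0.2, 0], -1),
             ("H2", "H", [x, 0.4, 0], -1)], "water", "HOH", "W")
    system = MolecularSystem(
        names=names, elements=elements, residue_ids=resids,
        residue_names=resnames, chain_ids=chains, positions=pos,
        molecule_index=mol_index, molecule_species=mol_species,
        h_parent=h_parent,
    )
    recs = detect_hbonds(system, system.positions, select(system, "all"),
                         select(system, "all"), FAB_CRITERIA,
                         exclude_same_molecule=True)
    table = count_hbonds_by_class(
        recs, ["protein-water", "protein-glycine"], [0])
    assert table.loc[0, "protein-water"] == 3
    assert table.loc[0, "protein-glycine"] == 1
    with pytest.raises(ValueError):
        count_hbonds_by_class(recs, ["protein-unobtainium"], [0])


def test_two_replica_sem():
    a = pd.DataFrame({"protein-water": [4, 4]}, index=[0, 1])
    b = pd.DataFrame({"protein-water": [6, 6]}, index=[0, 1])
    out = summarize_counts([a, b])
    assert out.loc["protein-water", "mean"] == 5
    assert out.loc["protein-water", "sem"] == pytest.approx(1.0)


def test_zero_records_zero_counts():
    table = count_hbonds_by_class([], ["protein-water"], [0, 1])
    assert (table == 0).all().all()


# -- clustering ---------------------------------------------------------------

def _gly_chain_system(n, bonded_pairs):
    """n glycine molecules (N,H,O each); listed pairs are H-bonded."""
    names, elements, resids, resnames, chains = [], [], [], [], []
    pos, mol_index, mol_species, h_parent = [], [], [], []
    for j in range(n):
        base = len(names)
        x = 10.0 * j
        names += ["N", "H1", "O"]
        elements += ["N", "H", "O"]
        resids += [j + 1] * 3
        resnames += ["GLY"] * 3
        chains += ["G"] * 3
        mol_index += [j] * 3
        mol_species.append("glycine")
        pos += [[x, 0, 0], [x + 0.1, 0, 0], [x, 1.0, 0]]
        h_parent += [-1, base, -1]
    system = MolecularSystem(
        names=names, elements=elements, residue_ids=resids,
        residue_names=resnames, chain_ids=chains, positions=pos,
        molecule_index=mol_index, molecule_species=mol_species,
        h_parent=h_parent,
    )
    # place acceptor O of molecule b collinearly beyond donor H of molecule a
    coords = system.positions.copy()
    for a, b in bonded_pairs:
        coords[3 * b + 2] = coords[3 * a] + np.array([0.3, 0, 0])
    return system, coords


def test_no_bonds_all_monomers():
    system, coords = _gly_chain_system(10, [])
    recs = detect_hbonds(system, coords, select(system, "all"),
                         select(system, "all"), FAB_CRITERIA,
                         exclude_same_molecule=True)
    frac = classify_clusters(recs, 10, system, [0])
    assert np.allclose(frac.mean, [1.0, 0.0, 0.0])


def test_single_pair_all_dimer():
    system, coords = _gly_chain_system(2, [(0, 1)])
    recs = detect_hbonds(system, coords, select(system, "all"),
                         select(system, "all"), FAB_CRITERIA,
                         exclude_same_molecule=True)
    frac = classify_clusters(recs, 2, system, [0])
    assert np.allclose(frac.mean, [0.0, 1.0, 0.0])


def test_linear_chain_fractions():
    """A–B–C: terminal molecules have one bond (dimer class), the middle one
    has two (Nmer class)."""
    system, coords = _gly_chain_system(3, [(0, 1), (1, 2)])
    recs = detect_hbonds(system, coords, select(system, "all"),
                         select(system, "all"), FAB_CRITERIA,
                         exclude_same_molecule=True)
    frac = classify_clusters(recs, 3, system, [0])
    assert np.allclose(frac.mean, [0.0, 2 / 3, 1 / 3])
    assert frac.per_frame.sum(axis=1) == pytest.approx(1.0)


def test_cluster_fractions_always_sum_to_one(rng):
    system = random_water_box(30, 1.5, 5)
    recs = detect_hbonds(system, system.positions, select(system, "all"),
                         select(system, "all"), FAB_CRITERIA,
                         exclude_same_molecule=True)
    frac = classify_clusters(recs, 30, system, [0], species="water")
    assert frac.per_frame.sum(axis=1) == pytest.approx(1.0, abs=1e-9)


def test_cluster_requires_molecules():
    system, _ = _gly_chain_system(2, [])
    with pytest.raises(ValueError):
        classify_clusters([], 0, system, [0])


# -- occupancy ----------------------------------------------------------------

def test_occupancy_counts_formed_frames():
    system = _three_atom_system(0.3)
    formed = system.positions.copy()
    broken = formed.copy()
    broken[2, 0] = 0.6
    frames = np.stack([formed] * 30 + [broken] * 70)
    ens = ConformationEnsemble(system=system, frames=frames,
                               times=np.arange(100.0))
    occ = hbond_occupancy(ens, [(1, 3)])
    assert occ.occupancy.iloc[0] == pytest.approx(0.30)
    sites = site_occupancy(ens, {"hotspot": [(1, 3)]})
    assert sites["hotspot"] == pytest.approx(0.30)


def test_occupancy_validates_ids_and_empty():
    system = _three_atom_system(0.3)
    ens = ConformationEnsemble(system=system,
                               frames=system.positions[None],
                               times=np.array([0.0]))
    assert hbond_occupancy(ens, []).empty
    with pytest.raises(ValueError):
        hbond_occupancy(ens, [(1, 99)])
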