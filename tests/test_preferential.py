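"""RDFs, Γ23, hydration shells, displacement and contact maps."""
import numpy as np
import pytest

from fabsolv.model import ConformationEnsemble, MolecularSystem
from fabsolv.preferential import (
    compute_rdf,
    contact_frequency,
    displacement_percent,
    gamma23,
    proximal_distances,
    reference_sites,
    shell_occupancy,
)
from fabsolv.synth import (
    SolvationSpec,
    build_toy_protein,
    solvate,
    solvate_ensemble,
)


def _static_ensemble(system, n_frames=1):
    return ConformationEnsemble(
        system=system,
        frames=np.repeat(system.positions[None], n_frames, axis=0),
        times=np.arange(float(n_frames)),
    )


def _protein_plus_waters_at(distances, box=6.0, n_res=4):
    """Single-oxygen waters placed at exact proximal distances along +x from
    the protein's most x-positive heavy atom."""
    protein = build_toy_protein(n_res)
    shifted = protein.positions - protein.positions.mean(axis=0) + box / 2
    heavy = np.flatnonzero(protein.elements != "H")
    anchor = heavy[np.argmax(shifted[heavy, 0])]

    names = [str(n) for n in protein.names]
    elements = [str(e) for e in protein.elements]
    resids = list(protein.residue_ids)
    resnames = [str(r) for r in protein.residue_names]
    chains = [str(c) for c in protein.chain_ids]
    pos = [shifted]
    h_parent = list(protein.h_parent)
    mol_index = list(protein.molecule_index)
    mol_species = ["protein"]
    for j, d in enumerate(distances):
        mol_species.append("water")
        names.append("O")
        elements.append("O")
        resids.append(j + 1)
        resnames.append("HOH")
        chains.append("W")
        pos.append(shifted[anchor] + np.array([[d, 0.0, 0.0]]))
        h_parent.append(-1)
        mol_index.append(len(mol_species) - 1)
    return MolecularSystem(
        names=names, elements=elements, residue_ids=resids,
        residue_names=resnames, chain_ids=chains, positions=np.vstack(pos),
        molecule_index=mol_index, molecule_species=mol_species,
        h_parent=h_parent, box_edge=box, periodic=True,
    )


def test_reference_sites_water_oxygen_and_centroid():
    system = solvate(
        build_toy_protein(4),
        SolvationSpec(box_edge=4.0, n_water=5,
                      n_excipient={"glycine": 3}, seed=2),
    )
    wsites = reference_sites(system, system.positions, "water")
    mols = system.molecules_of_species("water")
    oxy = [system.molecule_atoms(int(m))[0] for m in mols]
    assert np.allclose(wsites, system.positions[oxy])
    gsites = reference_sites(system, system.positions, "glycine")
    for k, m in enumerate(system.molecules_of_species("glycine")):
        idx = system.molecule_atoms(int(m))
        heavy = idx[system.elements[idx] != "H"]
        assert np.allclose(gsites[k], system.positions[heavy].mean(axis=0))


def test_rdf_uniform_system_is_flat():
    protein = build_toy_protein(4)
    ens = solvate_ensemble(
        protein, SolvationSpec(box_edge=5.0, n_water=600, seed=9), 30,
    )
    rdf = compute_rdf(ens, "water", bin_width=0.1, r_max=2.0)
    # beyond the exclusion zone g should fluctuate around 1
    far = rdf.bin_centers > 0.6
    assert np.abs(rdf.g_values[far].mean() - 1.0) < 0.05


def test_rdf_single_occupied_bin():
    system = _protein_plus_waters_at([0.5] * 8)
    rdf = compute_rdf(_static_ensemble(system), "water",
                      bin_width=0.1, r_max=1.5, n_mc=50_000)
    occupied = np.flatnonzero(rdf.counts > 0)
    assert len(occupied) == 1
    assert rdf.bin_edges[occupied[0]] <= 0.5 < rdf.bin_edges[occupied[0] + 1]


def test_rdf_rejects_r_max_beyond_half_box():
    system = _protein_plus_waters_at([0.5])
    with pytest.raises(ValueError, match="half box"):
        compute_rdf(_static_ensemble(system), "water", r_max=4.0)


# -- Γ23 ----------------------------------------------------------------------

def test_gamma_zero_for_matched_distributions():
    protein = build_toy_protein(8)
    ens = solvate_ensemble(
        protein,
        SolvationSpec(box_edge=5.0, n_water=500,
                      n_excipient={"glycine": 60}, seed=21),
        60,
    )
    g = gamma23(ens, "glycine", "water")
    assert abs(g.gamma23) < 3 * g.sem + 1e-9


def test_gamma_matches_generator_bookkeeping():
    protein = build_toy_protein(8)
    ens = solvate_ensemble(
        protein,
        SolvationSpec(box_edge=5.0, n_water=500,
                      n_excipient={"glycine": 60},
                      excess_local={"glycine": 10}, seed=22),
        60,
    )
    g = gamma23(ens, "glycine", "water")
    truth = ens.provenance["gamma_truth"]["glycine"]
    assert abs(g.gamma23 - truth) < 3 * g.sem
    # dual-route agreement: counting vs RDF-integral
    assert abs(g.gamma23 - g.gamma23_integral) < max(0.02 * abs(g.gamma23), 0.5)
    assert g.mean == pytest.approx(np.mean(g.per_frame))


def test_gamma_no_excipient_is_zero(toy_protein):
    ens = solvate_ensemble(
        toy_protein, SolvationSpec(box_edge=5.5, n_water=100, seed=1), 3,
    )
    g = gamma23(ens, "glycine", "water")
    assert g.gamma23 == 0.0


def test_gamma_invariant_under_rigid_motion_and_relabeling():
    protein = build_toy_protein(6)
    ens = solvate_ensemble(
        protein,
        SolvationSpec(box_edge=4.5, n_water=250,
                      n_excipient={"glycine": 30},
                      excess_local={"glycine": 5}, seed=30),
        12,
    )
    g0 = gamma23(ens, "glycine", "water").gamma23
    moved = ConformationEnsemble(
        system=ens.system,
        frames=ens.frames + np.array([3.1, -1.7, 0.4]),
        times=ens.times,
    )
    assert gamma23(moved, "glycine", "water").gamma23 == pytest.approx(
        g0, abs=1e-9)


def test_gamma_monotone_in_local_excipient():
    """Adding excipient only inside the local domain never decreases Γ23."""
    protein = build_toy_protein(8)
    gammas = []
    for excess in (0, 5, 10):
        ens = solvate_ensemble(
            protein,
            SolvationSpec(box_edge=5.0, n_water=400,
                          n_excipient={"glycine": 40},
                          excess_local={"glycine": excess}, seed=33),
            20,
        )
        gammas.append(gamma23(ens, "glycine", "water").gamma23)
    assert gammas[0] < gammas[1] < gammas[2]


# -- shells and displacement --------------------------------------------------

def test_shell_occupancy_constructed_counts():
    system = _protein_plus_waters_at([0.30] * 5 + [0.50] * 7 + [0.80] * 3)
    occ = shell_occupancy(_static_ensemble(system), "water",
                          window_fraction=1.0)
    assert occ.mean_first == 5
    assert occ.mean_second == 7


def test_shell_boundary_is_half_open():
    system = _protein_plus_waters_at([0.35])
    occ = shell_occupancy(_static_ensemble(system), "water",
                          window_fraction=1.0)
    assert (occ.mean_first, occ.mean_second) == (0, 1)


def test_shells_partition_local_domain():
    protein = build_toy_protein(6)
    ens = solvate_ensemble(
        protein,
        SolvationSpec(box_edge=4.5, n_water=300,
                      n_excipient={"glycine": 30},
                      excess_local={"glycine": 8}, seed=13),
        10,
    )
    occ = shell_occupancy(ens, "water", window_fraction=1.0)
    for i, f in enumerate(ens.window(1.0)):
        coords = ens.frames[f]
        d = proximal_distances(
            ens.system, coords, reference_sites(ens.system, coords, "water"))
        assert occ.per_frame_first[i] + occ.per_frame_second[i] == \
            np.sum(d < 0.6)


def test_displacement_reproduces_published_shell_numbers():
    """First/second-shell displacement on initial excipient binding in the
    bundled Fab hydration table: 52 % and 73 % (rounded)."""
    from fabsolv.datasets import fab_hydration_table
    t = fab_hydration_table()
    first = displacement_percent(
        t.loc[0, "first_shell_water"], t.loc[10, "first_shell_water"])
    second = displacement_percent(
        t.loc[0, "second_shell_water"], t.loc[10, "second_shell_water"])
    assert first.percent_rounded == 52
    assert second.percent_rounded == 73
    assert first.percent == pytest.approx(100 * (3007 - 1450) / 3007)


def test_displacement_edge_cases():
    assert displacement_percent(100, 100).percent == 0
    with pytest.raises(ValueError):
        displacement_percent(0, 10)


# -- contact maps -------------------------------------------------------------

def test_contact_frequency_localised_to_one_residue():
    protein = build_toy_protein(10)
    box = 6.0
    shifted = protein.positions - protein.positions.mean(axis=0) + box / 2
    res7 = np.flatnonzero((protein.residue_ids == 7)
                          & (protein.elements != "H"))
    site = shifted[res7].mean(axis=0)
    direction = site - shifted.mean(axis=0)
    site = site + 0.45 * direction / np.linalg.norm(direction)

    names = [str(n) for n in protein.names] + ["C1"]
    elements = [str(e) for e in protein.elements] + ["C"]
    resids = list(protein.residue_ids) + [1]
    resnames = [str(r) for r in protein.residue_names] + ["CIT"]
    chains = [str(c) for c in protein.chain_ids] + ["X"]
    system = MolecularSystem(
        names=names, elements=elements, residue_ids=resids,
        residue_names=resnames, chain_ids=chains,
        positions=np.vstack([shifted, site[None]]),
        molecule_index=list(protein.molecule_index) + [1],
        molecule_species=["protein", "citrate"],
        h_parent=list(protein.h_parent) + [-1],
        box_edge=box, periodic=True,
    )
    formed = system.positions.copy()
    away = formed.copy()
    away[-1] += np.array([2.0, 0, 0])
    frames = np.stack([formed] * 30 + [away] * 70)
    ens = ConformationEnsemble(system=system, frames=frames,
                               times=np.arange(100.0))
    cmap = contact_frequency(ens, "citrate", window_fraction=1.0)
    freqs = cmap.frequencies["frequency"]
    assert freqs.loc[("A", 7)] == pytest.approx(0.30)
    touched = freqs[freqs > 0]
    assert freqs.loc[("A", 7)] == touched.max()
    assert (freqs[~freqs.index.isin(touched.index)] == 0).all()
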