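"""Superposition, RMSD/RMSF/ΔRMSF, Rg, SASA and Cα PCA."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fabsolv.conformation import (
    average_profiles,
    classify_exposure,
    delta_rmsf,
    delta_rmsf_by_group,
    pca_calpha,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    sasa,
    superpose,
)
from fabsolv.model import ConformationEnsemble, MolecularSystem, Selection
from fabsolv.selection import select
from fabsolv.synth import (
    FluctuationSpec,
    build_toy_protein,
    fluctuate,
    orthogonalize_mode,
)

from oracles import analytic_pair_sasa, brute_force_rmsf, quaternion_superpose


def _static_ensemble(system, n_frames=5):
    return ConformationEnsemble(
        system=system,
        frames=np.repeat(system.positions[None], n_frames, axis=0),
        times=np.arange(float(n_frames)),
    )


# -- superposition ------------------------------------------------------------

def test_superpose_identity(toy_protein):
    res = superpose(toy_protein.positions, toy_protein.positions)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_superpose_removes_rigid_motion(toy_protein, rng):
    theta = 1.1
    rot = np.array([
        [np.cos(theta), 0, np.sin(theta)],
        [0, 1, 0],
        [-np.sin(theta), 0, np.cos(theta)],
    ])
    moved = toy_protein.positions @ rot.T + np.array([1.0, -2.0, 0.5])
    res = superpose(moved, toy_protein.positions)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.apply(moved), toy_protein.positions, atol=1e-9)


def test_superpose_matches_quaternion_oracle(toy_protein, rng):
    ref = toy_protein.positions
    mobile = ref + rng.normal(0, 0.05, size=ref.shape)
    res = superpose(mobile, ref)
    rot_oracle, rmsd_oracle = quaternion_superpose(mobile, ref)
    assert np.allclose(res.rotation, rot_oracle, atol=1e-8)
    assert res.rmsd == pytest.approx(rmsd_oracle, abs=1e-10)


def test_superpose_rejects_collinear():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="collinear|degenerate"):
        superpose(line, line + 0.1)


# -- RMSD / RMSF --------------------------------------------------------------

def test_rmsd_series_static_is_zero(toy_protein):
    sel = select(toy_protein, "backbone")
    series = rmsd_series(_static_ensemble(toy_protein),
                         toy_protein.positions, sel)
    assert np.allclose(series.rmsd_nm, 0.0, atol=1e-12)


def test_rmsd_series_recovers_sigma_sqrt3():
    protein = build_toy_protein(60)
    sigma = 0.03
    ens = fluctuate(protein, FluctuationSpec(
        sigma_per_residue=np.full(60, sigma), n_frames=2000, seed=8))
    series = rmsd_series(ens, protein.positions, select(protein, "backbone"))
    assert series.rmsd_nm.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)


def test_rmsf_static_zero(toy_protein):
    prof = rmsf(_static_ensemble(toy_protein), select(toy_protein, "protein"),
                window_fraction=1.0)
    assert np.allclose(prof.rmsf, 0.0, atol=1e-12)


def test_rmsf_recovers_linear_sigma_profile():
    """A linear per-residue σ ramp is recovered as a proportional RMSF
    profile.  Chain ends are trimmed: rigid-body superposition absorbs
    disproportionate rotational variance at the largest lever arms."""
    n = 60
    protein = build_toy_protein(n)
    sigma = 0.04 + 0.0004 * np.arange(1, n + 1)
    ens = fluctuate(protein, FluctuationSpec(
        sigma_per_residue=sigma, n_frames=1500, seed=12))
    prof = rmsf(ens, select(protein, "protein"), window_fraction=1.0)
    ratio = prof.rmsf / (sigma * np.sqrt(3))
    assert np.abs(ratio[6:-6] - 1.0).max() < 0.05


def test_rmsf_equals_brute_force_on_aligned_toy(toy_protein):
    """When frames need no alignment, the per-atom RMSF equals the direct
    formula evaluation."""
    rng = np.random.default_rng(5)
    frames = toy_protein.positions + rng.normal(
        0, 1e-4, size=(10, toy_protein.n_atoms, 3))
    ens = ConformationEnsemble(system=toy_protein, frames=frames,
                               times=np.arange(10.0))
    prof = rmsf(ens, select(toy_protein, "protein"), window_fraction=1.0)
    oracle = brute_force_rmsf(frames)
    expected = []
    for rid in prof.residue_ids:
        idx = np.flatnonzero(toy_protein.residue_ids == rid)
        expected.append(np.average(oracle[idx],
                                   weights=toy_protein.masses[idx]))
    # superposition perturbs the direct formula at the percent level only
    assert np.allclose(prof.rmsf, expected, rtol=0.05)


def test_rmsf_requires_two_frames(toy_protein):
    with pytest.raises(ValueError):
        rmsf(_static_ensemble(toy_protein, n_frames=1),
             select(toy_protein, "protein"), window_fraction=1.0)


# -- ΔRMSF --------------------------------------------------------------------

def _profile(values):
    from fabsolv.conformation import FlexibilityProfile
    values = np.asarray(values, dtype=float)
    return FlexibilityProfile(residue_ids=np.arange(1, len(values) + 1),
                              rmsf=values)


def test_delta_rmsf_identity_doubling_and_scaling():
    ref = _profile([0.1, 0.2, 0.3])
    assert delta_rmsf(ref, ref).global_percent == pytest.approx(0.0)
    assert delta_rmsf(_profile([0.2, 0.4, 0.6]), ref).global_percent == \
        pytest.approx(100.0)
    d = delta_rmsf(_profile(np.array([0.1, 0.2, 0.3]) * 0.85), ref)
    assert d.global_percent == pytest.approx(-15.0)
    assert np.allclose(d.per_residue_percent, -15.0)


def test_delta_rmsf_zero_reference_flagged():
    ref = _profile([0.0, 0.2])
    with pytest.warns(UserWarning, match="zero reference"):
        d = delta_rmsf(_profile([0.1, 0.4]), ref)
    assert np.isnan(d.per_residue_percent[0])
    assert d.global_percent == pytest.approx(100.0)


def test_delta_rmsf_group_breakdown(toy_protein):
    ref = _profile(np.full(20, 0.1))
    cur = _profile(np.concatenate([np.full(10, 0.12), np.full(10, 0.09)]))
    groups = {"front": np.arange(20) < 10, "back": np.arange(20) >= 10}
    out = delta_rmsf_by_group(cur, ref, groups)
    assert out["front"] == pytest.approx(20.0)
    assert out["back"] == pytest.approx(-10.0)


def test_average_profiles_sem():
    avg = average_profiles([_profile([0.1, 0.2]), _profile([0.3, 0.4])])
    assert np.allclose(avg.rmsf, [0.2, 0.3])
    assert np.allclose(avg.sem, [0.1, 0.1])


# -- radius of gyration -------------------------------------------------------

def test_rg_two_point_symmetry():
    coords = np.array([[0, 0, 0], [0.4, 0, 0]])
    assert radius_of_gyration(coords) == pytest.approx(0.2)


def test_rg_single_atom_and_oracle(toy_protein):
    assert radius_of_gyration(np.zeros((1, 3))) == 0.0
    coords = toy_protein.positions
    masses = toy_protein.masses
    com = np.average(coords, axis=0, weights=masses)
    brute = np.sqrt(
        np.sum(masses * np.sum((coords - com) ** 2, axis=1)) / masses.sum())
    assert radius_of_gyration(coords, masses) == pytest.approx(brute)


# -- SASA ---------------------------------------------------------------------

def _sphere_system(positions, radii):
    n = len(positions)
    return MolecularSystem(
        names=["O"] * n, elements=["O"] * n,
        residue_ids=list(range(1, n + 1)), residue_names=["HOH"] * n,
        chain_ids=["W"] * n, positions=positions,
        molecule_index=list(range(n)), molecule_species=["water"] * n,
        vdw_radii=radii,
    )


def test_sasa_lone_sphere_closed_form():
    system = _sphere_system(np.zeros((1, 3)), [0.15])
    res = sasa(system, system.positions)
    assert res.total == pytest.approx(4 * np.pi * 0.29 ** 2, rel=5e-3)


def test_sasa_disjoint_pair_adds_up():
    system = _sphere_system(np.array([[0.0, 0, 0], [2.0, 0, 0]]), [0.15, 0.12])
    res = sasa(system, system.positions)
    lone = 4 * np.pi * (np.array([0.15, 0.12]) + 0.14) ** 2
    assert np.allclose(res.per_atom, lone, rtol=1e-12)


def test_sasa_overlapping_pair_matches_cap_formula():
    for d in (0.20, 0.30, 0.45):
        system = _sphere_system(np.array([[0.0, 0, 0], [d, 0, 0]]),
                                [0.15, 0.16])
        res = sasa(system, system.positions)
        assert res.total == pytest.approx(
            analytic_pair_sasa(0.15, 0.16, d, 0.14), rel=0.02)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(min_value=0.15, max_value=0.55))
def test_sasa_monotone_as_atoms_approach(d):
    near = _sphere_system(np.array([[0.0, 0, 0], [d, 0, 0]]), [0.15, 0.15])
    far = _sphere_system(np.array([[0.0, 0, 0], [d + 0.03, 0, 0]]),
                         [0.15, 0.15])
    assert sasa(near, near.positions).total <= \
        sasa(far, far.positions).total + 1e-9


def test_exposure_split_tracks_surface_enriched_noise():
    """Buried residues get lower σ in the fixture, hence lower RMSF."""
    protein = build_toy_protein(24)
    exposed = classify_exposure(protein, protein.positions,
                                threshold=0.55, n_points=240)
    labels = np.array([exposed.get(int(r), True)
                       for r in np.unique(protein.residue_ids)])
    assert 0 < labels.sum() < len(labels)
    sigma = np.where(labels, 0.06, 0.02)
    ens = fluctuate(protein, FluctuationSpec(
        sigma_per_residue=sigma, n_frames=400, seed=6))
    prof = rmsf(ens, select(protein, "protein"), window_fraction=1.0)
    assert prof.rmsf[labels].mean() > prof.rmsf[~labels].mean()


# -- PCA ----------------------------------------------------------------------

def test_pca_static_all_zero(toy_protein):
    res = pca_calpha([_static_ensemble(toy_protein)])
    assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)


def test_pca_recovers_planted_mode_and_trace_identity():
    n = 30
    protein = build_toy_protein(n)
    ca = protein.positions[select(protein, "calpha").indices]
    rng = np.random.default_rng(4)
    mode = orthogonalize_mode(rng.normal(size=(n, 3)), ca)
    sigma_iso, var_mode = 0.01, 3e-4
    ens = fluctuate(protein, FluctuationSpec(
        sigma_per_residue=np.full(n, sigma_iso), n_frames=5000, seed=9,
        mode_shape=mode, mode_sigma=np.sqrt(var_mode)))
    res = pca_calpha([ens])
    expected_top = var_mode + sigma_iso ** 2
    assert res.eigenvalues[0] == pytest.approx(expected_top, rel=0.10)
    assert res.eigenvalues.sum() == pytest.approx(res.total_variance,
                                                  abs=1e-9)
    assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
    assert res.variance_fractions[0] == pytest.approx(
        expected_top / res.total_variance, rel=0.10)


def test_pca_concatenates_replicas_and_checks_topology(toy_protein):
    a = fluctuate(toy_protein, FluctuationSpec(
        sigma_per_residue=np.full(20, 0.02), n_frames=50, seed=1))
    b = fluctuate(toy_protein, FluctuationSpec(
        sigma_per_residue=np.full(20, 0.02), n_frames=50, seed=2))
    res = pca_calpha([a, b])
    assert res.projections.shape[0] == 100
    other = build_toy_protein(5)
    c = fluctuate(other, FluctuationSpec(
        sigma_per_residue=np.full(5, 0.02), n_frames=10, seed=3))
    with pytest.raises(ValueError):
        pca_calpha([a, c])
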