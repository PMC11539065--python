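"""Independent brute-force oracles used only by the test suite."""
from __future__ import annotations

import numpy as np

from fabsolv.hbonds import HBondCriteria, _angle_deg
from fabsolv.model import MolecularSystem, minimum_image


def brute_force_hbonds(
    system: MolecularSystem,
    coords: np.ndarray,
    criteria: HBondCriteria,
    exclude_same_molecule: bool,
) -> set[tuple[int, int, int]]:
    """O(N²) all-pairs hydrogen-bond evaluation; returns 1-based
    (donor, hydrogen, acceptor) id triples."""
    box = system.box_edge if system.periodic else None
    out: set[tuple[int, int, int]] = set()
    for d in range(system.n_atoms):
        if not system.is_donor_heavy[d]:
            continue
        for h in system.bonded_hydrogens_of(d):
            for a in range(system.n_atoms):
                if not system.is_acceptor[a] or a == d:
                    continue
                if (exclude_same_molecule
                        and system.molecule_index[a] == system.molecule_index[d]):
                    continue
                da = minimum_image(coords[a] - coords[d], box)
                dh = minimum_image(coords[h] - coords[d], box)
                ha = minimum_image(coords[a] - coords[h], box)
                if criteria.distance_definition == "donor-acceptor":
                    dist = np.linalg.norm(da)
                else:
                    dist = np.linalg.norm(ha)
                if dist > criteria.distance_cutoff:
                    continue
                if criteria.angle_definition == "hda":
                    ang = _angle_deg(dh, da)
                else:
                    ang = 180.0 - _angle_deg(-dh, ha)
                if ang <= criteria.angle_cutoff:
                    out.add((d + 1, int(h) + 1, a + 1))
    return out


def quaternion_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Horn's quaternion method for the optimal proper rotation; independent
    of the Kabsch SVD implementation under test."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    evals, evecs = np.linalg.eigh(K)
    q = evecs[:, -1]
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    rot = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((rot - Q) ** 2, axis=1))))
    return R, rmsd


def analytic_pair_sasa(r1: float, r2: float, d: float, probe: float) -> float:
    """Closed-form accessible area of two spheres via spherical caps."""
    R1, R2 = r1 + probe, r2 + probe
    a1, a2 = 4 * np.pi * R1 ** 2, 4 * np.pi * R2 ** 2
    if d >= R1 + R2:
        return a1 + a2
    h1 = R1 - (d ** 2 + R1 ** 2 - R2 ** 2) / (2 * d)
    h2 = R2 - (d ** 2 + R2 ** 2 - R1 ** 2) / (2 * d)
    return a1 - 2 * np.pi * R1 * h1 + a2 - 2 * np.pi * R2 * h2


def brute_force_rmsf(coords: np.ndarray) -> np.ndarray:
    """Direct per-atom RMSF formula on pre-aligned coordinates."""
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def random_water_box(
    n_molecules: int, box_edge: float, seed: int, periodic: bool = True
) -> MolecularSystem:
    """Random (possibly overlapping) rigid waters: a stress fixture for the
    hydrogen-bond oracle comparisons."""
    from fabsolv.synth import _random_rotation, _water_template

    rng = np.random.default_rng(seed)
    t_names, t_elements, t_coords, t_hp, resname = _water_template()
    names, elements, resids, resnames, chains = [], [], [], [], []
    pos, h_parent, mol_index, mol_species = [], [], [], []
    for j in range(n_molecules):
        site = rng.random(3) * box_edge
        coords = site + t_coords @ _random_rotation(rng).T
        base = len(names)
        mol = len(mol_species)
        mol_species.append("water")
        names.extend(t_names)
        elements.extend(t_elements)
        resids.extend([j + 1] * 3)
        resnames.extend([resname] * 3)
        chains.extend(["W"] * 3)
        pos.append(coords)
        h_parent.extend([p + base if p >= 0 else -1 for p in t_hp])
        mol_index.extend([mol] * 3)
    return MolecularSystem(
        names=names, elements=elements, residue_ids=resids,
        residue_names=resnames, chain_ids=chains, positions=np.vstack(pos),
        molecule_index=mol_index, molecule_species=mol_species,
        h_parent=h_parent, box_edge=box_edge, periodic=periodic,
    )
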