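"""Synthetic systems with known ground truth.

Everything the analysis layer consumes can be generated here: a rigid toy
protein in a solvated box with controlled near-surface excipient enrichment
(ground truth for the preferential interaction coefficient), Gaussian
fluctuation ensembles with prescribed per-residue amplitudes (ground truth for
RMSF/ΔRMSF and PCA), two-state melting curves, and first-order monomer-decay
series.  All generators are deterministic under their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    ConformationEnsemble,
    MolecularSystem,
    PackingError,
)
from .melt import FluorescenceMeltSeries
from .kinetics import MonomerLossSeries

R_GAS_KJ = 8.314e-3  # kJ/(mol K)

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class SolvationSpec:
    """Box composition with controlled local-domain excipient enrichment.

    ``excess_local`` adds (positive) or removes (negative) that many molecules
    of each excipient species from the local domain — the region within
    ``local_cutoff`` of any protein heavy atom — relative to the
    bulk-proportional expectation estimated from the water placement.  With
    matched distributions (``excess_local = 0``) the preferential interaction
    coefficient is zero by construction.
    """

    box_edge: float                       # nm
    n_water: int
    n_excipient: Mapping[str, int] = field(default_factory=dict)
    excess_local: Mapping[str, int] = field(default_factory=dict)
    local_cutoff: float = 0.6             # nm
    min_separation: float = 0.25          # nm, between placed sites
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if self.n_water < 0 or any(v < 0 for v in self.n_excipient.values()):
            raise ValueError("particle counts must be non-negative")
        for sp, ex in self.excess_local.items():
            if abs(ex) > self.n_excipient.get(sp, 0):
                raise ValueError(f"|excess_local| exceeds n_excipient for {sp!r}")


@dataclass
class FluctuationSpec:
    """Per-residue isotropic Gaussian fluctuations, optionally with one
    collective mode (per-residue shape × Gaussian amplitude) planted on top —
    the ground truth for the PCA eigenvalue recovery checks."""

    sigma_per_residue: np.ndarray         # nm
    n_frames: int
    frame_stride: float = 10.0            # ps
    seed: int = 0
    mode_shape: np.ndarray | None = None  # (n_residues, 3), unit flattened norm
    mode_sigma: float = 0.0               # nm

    def __post_init__(self) -> None:
        self.sigma_per_residue = np.asarray(self.sigma_per_residue, dtype=float)
        if np.any(self.sigma_per_residue < 0):
            raise ValueError("sigmas must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


@dataclass
class MeltSimSpec:
    Tm_true: float                        # K
    dHvh_true: float                      # kJ/mol
    native_bcm: float = 345.0             # nm
    denatured_bcm: float = 355.0          # nm
    baseline_slopes: tuple[float, float] = (0.0, 0.0)   # nm/K
    noise_sigma: float = 0.0              # nm
    T_grid: np.ndarray = None             # K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dHvh_true <= 0:
            raise ValueError("dHvh_true must be positive")
        if self.T_grid is None:
            self.T_grid = np.arange(293.15, 364.15, 1.0)
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        if not np.all(np.diff(self.T_grid) > 0):
            raise ValueError("T_grid must be strictly increasing")
        if not (self.T_grid[0] < self.Tm_true < self.T_grid[-1]):
            raise ValueError("T_grid must bracket Tm_true")


@dataclass
class KineticsSimSpec:
    M0_true: float                        # %
    kobs_true: float                      # per day
    noise_sigma: float = 0.0              # %
    timepoints: np.ndarray = None         # days
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M0_true <= 0:
            raise ValueError("M0_true must be positive")
        if self.kobs_true < 0:
            raise ValueError("kobs_true must be non-negative")
        if self.timepoints is None:
            self.timepoints = np.linspace(0.0, 8.0, 9)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if np.any(self.timepoints < 0) or not np.all(np.diff(self.timepoints) > 0):
            raise ValueError("timepoints must be non-negative and increasing")


# ---------------------------------------------------------------------------
# toy protein
# ---------------------------------------------------------------------------

#: documented builder geometry (nm, degrees)
TOY_GEOMETRY = {
    "helix_rise_per_residue": 0.15,
    "helix_radius": 0.23,
    "helix_twist_deg": 100.0,
    "extended_step": 0.35,
    "n_to_h_bond": 0.10,
    "c_to_o_bond": 0.123,
    "ca_to_cb_bond": 0.153,
}

_RES_ATOM_NAMES = ("N", "H", "CA", "C", "O", "CB")
_RES_ELEMENTS = ("N", "H", "C", "C", "O", "C")


def build_toy_protein(n_residues: int, geometry: str = "helix") -> MolecularSystem:
    """Rigid toy polypeptide: backbone N, CA, C, O plus an amide hydrogen and
    one side-chain pseudo-atom (CB) per residue; alternating residues carry
    the VH / VL pseudo-domain labels so per-domain statistics are testable."""
    if n_residues < 2:
        raise ValueError("n_residues must be at least 2")
    if geometry not in ("helix", "extended"):
        raise ValueError(f"unknown geometry {geometry!r}")
    g = TOY_GEOMETRY
    positions = []
    for i in range(n_residues):
        if geometry == "helix":
            theta = np.deg2rad(g["helix_twist_deg"]) * i
            u = np.array([np.cos(theta), np.sin(theta), 0.0])
            t = np.array([-np.sin(theta), np.cos(theta), 0.0])
            k = np.array([0.0, 0.0, 1.0])
            ca = g["helix_radius"] * u + np.array([0, 0, g["helix_rise_per_residue"] * i])
        else:
            u = np.array([0.0, 1.0, 0.0])
            t = np.array([1.0, 0.0, 0.0])
            k = np.array([0.0, 0.0, 1.0])
            ca = np.array([g["extended_step"] * i, 0.05 * (-1) ** i, 0.0])
        n = ca - 0.08 * u - 0.11 * t + 0.04 * k
        h = n + g["n_to_h_bond"] * (n - ca) / np.linalg.norm(n - ca)
        c = ca + 0.09 * u + 0.11 * t - 0.05 * k
        o = c - g["c_to_o_bond"] * k
        cb = ca + g["ca_to_cb_bond"] * u
        positions.extend([n, h, ca, c, o, cb])
    positions = np.asarray(positions)

    names, elements, resids, resnames, chains, domains = [], [], [], [], [], []
    h_parent = np.full(6 * n_residues, -1, dtype=np.int64)
    for i in range(n_residues):
        base = 6 * i
        names.extend(_RES_ATOM_NAMES)
        elements.extend(_RES_ELEMENTS)
        resids.extend([i + 1] * 6)
        resnames.extend(["ALA"] * 6)
        chains.extend(["A"] * 6)
        domains.extend(["VH" if i % 2 == 0 else "VL"] * 6)
        h_parent[base + 1] = base  # amide H on N
    return MolecularSystem(
        names=names,
        elements=elements,
        residue_ids=resids,
        residue_names=resnames,
        chain_ids=chains,
        positions=positions,
        molecule_index=np.zeros(6 * n_residues, dtype=np.int64),
        molecule_species=["protein"],
        domain_labels=domains,
        h_parent=h_parent,
        provenance={"builder": "toy_protein", "geometry": geometry},
    )


# ---------------------------------------------------------------------------
# solvation
# ---------------------------------------------------------------------------

# rigid solvent/excipient fragments in local coordinates (nm), centred so the
# placement site coincides with the analysis reference site (water: O;
# excipient: heavy-atom centroid)
def _water_template():
    names = ["O", "H1", "H2"]
    elements = ["O", "H", "H"]
    r = 0.0957
    coords = np.array([
        [0.0, 0.0, 0.0],
        [r, 0.0, 0.0],
        [r * np.cos(np.deg2rad(104.5)), r * np.sin(np.deg2rad(104.5)), 0.0],
    ])
    h_parent = [-1, 0, 0]
    return names, elements, coords, h_parent, "HOH"


def _glycine_template():
    heavy = np.array([
        [-0.15, 0.00, 0.0],   # N
        [0.00, 0.00, 0.0],    # CA
        [0.13, 0.08, 0.0],    # C
        [0.24, 0.13, 0.0],    # O
        [0.16, -0.04, 0.0],   # OXT
    ])
    heavy = heavy - heavy.mean(axis=0)
    n = heavy[0]
    d1 = np.array([-0.7, 0.7, 0.15]); d1 /= np.linalg.norm(d1)
    d2 = np.array([-0.7, -0.7, 0.15]); d2 /= np.linalg.norm(d2)
    coords = np.vstack([heavy, n + 0.10 * d1, n + 0.10 * d2])
    names = ["N", "CA", "C", "O", "OXT", "H1", "H2"]
    elements = ["N", "C", "C", "O", "O", "H", "H"]
    h_parent = [-1, -1, -1, -1, -1, 0, 0]
    return names, elements, coords, h_parent, "GLY"


def _citrate_template():
    # central carbon with six acceptor oxygens (the 3- species donates no H)
    coords = [np.zeros(3)]
    for axis in range(3):
        for s in (+1, -1):
            v = np.zeros(3)
            v[axis] = 0.14 * s
            coords.append(v)
    coords = np.asarray(coords)
    coords = coords - coords.mean(axis=0)
    names = ["C1", "O1", "O2", "O3", "O4", "O5", "O6"]
    elements = ["C", "O", "O", "O", "O", "O", "O"]
    h_parent = [-1] * 7
    return names, elements, coords, h_parent, "CIT"


_TEMPLATES = {
    "water": _water_template(),
    "glycine": _glycine_template(),
    "citrate": _citrate_template(),
}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class _Grid:
    """Occupancy grid for min-separation rejection (cell edge = cutoff)."""

    def __init__(self, cell: float):
        self.cell = cell
        self.cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _key(self, p: np.ndarray) -> tuple[int, int, int]:
        return tuple((p // self.cell).astype(int))

    def far_enough(self, p: np.ndarray) -> bool:
        kx, ky, kz = self._key(p)
        c2 = self.cell * self.cell
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in self.cells.get((kx + dx, ky + dy, kz + dz), ()):
                        d = p - q
                        if d @ d < c2:
                            return False
        return True

    def add(self, p: np.ndarray) -> None:
        self.cells.setdefault(self._key(p), []).append(p)


def _place_sites(
    rng: np.random.Generator,
    n: int,
    region: str,
    *,
    box_edge: float,
    prot_heavy: np.ndarray,
    prot_tree: cKDTree,
    grid: _Grid,
    min_sep: float,
    local_cutoff: float,
    max_batches: int = 400,
) -> np.ndarray:
    """Place ``n`` reference sites in the requested region ('any', 'local',
    'nonlocal') at min separation from protein heavy atoms and prior sites."""
    placed: list[np.ndarray] = []
    batches = 0
    while len(placed) < n:
        batches += 1
        if batches > max_batches:
            raise PackingError(
                f"could not place {n} sites in region {region!r} "
                f"(placed {len(placed)}); box too crowded"
            )
        m = max(64, 3 * (n - len(placed)))
        if region == "local":
            anchors = prot_heavy[rng.integers(0, len(prot_heavy), m)]
            dirs = rng.normal(size=(m, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            lo3, hi3 = min_sep ** 3, local_cutoff ** 3
            rad = (lo3 + rng.random(m) * (hi3 - lo3)) ** (1 / 3)
            pts = anchors + dirs * rad[:, None]
            inside = np.all((pts >= 0) & (pts < box_edge), axis=1)
            pts = pts[inside]
        else:
            pts = rng.random((m, 3)) * box_edge
        if len(pts) == 0:
            continue
        prox, _ = prot_tree.query(pts, k=1)
        ok = prox >= min_sep
        if region == "local":
            ok &= prox <= local_cutoff
        elif region == "nonlocal":
            ok &= prox > local_cutoff
        for p in pts[ok]:
            if grid.far_enough(p):
                grid.add(p)
                placed.append(p)
                if len(placed) == n:
                    break
    return np.asarray(placed).reshape(n, 3)


def solvate(protein: MolecularSystem, spec: SolvationSpec) -> MolecularSystem:
    """Solvate a (copy of the) protein in a periodic cubic box.

    Waters are placed uniformly outside the protein's excluded volume; each
    excipient species is split between the local domain and the bulk so that
    its local count equals the bulk-proportional expectation (from the water
    placement) plus ``excess_local``.  Exact per-region placement counts and
    the implied preferential-interaction ground truth are recorded under
    ``provenance['solvation']``.
    """
    rng = np.random.default_rng(spec.seed)
    box = spec.box_edge
    prot_pos = protein.positions - protein.positions.mean(axis=0) + box / 2
    if np.any(prot_pos < 0) or np.any(prot_pos >= box):
        raise PackingError("protein does not fit in the requested box")
    heavy_idx = np.flatnonzero(protein.elements != "H")
    prot_heavy = prot_pos[heavy_idx]
    prot_tree = cKDTree(prot_heavy)
    grid = _Grid(spec.min_separation)

    water_sites = _place_sites(
        rng, spec.n_water, "any",
        box_edge=box, prot_heavy=prot_heavy, prot_tree=prot_tree,
        grid=grid, min_sep=spec.min_separation, local_cutoff=spec.local_cutoff,
    )
    if spec.n_water:
        dw, _ = prot_tree.query(water_sites, k=1)
        n1_local = int(np.sum(dw <= spec.local_cutoff))
    else:
        n1_local = 0
    n1_nonlocal = spec.n_water - n1_local

    book: dict[str, dict] = {
        "water": {"n_local": n1_local, "n_nonlocal": n1_nonlocal},
    }
    species_sites: dict[str, np.ndarray] = {}
    for sp in sorted(spec.n_excipient):
        n_sp = spec.n_excipient[sp]
        excess = spec.excess_local.get(sp, 0)
        expected = n_sp * n1_local / spec.n_water if spec.n_water else 0.0
        if excess == 0:
            # same spatial law as water: uniform over the accessible volume,
            # so the preferential interaction coefficient is 0 in expectation
            sites = _place_sites(
                rng, n_sp, "any",
                box_edge=box, prot_heavy=prot_heavy, prot_tree=prot_tree,
                grid=grid, min_sep=spec.min_separation,
                local_cutoff=spec.local_cutoff,
            )
            if n_sp:
                ds, _ = prot_tree.query(sites, k=1)
                target_local = int(np.sum(ds <= spec.local_cutoff))
            else:
                target_local = 0
            species_sites[sp] = sites
        else:
            target_local = int(round(expected)) + excess
            target_local = min(max(target_local, 0), n_sp)
            loc = _place_sites(
                rng, target_local, "local",
                box_edge=box, prot_heavy=prot_heavy, prot_tree=prot_tree,
                grid=grid, min_sep=spec.min_separation,
                local_cutoff=spec.local_cutoff,
            )
            non = _place_sites(
                rng, n_sp - target_local, "nonlocal",
                box_edge=box, prot_heavy=prot_heavy, prot_tree=prot_tree,
                grid=grid, min_sep=spec.min_separation,
                local_cutoff=spec.local_cutoff,
            )
            species_sites[sp] = np.vstack([loc, non]) if n_sp else np.zeros((0, 3))
        n_nonloc = n_sp - target_local
        gamma_truth = (
            target_local - (n_nonloc / n1_nonlocal) * n1_local
            if n1_nonlocal else float("nan")
        )
        book[sp] = {
            "n_local": target_local,
            "n_nonlocal": n_nonloc,
            "expected_local": expected,
            "excess_requested": excess,
            "excess_effective": target_local - expected,
            "gamma_truth": gamma_truth,
        }

    # assemble atoms: protein, then waters, then excipients (sorted)
    names = [str(n) for n in protein.names]
    elements = [str(e) for e in protein.elements]
    resids = list(protein.residue_ids)
    resnames = [str(r) for r in protein.residue_names]
    chain_ids = [str(c) for c in protein.chain_ids]
    domains = [str(d) for d in protein.domain_labels]
    positions = [prot_pos]
    h_parent = list(protein.h_parent)
    molecule_index = list(protein.molecule_index)
    molecule_species = list(protein.molecule_species)

    chain_for = {"water": "W", "glycine": "G", "citrate": "X"}
    order = ["water"] + sorted(spec.n_excipient)
    all_sites = {"water": water_sites, **species_sites}
    for sp in order:
        t_names, t_elements, t_coords, t_hp, resname = _TEMPLATES[sp]
        for j, site in enumerate(all_sites[sp]):
            rot = _random_rotation(rng)
            coords = site + t_coords @ rot.T
            base = len(names)
            mol = len(molecule_species)
            molecule_species.append(sp)
            names.extend(t_names)
            elements.extend(t_elements)
            resids.extend([j + 1] * len(t_names))
            resnames.extend([resname] * len(t_names))
            chain_ids.extend([chain_for[sp]] * len(t_names))
            domains.extend(["none"] * len(t_names))
            positions.append(coords)
            h_parent.extend([p + base if p >= 0 else -1 for p in t_hp])
            molecule_index.extend([mol] * len(t_names))

    return MolecularSystem(
        names=names,
        elements=elements,
        residue_ids=resids,
        residue_names=resnames,
        chain_ids=chain_ids,
        positions=np.vstack(positions),
        molecule_index=molecule_index,
        molecule_species=molecule_species,
        domain_labels=domains,
        h_parent=h_parent,
        box_edge=box,
        periodic=True,
        provenance={"solvation": book, "seed": spec.seed},
    )


def solvate_ensemble(
    protein: MolecularSystem,
    spec: SolvationSpec,
    n_frames: int,
    *,
    frame_stride: float = 10.0,
    replica_id: int = 0,
) -> ConformationEnsemble:
    """Independent solvent re-placements of one composition → an ensemble with
    fixed topology; per-frame bookkeeping (and its mean Γ truth) is kept in
    ``provenance``."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    frames = []
    books = []
    system = None
    for f in range(n_frames):
        fspec = SolvationSpec(
            box_edge=spec.box_edge,
            n_water=spec.n_water,
            n_excipient=dict(spec.n_excipient),
            excess_local=dict(spec.excess_local),
            local_cutoff=spec.local_cutoff,
            min_separation=spec.min_separation,
            seed=int(np.random.SeedSequence([spec.seed, f]).generate_state(1)[0]
                     % (2 ** 31)),
        )
        sys_f = solvate(protein, fspec)
        if system is None:
            system = sys_f
        frames.append(sys_f.positions)
        books.append(sys_f.provenance["solvation"])
    gamma_truth = {
        sp: float(np.mean([b[sp]["gamma_truth"] for b in books]))
        for sp in sorted(spec.n_excipient)
    }
    ens = ConformationEnsemble(
        system=system,
        frames=np.stack(frames),
        times=np.arange(n_frames) * frame_stride,
        replica_id=replica_id,
        provenance={"solvation_frames": books, "gamma_truth": gamma_truth,
                    "seed": spec.seed},
    )
    return ens


# ---------------------------------------------------------------------------
# fluctuation ensembles
# ---------------------------------------------------------------------------

def _residue_groups(system: MolecularSystem) -> list[np.ndarray]:
    """Atom index groups per (chain, residue) in order of first appearance."""
    seen: dict[tuple, list[int]] = {}
    for i in range(system.n_atoms):
        key = (str(system.chain_ids[i]), int(system.residue_ids[i]))
        seen.setdefault(key, []).append(i)
    return [np.asarray(v) for v in seen.values()]


def orthogonalize_mode(
    mode_shape: np.ndarray, reference_points: np.ndarray
) -> np.ndarray:
    """Project a per-residue displacement field off the six rigid-body modes
    of ``reference_points`` and normalise it to unit flattened norm, so a
    planted collective mode survives trajectory superposition."""
    pts = reference_points - reference_points.mean(axis=0)
    n = len(pts)
    basis = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis.append(t.ravel())
    for ax in range(3):
        omega = np.zeros(3)
        omega[ax] = 1.0
        basis.append(np.cross(omega, pts).ravel())
    v = np.asarray(mode_shape, dtype=float).ravel().copy()
    for b in basis:
        nb = np.linalg.norm(b)
        if nb > 1e-12:
            v -= (v @ b) / (nb * nb) * b
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValueError("mode lies entirely in the rigid-body subspace")
    return (v / nv).reshape(n, 3)


def fluctuate(system: MolecularSystem, spec: FluctuationSpec) -> ConformationEnsemble:
    """Frames = reference + i.i.d. isotropic Gaussian displacement with
    per-residue σ applied to every atom of the residue (plus the optional
    collective mode)."""
    groups = _residue_groups(system)
    if len(spec.sigma_per_residue) != len(groups):
        raise ValueError(
            f"sigma array length {len(spec.sigma_per_residue)} != residue "
            f"count {len(groups)}"
        )
    if spec.mode_shape is not None and len(spec.mode_shape) != len(groups):
        raise ValueError("mode_shape length must equal residue count")
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, system.n_atoms, 3))
    for f in range(spec.n_frames):
        disp_res = rng.normal(size=(len(groups), 3)) * spec.sigma_per_residue[:, None]
        if spec.mode_shape is not None and spec.mode_sigma > 0:
            disp_res = disp_res + rng.normal(0, spec.mode_sigma) * np.asarray(
                spec.mode_shape
            )
        frame = system.positions.copy()
        for r, idx in enumerate(groups):
            frame[idx] += disp_res[r]
        frames[f] = frame
    return ConformationEnsemble(
        system=system,
        frames=frames,
        times=np.arange(spec.n_frames) * spec.frame_stride,
        provenance={"generator": "fluctuate", "seed": spec.seed},
    )


# ---------------------------------------------------------------------------
# assay simulators
# ---------------------------------------------------------------------------

def two_state_signal(
    T: np.ndarray, Tm: float, dHvh: float,
    native: float, denatured: float,
    slope_native: float = 0.0, slope_denatured: float = 0.0,
) -> np.ndarray:
    """Two-state van't Hoff sigmoid: I(T) = [I_N + I_D·K]/(1+K) with
    K(T) = exp[−(ΔHvh/R)(1/T − 1/Tm)]; baselines are linear about Tm."""
    T = np.asarray(T, dtype=float)
    K = np.exp(np.clip(-(dHvh / R_GAS_KJ) * (1.0 / T - 1.0 / Tm),
                       -500.0, 500.0))
    i_n = native + slope_native * (T - Tm)
    i_d = denatured + slope_denatured * (T - Tm)
    return (i_n + i_d * K) / (1.0 + K)


def simulate_melt(spec: MeltSimSpec) -> FluorescenceMeltSeries:
    """BCM(T) from the two-state model; the noiseless unfolded fraction at
    ``Tm_true`` is exactly 0.5 (K = 1)."""
    bcm = two_state_signal(
        spec.T_grid, spec.Tm_true, spec.dHvh_true,
        spec.native_bcm, spec.denatured_bcm,
        spec.baseline_slopes[0], spec.baseline_slopes[1],
    )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        bcm = bcm + rng.normal(0, spec.noise_sigma, size=bcm.shape)
    return FluorescenceMeltSeries(temperatures=spec.T_grid.copy(), bcm=bcm)


def simulate_monomer_loss(spec: KineticsSimSpec) -> MonomerLossSeries:
    """M(t) = M0·exp(−kobs·t) (+ Gaussian noise)."""
    m = spec.M0_true * np.exp(-spec.kobs_true * spec.timepoints)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        m = m + rng.normal(0, spec.noise_sigma, size=m.shape)
    return MonomerLossSeries(times=spec.timepoints.copy(), monomer=m)


# ---------------------------------------------------------------------------
# whole synthetic study on disk
# ---------------------------------------------------------------------------

def generate_study(
    outdir: str | Path,
    seed: int = 0,
    *,
    labels: tuple[str, ...] = ("GLY0", "GLYPLUS", "GLYMINUS"),
    excess_local: tuple[int, ...] = (0, 6, -6),
    sigma_scale: tuple[float, ...] = (1.0, 0.85, 1.15),
    tm_true: tuple[float, ...] = (350.0, 352.0, 354.0),
    kobs_true: tuple[float, ...] = (0.20, 0.10, 0.05),
    n_residues: int = 14,
    n_water: int = 320,
    n_glycine: int = 40,
    n_frames_surface: int = 40,
    n_frames_flex: int = 300,
    box_edge: float = 5.0,
    n_replicas: int = 1,
) -> Path:
    """Write a complete file-based synthetic study (structures, multi-model
    PDB trajectories, assay CSVs and a pipeline config) with planted truth:
    Γ23 sign pattern ≈0/+/−, global ΔRMSF 0/−15 %/+15 %, monotone Tm."""
    from . import io as fio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protein = build_toy_protein(n_residues, "helix")
    base_sigma = np.full(n_residues, 0.04)
    lines = [
        f'reference = "{labels[0]}"',
        "window_fraction = 0.6667",
        f"seed = {seed}",
        "",
    ]
    for c, label in enumerate(labels):
        cdir = outdir / label
        cdir.mkdir(exist_ok=True)
        surface_paths, flex_paths = [], []
        for rep in range(n_replicas):
            sub = seed * 1009 + c * 101 + rep
            ens = solvate_ensemble(
                protein,
                SolvationSpec(
                    box_edge=box_edge, n_water=n_water,
                    n_excipient={"glycine": n_glycine},
                    excess_local={"glycine": excess_local[c]},
                    seed=sub,
                ),
                n_frames_surface,
                replica_id=rep,
            )
            if rep == 0:
                fio.write_pdb(ens.system, cdir / "structure.pdb")
            spath = cdir / f"surface_rep{rep}.pdb"
            fio.write_trajectory(ens, spath)
            surface_paths.append(spath)
            flex = fluctuate(
                protein,
                FluctuationSpec(
                    sigma_per_residue=base_sigma * sigma_scale[c],
                    n_frames=n_frames_flex, seed=sub + 7,
                ),
            )
            fpath = cdir / f"flex_rep{rep}.pdb"
            fio.write_trajectory(flex, fpath)
            flex_paths.append(fpath)
        fio.write_pdb(protein, outdir / "protein.pdb")
        melt = simulate_melt(MeltSimSpec(
            Tm_true=tm_true[c], dHvh_true=450.0, noise_sigma=0.05,
            seed=seed * 13 + c,
        ))
        import pandas as pd
        pd.DataFrame(
            {"temperature": melt.temperatures - 273.15, "bcm": melt.bcm}
        ).to_csv(cdir / "melt.csv", index=False)
        kin = simulate_monomer_loss(KineticsSimSpec(
            M0_true=100.0, kobs_true=kobs_true[c], noise_sigma=0.3,
            seed=seed * 17 + c,
        ))
        pd.DataFrame(
            {"time_days": kin.times, "monomer_percent": kin.monomer}
        ).to_csv(cdir / "kinetics.csv", index=False)
        lines += [
            f"[conditions.{label}]",
            f'structure = "{label}/structure.pdb"',
            "surface_trajectories = ["
            + ", ".join(f'"{label}/{p.name}"' for p in surface_paths) + "]",
            f'flex_structure = "protein.pdb"',
            "flex_trajectories = ["
            + ", ".join(f'"{label}/{p.name}"' for p in flex_paths) + "]",
            f'melt_csv = "{label}/melt.csv"',
            f'kinetics_csv = "{label}/kinetics.csv"',
            "",
        ]
    (outdir / "config.toml").write_text("\n".join(lines))
    return outdir / "config.toml"
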