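"""Preferential interaction statistics around the protein surface.

The local domain is the region within a cutoff (default 0.6 nm ≈ two
hydration shells) of the protein.  The default distance metric is *proximal*:
a molecule's distance is the minimum distance from its reference site (water:
the oxygen; excipients: the heavy-atom centroid) to any protein heavy atom.
A centre-of-mass radial metric is retained as an option.

The preferential interaction coefficient is computed two independent ways:

* counting form   Γ23 = ⟨ n3(R) − (ρ3/ρ1)·n1(R) ⟩, bulk densities taken
  from the region farther than 2R from the protein;
* RDF-integral form  Γ23 = ρ3 Σ_r [g3(r) − g1(r)]·V(r) up to R, with
  Monte-Carlo-estimated accessible shell volumes V(r).

Positive Γ23 means preferential binding of the excipient, negative means
preferential exclusion (hydration-shell dominance).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import (
    ConformationEnsemble,
    EmptySelectionError,
    MolecularSystem,
    Selection,
)

METRIC_PROXIMAL = "proximal"
METRIC_COM_RADIAL = "com_radial"


def species_molecules(system: MolecularSystem, species) -> np.ndarray:
    """Molecule indices for a species name or a :class:`Selection`."""
    if isinstance(species, Selection):
        return np.unique(system.molecule_index[species.indices])
    return system.molecules_of_species(str(species))


class SiteIndex:
    """Precomputed per-molecule reference-site atom indices for one species,
    reusable across frames: water → its oxygen; others → heavy-atom set
    whose centroid is the site."""

    def __init__(self, system: MolecularSystem, species):
        mols = species_molecules(system, species)
        if len(mols) == 0:
            raise EmptySelectionError(f"no molecules of species {species!r}")
        atom_lists = []
        for m in mols:
            idx = system.molecule_atoms(int(m))
            heavy = idx[system.elements[idx] != "H"]
            if system.molecule_species[int(m)] == "water":
                oxy = heavy[system.elements[heavy] == "O"]
                atom_lists.append(oxy[:1] if len(oxy) else heavy)
            else:
                atom_lists.append(heavy)
        self.molecules = mols
        self.flat = np.concatenate(atom_lists)
        counts = np.array([len(a) for a in atom_lists])
        self.offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.counts = counts

    def sites(self, coords: np.ndarray) -> np.ndarray:
        sums = np.add.reduceat(coords[self.flat], self.offsets, axis=0)
        return sums / self.counts[:, None]


def reference_sites(
    system: MolecularSystem, coords: np.ndarray, species
) -> np.ndarray:
    """(n_molecules, 3) reference sites: water oxygen, else heavy centroid."""
    return SiteIndex(system, species).sites(coords)


def _protein_tree(system: MolecularSystem, coords: np.ndarray):
    heavy = system.protein_heavy_indices()
    box = system.box_edge if system.periodic else None
    if box is not None:
        return cKDTree(np.mod(coords[heavy], box), boxsize=box), box
    return cKDTree(coords[heavy]), None


def proximal_distances(
    system: MolecularSystem, coords: np.ndarray, sites: np.ndarray
) -> np.ndarray:
    """Minimum distance of each site to any protein heavy atom (min image)."""
    tree, box = _protein_tree(system, coords)
    pts = np.mod(sites, box) if box is not None else sites
    d, _ = tree.query(pts, k=1)
    return d


# ---------------------------------------------------------------------------
# radial distribution functions
# ---------------------------------------------------------------------------


@dataclass
class RDFProfile:
    bin_edges: np.ndarray               # nm
    g_values: np.ndarray                # dimensionless
    species: str
    distance_metric: str
    bulk_density: float                 # nm^-3
    shell_volumes: np.ndarray           # nm^3 per bin
    counts: np.ndarray                  # mean molecules per frame per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.bin_centers, "g": self.g_values})


def _mc_shell_volumes(
    system: MolecularSystem,
    coords: np.ndarray,
    bin_edges: np.ndarray,
    bulk_start: float,
    n_mc: int,
    seed: int,
) -> tuple[np.ndarray, float]:
    """Monte-Carlo accessible volumes of proximal-distance shells and of the
    bulk region (proximal distance > bulk_start), in nm³."""
    box = system.box_edge
    if box is None:
        raise ValueError("proximal shell volumes need a box")
    rng = np.random.default_rng(seed)
    pts = rng.random((n_mc, 3)) * box
    tree, _ = _protein_tree(system, coords)
    d, _idx = tree.query(pts, k=1)
    vol_box = box ** 3
    hist, _ = np.histogram(d, bins=bin_edges)
    shell_vol = hist / n_mc * vol_box
    bulk_vol = np.sum(d > bulk_start) / n_mc * vol_box
    return shell_vol, bulk_vol


def compute_rdf(
    ensemble: ConformationEnsemble,
    species,
    metric: str = METRIC_PROXIMAL,
    bin_width: float = 0.02,
    r_max: float | None = None,
    *,
    cutoff: float = 0.6,
    n_mc: int = 200_000,
    seed: int = 0,
    window_fraction: float = 1.0,
) -> RDFProfile:
    """Distribution of a species around the protein.

    ``proximal`` normalises by Monte-Carlo accessible shell volumes;
    ``com_radial`` by spherical shell volumes around the protein centre of
    mass.  The bulk density is estimated from the region farther than
    2×``cutoff`` (proximal) from the protein, away from the interface.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    system = ensemble.system
    box = system.box_edge
    if r_max is None:
        r_max = (box / 2) if box else 2.5
    if box is not None and r_max > box / 2 + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half box edge {box / 2}")
    if metric not in (METRIC_PROXIMAL, METRIC_COM_RADIAL):
        raise ValueError(f"unknown metric {metric!r}")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    frames = ensemble.window(window_fraction)
    bulk_start = 2 * cutoff

    prot_idx = system.protein_heavy_indices()
    masses = system.masses[prot_idx]
    counts = np.zeros(len(edges) - 1)
    bulk_counts = 0.0
    n_f = len(frames)
    site_index = SiteIndex(system, species)
    for f in frames:
        coords = ensemble.frames[f]
        sites = site_index.sites(coords)
        prox = proximal_distances(system, coords, sites)
        if metric == METRIC_PROXIMAL:
            dist = prox
        else:
            com = np.average(coords[prot_idx], axis=0, weights=masses)
            dist = np.linalg.norm(sites - com, axis=1)
        h, _ = np.histogram(dist, bins=edges)
        counts += h
        bulk_counts += np.sum(prox > bulk_start)
    counts /= n_f
    bulk_counts /= n_f

    if metric == METRIC_PROXIMAL:
        shell_vol, bulk_vol = _mc_shell_volumes(
            system, ensemble.frames[frames[0]], edges, bulk_start, n_mc, seed
        )
    else:
        shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        _sv, bulk_vol = _mc_shell_volumes(
            system, ensemble.frames[frames[0]], edges, bulk_start, n_mc, seed
        )
    if bulk_vol <= 0:
        raise ValueError("no bulk region available for density estimation")
    rho_bulk = bulk_counts / bulk_vol
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(
            (shell_vol > 0) & (rho_bulk > 0),
            counts / np.maximum(shell_vol, 1e-300) / max(rho_bulk, 1e-300),
            0.0,
        )
    return RDFProfile(
        bin_edges=edges,
        g_values=g,
        species=str(species),
        distance_metric=metric,
        bulk_density=float(rho_bulk),
        shell_volumes=shell_vol,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# preferential interaction coefficient
# ---------------------------------------------------------------------------


@dataclass
class PreferentialCoefficient:
    gamma23: float                      # counting form, mean over window
    gamma23_integral: float             # RDF-integral form
    cutoff: float
    per_frame: np.ndarray
    mean: float = field(init=False)
    sem: float = field(init=False)
    rho3_bulk: float = 0.0              # nm^-3
    rho1_bulk: float = 0.0

    def __post_init__(self) -> None:
        self.per_frame = np.asarray(self.per_frame, dtype=float)
        self.mean = float(self.per_frame.mean())
        n = len(self.per_frame)
        self.sem = float(self.per_frame.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")


def gamma23(
    ensemble: ConformationEnsemble,
    excipient="glycine",
    water="water",
    cutoff: float = 0.6,
    *,
    window_fraction: float = 2 / 3,
    bin_width: float = 0.02,
    n_mc: int = 200_000,
    seed: int = 0,
) -> PreferentialCoefficient:
    """Preferential interaction coefficient of an excipient species.

    Counting and RDF-integral routes are both evaluated; they agree within a
    few percent on well-sampled systems and the counting mean is the headline
    value.  Raises when the bulk contains no water (undefined density ratio).
    """
    system = ensemble.system
    frames = ensemble.window(window_fraction)
    bulk_start = 2 * cutoff

    exc_mols = species_molecules(system, excipient)
    if len(exc_mols) == 0:
        return PreferentialCoefficient(
            gamma23=0.0, gamma23_integral=0.0, cutoff=cutoff,
            per_frame=np.zeros(len(frames)),
        )

    exc_index = SiteIndex(system, excipient)
    wat_index = SiteIndex(system, water)
    per_frame = np.empty(len(frames))
    n3_bulk_tot = 0.0
    n1_bulk_tot = 0.0
    for i, f in enumerate(frames):
        coords = ensemble.frames[f]
        d3 = proximal_distances(system, coords, exc_index.sites(coords))
        d1 = proximal_distances(system, coords, wat_index.sites(coords))
        n3_loc = np.sum(d3 <= cutoff)
        n1_loc = np.sum(d1 <= cutoff)
        n3_b = np.sum(d3 > bulk_start)
        n1_b = np.sum(d1 > bulk_start)
        if n1_b == 0:
            raise ZeroDivisionError(
                "zero bulk water count: density ratio undefined"
            )
        per_frame[i] = n3_loc - (n3_b / n1_b) * n1_loc
        n3_bulk_tot += n3_b
        n1_bulk_tot += n1_b

    # independent route through the binned RDF machinery
    bw = cutoff / max(1, round(cutoff / bin_width))
    box = system.box_edge
    r_max = box / 2 if box else 2.5
    rdf3 = compute_rdf(
        ensemble, excipient, METRIC_PROXIMAL, bw, r_max,
        cutoff=cutoff, n_mc=n_mc, seed=seed, window_fraction=window_fraction,
    )
    rdf1 = compute_rdf(
        ensemble, water, METRIC_PROXIMAL, bw, r_max,
        cutoff=cutoff, n_mc=n_mc, seed=seed + 1, window_fraction=window_fraction,
    )
    inside = rdf3.bin_edges[1:] <= cutoff + 1e-9
    gamma_int = rdf3.bulk_density * float(np.sum(
        (rdf3.g_values[inside] - rdf1.g_values[inside])
        * rdf3.shell_volumes[inside]
    ))
    return PreferentialCoefficient(
        gamma23=float(per_frame.mean()),
        gamma23_integral=gamma_int,
        cutoff=cutoff,
        per_frame=per_frame,
        rho3_bulk=rdf3.bulk_density,
        rho1_bulk=rdf1.bulk_density,
    )


# ---------------------------------------------------------------------------
# hydration shells, displacement, contacts
# ---------------------------------------------------------------------------


@dataclass
class ShellOccupancy:
    """Per-frame counts of a species with proximal distance in the first
    [0, 0.35) nm and second [0.35, 0.6) nm hydration shells (half-open)."""

    boundaries: tuple[float, float]
    per_frame_first: np.ndarray
    per_frame_second: np.ndarray
    mean_first: float = field(init=False)
    mean_second: float = field(init=False)
    sem_first: float = field(init=False)
    sem_second: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_frame_first = np.asarray(self.per_frame_first, dtype=float)
        self.per_frame_second = np.asarray(self.per_frame_second, dtype=float)
        n = len(self.per_frame_first)
        self.mean_first = float(self.per_frame_first.mean())
        self.mean_second = float(self.per_frame_second.mean())
        if n > 1:
            self.sem_first = float(self.per_frame_first.std(ddof=1) / np.sqrt(n))
            self.sem_second = float(self.per_frame_second.std(ddof=1) / np.sqrt(n))
        else:
            self.sem_first = self.sem_second = float("nan")


def shell_occupancy(
    ensemble: ConformationEnsemble,
    species="water",
    boundaries: tuple[float, float] = (0.35, 0.6),
    *,
    window_fraction: float = 2 / 3,
) -> ShellOccupancy:
    """First/second hydration-shell molecule counts by proximal distance of
    the reference site; a molecule exactly at the first boundary counts in
    the second shell."""
    system = ensemble.system
    frames = ensemble.window(window_fraction)
    b1, b2 = boundaries
    first = np.empty(len(frames))
    second = np.empty(len(frames))
    site_index = SiteIndex(system, species)
    for i, f in enumerate(frames):
        coords = ensemble.frames[f]
        d = proximal_distances(system, coords, site_index.sites(coords))
        first[i] = np.sum(d < b1)
        second[i] = np.sum((d >= b1) & (d < b2))
    return ShellOccupancy(boundaries=boundaries, per_frame_first=first,
                          per_frame_second=second)


@dataclass(frozen=True)
class Displacement:
    percent: float
    percent_rounded: int


def displacement_percent(count_reference: float, count_condition: float) -> Displacement:
    """Percent of molecules displaced relative to the reference condition:
    100·(ref − cond)/ref, reported raw and rounded to the nearest integer."""
    if count_reference <= 0:
        raise ValueError("count_reference must be positive")
    raw = 100.0 * (count_reference - count_condition) / count_reference
    return Displacement(percent=raw, percent_rounded=int(round(raw)))


@dataclass
class ContactFrequencyMap:
    """Per-residue fraction of frames with any species heavy atom within the
    cutoff of any residue heavy atom."""

    species: str
    cutoff: float
    frequencies: pd.DataFrame           # index (chain, residue_id), col 'frequency'

    def to_bfactors(self, system: MolecularSystem) -> np.ndarray:
        vals = {
            rid: float(v)
            for (_ch, rid), v in self.frequencies["frequency"].items()
        }
        out = np.zeros(system.n_atoms)
        for i in range(system.n_atoms):
            out[i] = vals.get(int(system.residue_ids[i]), 0.0)
        return out


def contact_frequency(
    ensemble: ConformationEnsemble,
    species,
    cutoff: float = 0.6,
    *,
    window_fraction: float = 2 / 3,
) -> ContactFrequencyMap:
    """Residue-level contact frequencies of an excipient species (the
    structure-colouring quantity)."""
    system = ensemble.system
    frames = ensemble.window(window_fraction)
    prot_heavy = system.protein_heavy_indices()
    residues = system.residue_index_table()
    res_key_of_atom = {
        int(i): (str(system.chain_ids[i]), int(system.residue_ids[i]))
        for i in prot_heavy
    }
    mols = species_molecules(system, species)
    sp_atoms = np.concatenate([
        system.molecule_atoms(int(m)) for m in mols
    ]) if len(mols) else np.array([], dtype=int)
    sp_heavy = sp_atoms[system.elements[sp_atoms] != "H"]
    if len(sp_heavy) == 0:
        raise EmptySelectionError(f"species {species!r} has no heavy atoms")
    box = system.box_edge if system.periodic else None

    hits = {key: 0 for key in residues}
    for f in frames:
        coords = ensemble.frames[f]
        if box is not None:
            tree = cKDTree(np.mod(coords[sp_heavy], box), boxsize=box)
            q = np.mod(coords[prot_heavy], box)
        else:
            tree = cKDTree(coords[sp_heavy])
            q = coords[prot_heavy]
        d, _ = tree.query(q, k=1)
        contacted = set()
        for i, dist in zip(prot_heavy, d):
            if dist <= cutoff:
                contacted.add(res_key_of_atom[int(i)])
        for key in contacted:
            hits[key] += 1
    n_f = len(frames)
    df = pd.DataFrame(
        {"frequency": [hits[key] / n_f for key in residues]},
        index=pd.MultiIndex.from_tuples(residues, names=["chain", "residue_id"]),
    )
    return ContactFrequencyMap(species=str(species), cutoff=cutoff,
                               frequencies=df)
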