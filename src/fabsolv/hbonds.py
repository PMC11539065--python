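"""Geometric hydrogen-bond detection, class counting, excipient clustering
and per-bond occupancy.

A bond is a (donor-H, acceptor) pair satisfying a distance cutoff (donor–
acceptor or hydrogen–acceptor, selectable) and an angle cutoff.  The default
angle convention is the hydrogen–donor–acceptor angle ≤ cutoff (the common
trajectory-tool convention); the deviation-from-linearity convention at the
hydrogen (180° − ∠D–H···A ≤ cutoff) is selectable.  Correctness is defined by
equivalence with the all-pairs oracle in the test suite, not by the KD-tree
acceleration used here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import ConformationEnsemble, MolecularSystem, Selection, minimum_image

DIST_DONOR_ACCEPTOR = "donor-acceptor"
DIST_HYDROGEN_ACCEPTOR = "hydrogen-acceptor"
ANGLE_HDA = "hda"                       # H–D–A angle at the donor
ANGLE_DHA_LINEARITY = "dha-linearity"   # 180° − ∠D–H–A at the hydrogen


@dataclass(frozen=True)
class HBondCriteria:
    distance_cutoff: float = 0.35       # nm
    distance_definition: str = DIST_DONOR_ACCEPTOR
    angle_cutoff: float = 30.0          # degrees
    angle_definition: str = ANGLE_HDA

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if not 0 < self.angle_cutoff < 180:
            raise ValueError("angle_cutoff must be in (0, 180)")
        if self.distance_definition not in (DIST_DONOR_ACCEPTOR,
                                            DIST_HYDROGEN_ACCEPTOR):
            raise ValueError(f"unknown distance definition "
                             f"{self.distance_definition!r}")
        if self.angle_definition not in (ANGLE_HDA, ANGLE_DHA_LINEARITY):
            raise ValueError(f"unknown angle definition "
                             f"{self.angle_definition!r}")


#: protein-surface and citrate–glycine criterion (0.35 nm d–a, 30° d–h–a)
FAB_CRITERIA = HBondCriteria()
#: glycine–glycine clustering criterion (0.22 nm donor–acceptor).  At
#: 0.22 nm a D–A contact is sterically implausible; pass
#: ``distance_definition='hydrogen-acceptor'`` to reinterpret the cutoff as
#: an H–A distance instead.
GLY_GLY_CRITERIA = HBondCriteria(distance_cutoff=0.22)


@dataclass(frozen=True)
class HBondRecord:
    frame_index: int
    donor_atom_id: int                  # 1-based
    hydrogen_atom_id: int
    acceptor_atom_id: int
    distance: float                     # nm, per the distance definition
    angle: float                        # degrees, per the angle convention
    partner_classes: tuple[str, str]    # (donor species, acceptor species)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.einsum("...i,...i", v1, v2) / np.maximum(n1 * n2, 1e-300)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(
    system: MolecularSystem,
    coords: np.ndarray,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria = FAB_CRITERIA,
    *,
    frame_index: int = 0,
    exclude_same_molecule: bool = False,
) -> list[HBondRecord]:
    """All (donor-H, acceptor) pairs in one frame satisfying the criteria.

    Donor atoms in the selection that carry no bonded hydrogen are skipped
    (one warning reports how many).  Results are invariant under rigid-body
    transforms and, for periodic systems, under coordinate wrapping.
    """
    coords = np.asarray(coords, dtype=float)
    donor_heavy = donors.indices[system.is_donor_heavy[donors.indices]]
    skipped = int(np.sum(
        system.is_acceptor[donors.indices]
        & ~system.is_donor_heavy[donors.indices]
    ))
    if skipped:
        warnings.warn(
            f"{skipped} donor candidate(s) without bonded hydrogens skipped",
            stacklevel=2,
        )
    acc = acceptors.indices[system.is_acceptor[acceptors.indices]]
    if len(donor_heavy) == 0 or len(acc) == 0:
        return []

    dh_pairs = [
        (d, h) for d in donor_heavy for h in system.bonded_hydrogens_of(d)
    ]
    if not dh_pairs:
        return []
    d_idx = np.asarray([p[0] for p in dh_pairs])
    h_idx = np.asarray([p[1] for p in dh_pairs])

    box = system.box_edge if system.periodic else None
    search_idx = d_idx if criteria.distance_definition == DIST_DONOR_ACCEPTOR else h_idx
    if box is not None:
        acc_tree = cKDTree(np.mod(coords[acc], box), boxsize=box)
        hits = acc_tree.query_ball_point(
            np.mod(coords[search_idx], box), r=criteria.distance_cutoff * (1 + 1e-12)
        )
    else:
        acc_tree = cKDTree(coords[acc])
        hits = acc_tree.query_ball_point(
            coords[search_idx], r=criteria.distance_cutoff * (1 + 1e-12)
        )

    records: list[HBondRecord] = []
    species = system.species_per_atom
    for k, neighbours in enumerate(hits):
        if not neighbours:
            continue
        d, h = d_idx[k], h_idx[k]
        a_candidates = acc[np.asarray(neighbours)]
        a_candidates = a_candidates[a_candidates != d]
        if exclude_same_molecule:
            a_candidates = a_candidates[
                system.molecule_index[a_candidates] != system.molecule_index[d]
            ]
        if len(a_candidates) == 0:
            continue
        da = minimum_image(coords[a_candidates] - coords[d], box)
        dh = minimum_image(coords[h] - coords[d], box)
        ha = minimum_image(coords[a_candidates] - coords[h], box)
        if criteria.distance_definition == DIST_DONOR_ACCEPTOR:
            dist = np.linalg.norm(da, axis=1)
        else:
            dist = np.linalg.norm(ha, axis=1)
        if criteria.angle_definition == ANGLE_HDA:
            ang = _angle_deg(np.broadcast_to(dh, da.shape), da)
        else:
            ang = 180.0 - _angle_deg(np.broadcast_to(-dh, ha.shape), ha)
        ok = (dist <= criteria.distance_cutoff) & (ang <= criteria.angle_cutoff)
        for a, dd, aa in zip(a_candidates[ok], dist[ok], ang[ok]):
            records.append(HBondRecord(
                frame_index=frame_index,
                donor_atom_id=int(d) + 1,
                hydrogen_atom_id=int(h) + 1,
                acceptor_atom_id=int(a) + 1,
                distance=float(dd),
                angle=float(aa),
                partner_classes=(str(species[d]), str(species[a])),
            ))
    return records


def detect_hbonds_ensemble(
    ensemble: ConformationEnsemble,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria = FAB_CRITERIA,
    *,
    exclude_same_molecule: bool = False,
    window_fraction: float = 1.0,
) -> tuple[list[HBondRecord], np.ndarray]:
    """Detect over the trailing window; returns (records, frame indices)."""
    frames = ensemble.window(window_fraction)
    records: list[HBondRecord] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in frames:
            records.extend(detect_hbonds(
                ensemble.system, ensemble.frames[f], donors, acceptors,
                criteria, frame_index=int(f),
                exclude_same_molecule=exclude_same_molecule,
            ))
    return records, frames


_NAMED_PAIRS = {
    "protein-glycine": ("protein", "glycine"),
    "protein-citrate": ("protein", "citrate"),
    "protein-water": ("protein", "water"),
    "glycine-glycine": ("glycine", "glycine"),
    "citrate-glycine": ("citrate", "glycine"),
    "backbone-intra": ("protein", "protein"),
}


def count_hbonds_by_class(
    records: list[HBondRecord],
    class_pairs: list[tuple[str, str] | str],
    frame_indices: np.ndarray | list[int],
) -> pd.DataFrame:
    """Per-frame bond counts for the requested species pairs (unordered
    match); rows = frames, columns = pairs."""
    pairs: list[tuple[str, str]] = []
    names: list[str] = []
    for p in class_pairs:
        if isinstance(p, str):
            if p not in _NAMED_PAIRS:
                raise ValueError(f"unknown class pair {p!r}")
            pairs.append(_NAMED_PAIRS[p])
            names.append(p)
        else:
            a, b = p
            pairs.append((a, b))
            names.append(f"{a}-{b}")
    frame_indices = list(frame_indices)
    table = pd.DataFrame(0, index=pd.Index(frame_indices, name="frame"),
                         columns=names, dtype=int)
    want = {tuple(sorted(p)): n for p, n in zip(pairs, names)}
    for rec in records:
        key = tuple(sorted(rec.partner_classes))
        name = want.get(key)
        if name is not None and rec.frame_index in table.index:
            table.loc[rec.frame_index, name] += 1
    return table


def summarize_counts(per_replica_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Replica means of the per-frame counts, then mean and SEM across
    replicas (SEM is NaN for a single replica)."""
    means = pd.concat([t.mean(axis=0) for t in per_replica_tables], axis=1)
    out = pd.DataFrame({
        "mean": means.mean(axis=1),
        "sem": means.std(axis=1, ddof=1) / np.sqrt(means.shape[1])
        if means.shape[1] > 1 else np.nan,
        "n_replicas": means.shape[1],
    })
    return out


@dataclass
class ClusterFractions:
    """Per-frame monomer/dimer/Nmer fractions of an excipient population:
    a molecule with 0 intermolecular H-bonds is a monomer, exactly 1 a dimer
    member, more than 1 an Nmer member."""

    frames: np.ndarray
    per_frame: np.ndarray               # (n_frames, 3): monomer, dimer, nmer
    mean: np.ndarray = field(init=False)
    sem: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.per_frame = np.asarray(self.per_frame, dtype=float)
        self.mean = self.per_frame.mean(axis=0)
        n = len(self.per_frame)
        self.sem = (self.per_frame.std(axis=0, ddof=1) / np.sqrt(n)
                    if n > 1 else np.full(3, np.nan))


def classify_clusters(
    records: list[HBondRecord],
    n_molecules: int,
    system: MolecularSystem,
    frame_indices: np.ndarray | list[int],
    species: str = "glycine",
) -> ClusterFractions:
    """Classify each molecule of ``species`` by its own intermolecular
    hydrogen-bond count in every frame; fractions are over ``n_molecules``
    and sum to 1 per frame."""
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    mol_ids = set(int(m) for m in system.molecules_of_species(species))
    frame_indices = list(frame_indices)
    frame_pos = {f: i for i, f in enumerate(frame_indices)}
    bonds_per_mol: list[dict[int, int]] = [dict() for _ in frame_indices]
    for rec in records:
        pos = frame_pos.get(rec.frame_index)
        if pos is None:
            continue
        md = int(system.molecule_index[rec.donor_atom_id - 1])
        ma = int(system.molecule_index[rec.acceptor_atom_id - 1])
        if md == ma:
            continue
        for m in (md, ma):
            if m in mol_ids:
                bonds_per_mol[pos][m] = bonds_per_mol[pos].get(m, 0) + 1
    per_frame = np.empty((len(frame_indices), 3))
    for i, counts in enumerate(bonds_per_mol):
        n_dimer = sum(1 for c in counts.values() if c == 1)
        n_nmer = sum(1 for c in counts.values() if c > 1)
        n_mono = n_molecules - n_dimer - n_nmer
        per_frame[i] = (n_mono / n_molecules, n_dimer / n_molecules,
                        n_nmer / n_molecules)
    return ClusterFractions(frames=np.asarray(frame_indices), per_frame=per_frame)


def hbond_occupancy(
    ensemble: ConformationEnsemble,
    pairs: list[tuple[int, int]],
    criteria: HBondCriteria = FAB_CRITERIA,
) -> pd.DataFrame:
    """Fraction of frames in which each (donor_atom_id, acceptor_atom_id)
    pair forms a hydrogen bond (through any hydrogen of the donor)."""
    sys = ensemble.system
    for d_id, a_id in pairs:
        if not (1 <= d_id <= sys.n_atoms and 1 <= a_id <= sys.n_atoms):
            raise ValueError(f"invalid atom ids ({d_id}, {a_id})")
    if not pairs:
        return pd.DataFrame(columns=["donor_atom_id", "acceptor_atom_id",
                                     "occupancy"])
    box = sys.box_edge if sys.periodic else None
    formed = np.zeros(len(pairs), dtype=int)
    for frame in ensemble.frames:
        for k, (d_id, a_id) in enumerate(pairs):
            d, a = d_id - 1, a_id - 1
            for h in sys.bonded_hydrogens_of(d):
                if _pair_formed(frame, d, h, a, criteria, box):
                    formed[k] += 1
                    break
    return pd.DataFrame({
        "donor_atom_id": [p[0] for p in pairs],
        "acceptor_atom_id": [p[1] for p in pairs],
        "occupancy": formed / ensemble.n_frames,
    })


def site_occupancy(
    ensemble: ConformationEnsemble,
    sites: dict[str, list[tuple[int, int]]],
    criteria: HBondCriteria = FAB_CRITERIA,
) -> pd.Series:
    """Site-level occupancy: the fraction of frames in which at least one of
    a named site's pairs is formed (hotspot-style bookkeeping)."""
    sys = ensemble.system
    box = sys.box_edge if sys.periodic else None
    out = {}
    for name, pairs in sites.items():
        count = 0
        for frame in ensemble.frames:
            hit = False
            for d_id, a_id in pairs:
                d, a = d_id - 1, a_id - 1
                for h in sys.bonded_hydrogens_of(d):
                    if _pair_formed(frame, d, h, a, criteria, box):
                        hit = True
                        break
                if hit:
                    break
            count += hit
        out[name] = count / ensemble.n_frames
    return pd.Series(out, name="site_occupancy")


def _pair_formed(coords, d, h, a, criteria: HBondCriteria, box) -> bool:
    da = minimum_image(coords[a] - coords[d], box)
    dh = minimum_image(coords[h] - coords[d], box)
    ha = minimum_image(coords[a] - coords[h], box)
    if criteria.distance_definition == DIST_DONOR_ACCEPTOR:
        dist = np.linalg.norm(da)
    else:
        dist = np.linalg.norm(ha)
    if dist > criteria.distance_cutoff:
        return False
    if criteria.angle_definition == ANGLE_HDA:
        ang = _angle_deg(dh, da)
    else:
        ang = 180.0 - _angle_deg(-dh, ha)
    return bool(ang <= criteria.angle_cutoff)
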