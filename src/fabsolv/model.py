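"""Core data model: atoms, molecular systems, conformational ensembles.

Units are nm (length), ps (time), amu (mass), K (temperature) throughout the
package; ångström appears only at PDB file boundaries.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

SPECIES = ("protein", "water", "glycine", "citrate", "ion", "other")
DOMAIN_LABELS = ("VH", "VL", "CH1", "CL", "other", "none")

#: van der Waals radii in nm (Bondi-style values; configurable per system).
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "NA": 0.227,
    "CL": 0.175,
}
DEFAULT_VDW_NM = 0.170

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
}
DEFAULT_MASS = 12.011


class FabsolvError(Exception):
    """Base class for package errors."""


class ParseError(FabsolvError):
    pass


class ClassificationError(FabsolvError):
    pass


class TopologyError(FabsolvError):
    pass


class SelectionError(FabsolvError):
    pass


class EmptySelectionError(SelectionError):
    pass


class PackingError(FabsolvError):
    pass


@dataclass
class AtomRecord:
    """A single atom; a row view into :class:`MolecularSystem` columns."""

    atom_id: int                      # 1-based, contiguous per system
    name: str
    element: str
    residue_id: int                   # 1-based
    residue_name: str
    chain_id: str
    domain_label: str
    position: np.ndarray              # (3,), nm
    vdw_radius: float                 # nm
    mass: float                       # amu
    is_donor_heavy: bool
    is_acceptor: bool
    bonded_hydrogens: list[int]       # atom_ids of attached hydrogens


class MolecularSystem:
    """Topology + reference coordinates of one solvated (or bare) system.

    Stored column-wise in numpy arrays for speed; :meth:`atom` materialises an
    :class:`AtomRecord` on demand.  Atoms are partitioned into molecules, each
    carrying a species label; surface analyses require exactly one ``protein``
    molecule.
    """

    def __init__(
        self,
        *,
        names: Sequence[str],
        elements: Sequence[str],
        residue_ids: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        positions: np.ndarray,
        molecule_index: Sequence[int],
        molecule_species: Sequence[str],
        domain_labels: Sequence[str] | None = None,
        vdw_radii: Sequence[float] | None = None,
        masses: Sequence[float] | None = None,
        h_parent: Sequence[int] | None = None,
        box_edge: float | None = None,
        periodic: bool = False,
        provenance: dict | None = None,
    ):
        n = len(names)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray([e.upper() for e in elements], dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=np.int64)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.positions = np.asarray(positions, dtype=float).reshape(n, 3)
        self.molecule_index = np.asarray(molecule_index, dtype=np.int64)
        self.molecule_species = list(molecule_species)
        if domain_labels is None:
            domain_labels = ["none"] * n
        self.domain_labels = np.asarray(domain_labels, dtype=object)
        if vdw_radii is None:
            vdw_radii = [VDW_RADII_NM.get(e, DEFAULT_VDW_NM) for e in self.elements]
        self.vdw_radii = np.asarray(vdw_radii, dtype=float)
        if masses is None:
            masses = [ATOMIC_MASSES.get(e, DEFAULT_MASS) for e in self.elements]
        self.masses = np.asarray(masses, dtype=float)
        # h_parent[i] = 0-based index of the heavy atom a hydrogen is bonded
        # to, -1 for heavy atoms / orphan hydrogens.
        if h_parent is None:
            h_parent = np.full(n, -1, dtype=np.int64)
        self.h_parent = np.asarray(h_parent, dtype=np.int64)
        self.box_edge = box_edge
        self.periodic = bool(periodic)
        self.provenance = provenance or {}
        self._validate()
        self._assign_donors_acceptors()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        n = self.n_atoms
        arrays = (
            self.names, self.elements, self.residue_ids, self.residue_names,
            self.chain_ids, self.molecule_index, self.domain_labels,
            self.vdw_radii, self.masses, self.h_parent,
        )
        if any(len(a) != n for a in arrays):
            raise TopologyError("column lengths disagree with atom count")
        if not np.all(np.isfinite(self.positions)):
            raise TopologyError("non-finite coordinates")
        if np.any(self.vdw_radii <= 0):
            raise TopologyError("vdw radii must be positive")
        if n and (self.molecule_index.min() < 0
                  or self.molecule_index.max() >= len(self.molecule_species)):
            raise TopologyError("molecule index out of range")
        for s in self.molecule_species:
            if s not in SPECIES:
                raise ClassificationError(f"unknown species label {s!r}")
        bad = (self.h_parent >= n) | (self.h_parent < -1)
        if np.any(bad):
            raise TopologyError("bonded hydrogen parent does not exist")
        if self.periodic and (self.box_edge is None or self.box_edge <= 0):
            raise TopologyError("periodic system requires positive box_edge")

    def _assign_donors_acceptors(self) -> None:
        n_or_o = (self.elements == "N") | (self.elements == "O")
        self.is_acceptor = np.array(n_or_o, dtype=bool)
        has_h = np.zeros(self.n_atoms, dtype=bool)
        parents = self.h_parent[self.h_parent >= 0]
        has_h[parents] = True
        self.is_donor_heavy = n_or_o & has_h

    # -- basic queries --------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_species)

    @property
    def atom_ids(self) -> np.ndarray:
        """1-based contiguous ids."""
        return np.arange(1, self.n_atoms + 1)

    @property
    def species_per_atom(self) -> np.ndarray:
        return np.asarray(
            [self.molecule_species[m] for m in self.molecule_index], dtype=object
        )

    def bonded_hydrogens_of(self, index: int) -> np.ndarray:
        """0-based indices of hydrogens bonded to heavy atom ``index``."""
        return np.flatnonzero(self.h_parent == index)

    def atom(self, index: int) -> AtomRecord:
        """Materialise atom at 0-based ``index``."""
        return AtomRecord(
            atom_id=index + 1,
            name=str(self.names[index]),
            element=str(self.elements[index]),
            residue_id=int(self.residue_ids[index]),
            residue_name=str(self.residue_names[index]),
            chain_id=str(self.chain_ids[index]),
            domain_label=str(self.domain_labels[index]),
            position=self.positions[index].copy(),
            vdw_radius=float(self.vdw_radii[index]),
            mass=float(self.masses[index]),
            is_donor_heavy=bool(self.is_donor_heavy[index]),
            is_acceptor=bool(self.is_acceptor[index]),
            bonded_hydrogens=[int(i) + 1 for i in self.bonded_hydrogens_of(index)],
        )

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield self.atom(i)

    def molecule_atoms(self, molecule: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_index == molecule)

    def molecules_of_species(self, species: str) -> np.ndarray:
        return np.flatnonzero(
            np.asarray(self.molecule_species, dtype=object) == species
        )

    def protein_molecule(self) -> int:
        prot = self.molecules_of_species("protein")
        if len(prot) != 1:
            raise TopologyError(
                f"surface analyses need exactly one protein molecule, found {len(prot)}"
            )
        return int(prot[0])

    def protein_heavy_indices(self) -> np.ndarray:
        mol = self.protein_molecule()
        mask = (self.molecule_index == mol) & (self.elements != "H")
        return np.flatnonzero(mask)

    def residue_index_table(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_id) pairs of the protein."""
        mol = self.protein_molecule()
        seen: dict[tuple[str, int], None] = {}
        for i in np.flatnonzero(self.molecule_index == mol):
            seen.setdefault((str(self.chain_ids[i]), int(self.residue_ids[i])), None)
        return list(seen)


@dataclass
class ConformationEnsemble:
    """Ordered frames of one system (one simulation replica)."""

    system: MolecularSystem
    frames: np.ndarray                # (n_frames, n_atoms, 3), nm
    times: np.ndarray                 # ps, strictly increasing
    replica_id: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.system.n_atoms, 3):
            raise TopologyError(
                f"frame shape {self.frames.shape} does not match topology "
                f"({self.system.n_atoms} atoms)"
            )
        if self.frames.shape[0] < 1:
            raise TopologyError("ensemble needs at least one frame")
        if len(self.times) != self.frames.shape[0]:
            raise TopologyError("times length differs from frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TopologyError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def window(self, fraction: float) -> np.ndarray:
        """Frame indices of the trailing analysis window (e.g. 2/3 → last two
        thirds of frames, the usual equilibrated-production portion)."""
        if not 0 < fraction <= 1:
            raise ValueError("window fraction must be in (0, 1]")
        start = self.n_frames - max(1, int(round(self.n_frames * fraction)))
        return np.arange(start, self.n_frames)


@dataclass(frozen=True)
class Selection:
    """An ordered set of atoms of one system."""

    indices: np.ndarray               # 0-based, sorted unique
    description: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "indices", idx)

    @property
    def atom_ids(self) -> np.ndarray:
        return self.indices + 1

    def __len__(self) -> int:
        return len(self.indices)

    def require_atoms(self) -> "Selection":
        if len(self) == 0:
            raise EmptySelectionError(f"selection {self.description!r} is empty")
        return self


def minimum_image(delta: np.ndarray, box_edge: float | None) -> np.ndarray:
    """Apply the cubic minimum-image convention to displacement vectors."""
    if box_edge is None:
        return delta
    return delta - box_edge * np.round(delta / box_edge)


def pair_distance(a: np.ndarray, b: np.ndarray, box_edge: float | None) -> np.ndarray:
    d = minimum_image(np.asarray(b) - np.asarray(a), box_edge)
    return np.linalg.norm(d, axis=-1)
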