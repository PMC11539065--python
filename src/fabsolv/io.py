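"""Read/write structures, trajectories and assay tables.

MDAnalysis is the reader/writer adapter for PDB, XTC, DCD and TRR; this module
maps its universes into the package's :class:`~fabsolv.model.MolecularSystem` /
:class:`~fabsolv.model.ConformationEnsemble` data model (nm, ps) and performs
the species / donor / acceptor annotation the analyses need.
"""
from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import (
    ConformationEnsemble,
    MolecularSystem,
    ParseError,
    ClassificationError,
    TopologyError,
)

A_PER_NM = 10.0

_WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "H2O"}
_ION_RESNAMES = {"NA", "CL", "SOD", "CLA", "K", "MG", "ZN", "CA2"}
_CITRATE_RESNAMES = {"CIT", "CIT3"}
_OTHER_RESNAMES = {"UNK", "UNL", "LIG", "MOL"}
_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH",
}
#: maximum H–heavy distance treated as a covalent bond, nm
_H_BOND_LENGTH_NM = 0.135


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _element_from_name(name: str, resname: str) -> str:
    if resname.strip().upper() in _ION_RESNAMES:
        return resname.strip().upper()
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if stripped[0].upper() == "H":
        return "H"
    if stripped[:2].upper() in ("CL", "NA", "MG", "ZN") and len(name.strip()) <= 2:
        return stripped[:2].upper()
    return stripped[0].upper()


def _prescan_pdb(path: Path) -> list[str]:
    """Validate ATOM/HETATM records of the first model; return element symbols.

    Raises :class:`ParseError` naming the offending line.
    """
    elements: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}: truncated {rec} record at line {lineno}")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise ParseError(
                    f"{path}: malformed coordinate field at line {lineno}"
                ) from None
            elem = line[76:78].strip() if len(line) >= 78 else ""
            elements.append(elem.upper() or _element_from_name(line[12:16], line[17:21]))
    return elements


def _classify_residues(
    resnames: list[str],
    chain_of_res: list[str],
    overrides: dict[str, str] | None,
) -> list[str]:
    """Species per residue.  A GLY residue counts as protein when its chain
    holds other amino-acid residues, and as the free glycine excipient when it
    stands alone."""
    overrides = {k.upper(): v for k, v in (overrides or {}).items()}
    chains_with_protein = set()
    for rn, ch in zip(resnames, chain_of_res):
        if rn.upper() in _STANDARD_AA and rn.upper() != "GLY":
            chains_with_protein.add(ch)
    species = []
    for rn, ch in zip(resnames, chain_of_res):
        rn_u = rn.upper()
        if rn_u in overrides:
            species.append(overrides[rn_u])
        elif rn_u in _WATER_RESNAMES:
            species.append("water")
        elif rn_u in _CITRATE_RESNAMES:
            species.append("citrate")
        elif rn_u in _ION_RESNAMES:
            species.append("ion")
        elif rn_u in _OTHER_RESNAMES:
            species.append("other")
        elif rn_u == "GLY":
            species.append("protein" if ch in chains_with_protein else "glycine")
        elif rn_u in _STANDARD_AA:
            species.append("protein")
        else:
            raise ClassificationError(
                f"residue name {rn!r} not classifiable; supply a species override"
            )
    return species


def _guess_h_parents(elements: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Attach each hydrogen to its nearest heavy atom within bond range."""
    n = len(elements)
    h_parent = np.full(n, -1, dtype=np.int64)
    heavy = np.flatnonzero(elements != "H")
    hydrogens = np.flatnonzero(elements == "H")
    if len(heavy) == 0 or len(hydrogens) == 0:
        return h_parent
    tree = cKDTree(positions[heavy])
    dist, nearest = tree.query(positions[hydrogens], k=1)
    ok = dist <= _H_BOND_LENGTH_NM
    h_parent[hydrogens[ok]] = heavy[nearest[ok]]
    return h_parent


def load_structure(
    path: str | Path,
    format: str = "PDB",
    *,
    species_overrides: dict[str, str] | None = None,
    box_edge: float | None = None,
    periodic: bool | None = None,
) -> MolecularSystem:
    """Read a PDB file (first model) into a :class:`MolecularSystem`.

    Coordinates are converted Å→nm.  Species are inferred from residue names
    (HOH/WAT/SOL→water, free GLY→glycine, CIT→citrate, NA/CL→ion, standard
    amino acids→protein); anything else needs ``species_overrides``.
    """
    path = Path(path)
    if format.upper() != "PDB":
        raise ValueError(f"unsupported structure format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    elements = _prescan_pdb(path)
    if not elements:
        raise ParseError(f"{path}: no ATOM/HETATM records found")

    mda = _import_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    ag = u.atoms
    if len(ag) != len(elements):
        # e.g. duplicate models without MODEL records; trust the universe
        elements = [
            _element_from_name(nm, rn)
            for nm, rn in zip(ag.names, ag.resnames)
        ]
    names = [str(n) for n in ag.names]
    resnames = [str(r) for r in ag.resnames]
    resids = np.asarray(ag.resids, dtype=np.int64)
    if hasattr(ag, "chainIDs"):
        chains = [str(c) for c in ag.chainIDs]
    else:
        chains = [str(s) for s in ag.segids]
    positions = np.asarray(ag.positions, dtype=float) / A_PER_NM

    # group into residues in file order
    res_keys: list[tuple] = []
    res_of_atom = np.empty(len(names), dtype=np.int64)
    seen: dict[tuple, int] = {}
    for i in range(len(names)):
        key = (chains[i], int(resids[i]), resnames[i])
        if key not in seen:
            seen[key] = len(res_keys)
            res_keys.append(key)
        res_of_atom[i] = seen[key]
    res_chain = [k[0] for k in res_keys]
    res_name = [k[2] for k in res_keys]
    res_species = _classify_residues(res_name, res_chain, species_overrides)

    # molecules: all protein residues merge into one molecule; every other
    # residue is its own molecule
    molecule_species: list[str] = []
    mol_of_res = np.empty(len(res_keys), dtype=np.int64)
    protein_mol = -1
    for r, sp in enumerate(res_species):
        if sp == "protein":
            if protein_mol < 0:
                protein_mol = len(molecule_species)
                molecule_species.append("protein")
            mol_of_res[r] = protein_mol
        else:
            mol_of_res[r] = len(molecule_species)
            molecule_species.append(sp)
    molecule_index = mol_of_res[res_of_atom]

    elements_arr = np.asarray([e.upper() for e in elements], dtype=object)
    if box_edge is None:
        dims = u.dimensions
        if dims is not None and dims[0] > 0:
            box_edge = float(dims[0]) / A_PER_NM
    return MolecularSystem(
        names=names,
        elements=list(elements_arr),
        residue_ids=resids,
        residue_names=resnames,
        chain_ids=chains,
        positions=positions,
        molecule_index=molecule_index,
        molecule_species=molecule_species,
        h_parent=_guess_h_parents(elements_arr, positions),
        box_edge=box_edge,
        periodic=bool(periodic) if periodic is not None else box_edge is not None,
        provenance={"source": str(path)},
    )


_TRAJ_FORMATS = {"XTC", "DCD", "TRR", "PDB"}


def load_trajectory(
    system: MolecularSystem,
    path: str | Path,
    format: str | None = None,
    *,
    stride_ps: float = 10.0,
    replica_id: int = 0,
) -> ConformationEnsemble:
    """Read a coordinate trajectory (XTC/DCD/TRR or multi-model PDB) onto an
    existing topology.  Times come from the file when present, otherwise they
    are synthesised as ``frame_index × stride_ps``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in _TRAJ_FORMATS:
        raise ValueError(f"unsupported trajectory format {fmt!r}")

    mda = _import_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(system.n_atoms, trajectory=True)
        try:
            u.load_new(str(path), format=fmt)
        except (ValueError, OSError, IndexError) as exc:
            raise TopologyError(
                f"{path}: trajectory does not match topology "
                f"({system.n_atoms} atoms): {exc}"
            ) from exc
        frames = []
        times = []
        for ts in u.trajectory:
            if ts.positions.shape[0] != system.n_atoms:
                raise TopologyError(
                    f"{path}: frame has {ts.positions.shape[0]} atoms, "
                    f"topology has {system.n_atoms}"
                )
            frames.append(ts.positions.copy() / A_PER_NM)
            times.append(float(ts.time) if ts.time is not None else np.nan)
    if not frames:
        raise TopologyError(f"{path}: trajectory contains zero frames")
    times_arr = np.asarray(times)
    if (fmt == "PDB" or np.any(~np.isfinite(times_arr))
            or (len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0))):
        times_arr = np.arange(len(frames)) * stride_ps
    return ConformationEnsemble(
        system=system,
        frames=np.stack(frames),
        times=times_arr,
        replica_id=replica_id,
        provenance={"source": str(path), "format": fmt},
    )


def _universe_from_system(system: MolecularSystem, frames_nm: np.ndarray):
    mda = _import_mda()
    from MDAnalysis.coordinates.memory import MemoryReader

    res_keys: list[tuple] = []
    res_of_atom = np.empty(system.n_atoms, dtype=np.int64)
    seen: dict[tuple, int] = {}
    for i in range(system.n_atoms):
        key = (str(system.chain_ids[i]), int(system.residue_ids[i]),
               str(system.residue_names[i]))
        if key not in seen:
            seen[key] = len(res_keys)
            res_keys.append(key)
        res_of_atom[i] = seen[key]
    n_res = len(res_keys)
    chains_of_res = [k[0] for k in res_keys]
    uniq_chains = sorted(set(chains_of_res))
    seg_of_res = np.asarray([uniq_chains.index(c) for c in chains_of_res])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            system.n_atoms,
            n_residues=n_res,
            n_segments=len(uniq_chains),
            atom_resindex=res_of_atom,
            residue_segindex=seg_of_res,
            trajectory=False,
        )
        u.add_TopologyAttr("names", [str(n) for n in system.names])
        u.add_TopologyAttr("elements", [str(e) for e in system.elements])
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("segids", uniq_chains)
        u.add_TopologyAttr("chainIDs", [chains_of_res[r] for r in res_of_atom])
        u.add_TopologyAttr("occupancies", np.ones(system.n_atoms))
        u.add_TopologyAttr("tempfactors", np.zeros(system.n_atoms))
        coords = np.asarray(frames_nm, dtype=np.float32) * A_PER_NM
        dims = None
        if system.box_edge:
            edge = system.box_edge * A_PER_NM
            dims = np.tile([edge, edge, edge, 90, 90, 90], (len(coords), 1))
        u.load_new(coords, format=MemoryReader, dimensions=dims)
    return u


def write_pdb(
    system: MolecularSystem,
    path: str | Path,
    *,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write the system's reference coordinates as a single-model PDB; an
    optional per-atom array fills the B-factor column (for structure
    colouring by e.g. contact frequency or ΔRMSF)."""
    u = _universe_from_system(system, system.positions[None, :, :])
    if bfactors is not None:
        u.atoms.tempfactors = np.asarray(bfactors, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(ensemble: ConformationEnsemble, path: str | Path) -> None:
    """Write all frames to a multi-model PDB or XTC/DCD/TRR file (format from
    the extension)."""
    path = Path(path)
    u = _universe_from_system(ensemble.system, ensemble.frames)
    mda = _import_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(
            str(path), n_atoms=ensemble.system.n_atoms, multiframe=True
        ) as w:
            for ts in u.trajectory:
                ts.time = ensemble.times[ts.frame]
                w.write(u.atoms)


def per_residue_bfactors(system: MolecularSystem, values: dict[int, float]) -> np.ndarray:
    """Expand a residue_id → value map to a per-atom B-factor array."""
    out = np.zeros(system.n_atoms)
    for i in range(system.n_atoms):
        out[i] = values.get(int(system.residue_ids[i]), 0.0)
    return out


# -- domain annotation --------------------------------------------------------

def load_domain_annotation(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a domain annotation CSV with header chain,res_start,res_end,label."""
    rows: list[tuple[str, int, int, str]] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                (rec["chain"], int(rec["res_start"]), int(rec["res_end"]),
                 rec["label"])
            )
    return rows


def apply_domains(
    system: MolecularSystem, table: list[tuple[str, int, int, str]]
) -> None:
    """Label protein atoms with Fab domains (VH/VL/CH1/CL/other) in place."""
    for chain, start, end, label in table:
        mask = (
            (np.asarray(system.chain_ids, dtype=object) == chain)
            & (system.residue_ids >= start)
            & (system.residue_ids <= end)
        )
        system.domain_labels[mask] = label


# -- assay tables -------------------------------------------------------------

def read_melt_csv(path: str | Path) -> pd.DataFrame:
    """Read a melting table: long format (temperature, wavelength, intensity)
    or (temperature, bcm); temperatures in °C or K are accepted as-is — the
    thermal_unfolding module normalises units."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "temperature" not in cols:
        raise ParseError(f"{path}: melting CSV needs a 'temperature' column")
    if not ({"wavelength", "intensity"} <= set(cols) or "bcm" in cols):
        raise ParseError(
            f"{path}: melting CSV needs (wavelength, intensity) or bcm columns"
        )
    return df.rename(columns=str.lower)


def read_kinetics_csv(path: str | Path) -> pd.DataFrame:
    """Read monomer-loss CSV: time_days, monomer_percent[, replicate]."""
    df = pd.read_csv(path)
    df = df.rename(columns=str.lower)
    if not {"time_days", "monomer_percent"} <= set(df.columns):
        raise ParseError(
            f"{path}: kinetics CSV needs time_days and monomer_percent columns"
        )
    return df
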