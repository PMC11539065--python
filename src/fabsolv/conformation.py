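"""Superposition, RMSD/RMSF, ΔRMSF, radius of gyration, SASA and Cα PCA.

All geometric measures are computed after least-squares rigid-body
superposition (Kabsch, proper rotation) and are therefore invariant under
rigid motion of the input coordinates.  Statistics over replicas follow the
per-replica-profile-then-average convention with SEM across replicas.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .model import (
    ConformationEnsemble,
    EmptySelectionError,
    MolecularSystem,
    Selection,
)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    rotation: np.ndarray                # (3,3), proper orthonormal
    translation: np.ndarray             # (3,), nm
    rmsd: float                         # nm, on the fit selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal least-squares rigid transform (Kabsch SVD, det=+1) mapping
    ``mobile`` onto ``reference``; RMSD is evaluated on the fit atoms after
    the transform.  Raises on degenerate (collinear) fit sets."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(len(mobile))
    fit_indices = np.asarray(fit_indices)
    if len(fit_indices) < 3:
        raise ValueError("need at least 3 fit atoms")
    P = mobile[fit_indices]
    Q = reference[fit_indices]
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    com_p = w @ P
    com_q = w @ Q
    Pc = P - com_p
    Qc = Q - com_q
    C = (Pc * w[:, None]).T @ Qc
    U, S, Vt = np.linalg.svd(C)
    if S[1] < 1e-12 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = com_q - R @ com_p
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.sum(w[:, None] * diff ** 2)))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd_series(
    ensemble: ConformationEnsemble,
    reference: np.ndarray,
    fit_selection: Selection,
    measure_selection: Selection | None = None,
) -> pd.DataFrame:
    """Per-frame superposition on the fit selection, RMSD on the measure
    selection (defaults to the fit selection); the simulation-convergence
    diagnostic."""
    fit_selection.require_atoms()
    measure = measure_selection or fit_selection
    measure.require_atoms()
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        res = superpose(ensemble.frames[f], reference, fit_selection.indices)
        moved = res.apply(ensemble.frames[f])
        diff = moved[measure.indices] - reference[measure.indices]
        out[f] = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return pd.DataFrame({"time_ps": ensemble.times, "rmsd_nm": out})


# ---------------------------------------------------------------------------
# RMSF / ΔRMSF
# ---------------------------------------------------------------------------


@dataclass
class FlexibilityProfile:
    residue_ids: np.ndarray
    rmsf: np.ndarray                    # nm, per residue
    atom_subset: str = "all"
    window_fraction: float = 2 / 3
    per_atom: pd.DataFrame | None = None
    sem: np.ndarray | None = None       # across replicas, when averaged

    @property
    def global_mean(self) -> float:
        return float(np.mean(self.rmsf))


def _aligned_window_coords(
    ensemble: ConformationEnsemble,
    fit_indices: np.ndarray,
    window_fraction: float,
) -> np.ndarray:
    """Frames of the trailing window superposed onto their mean structure
    (two-pass: align to first frame, re-align to the running mean)."""
    frames = ensemble.window(window_fraction)
    coords = ensemble.frames[frames].copy()
    ref = coords[0]
    for _ in range(2):
        for i in range(len(coords)):
            res = superpose(coords[i], ref, fit_indices)
            coords[i] = res.apply(coords[i])
        ref = coords.mean(axis=0)
    return coords


def rmsf(
    ensemble: ConformationEnsemble,
    selection: Selection,
    *,
    window_fraction: float = 2 / 3,
    atom_subset: str = "all",
    fit_selection: Selection | None = None,
) -> FlexibilityProfile:
    """Per-residue RMSF about the window-mean position after superposition;
    the residue value is the mass-weighted mean over its selected atoms."""
    selection.require_atoms()
    system = ensemble.system
    if len(ensemble.window(window_fraction)) < 2:
        raise ValueError("RMSF needs at least 2 frames in the window")
    fit_idx = (fit_selection or selection).indices
    coords = _aligned_window_coords(ensemble, fit_idx, window_fraction)
    sel = selection.indices
    mean = coords[:, sel].mean(axis=0)
    dev2 = np.mean(np.sum((coords[:, sel] - mean) ** 2, axis=2), axis=0)
    per_atom_rmsf = np.sqrt(dev2)

    resids = system.residue_ids[sel]
    masses = system.masses[sel]
    table = pd.DataFrame({
        "atom_index": sel,
        "residue_id": resids,
        "mass": masses,
        "rmsf_nm": per_atom_rmsf,
    })
    grouped = table.groupby("residue_id").apply(
        lambda g: np.average(g["rmsf_nm"], weights=g["mass"]),
        include_groups=False,
    )
    return FlexibilityProfile(
        residue_ids=grouped.index.to_numpy(),
        rmsf=grouped.to_numpy(),
        atom_subset=atom_subset,
        window_fraction=window_fraction,
        per_atom=table,
    )


def average_profiles(profiles: list[FlexibilityProfile]) -> FlexibilityProfile:
    """Replica-average profile with SEM across replicas."""
    ref_ids = profiles[0].residue_ids
    for p in profiles[1:]:
        if not np.array_equal(p.residue_ids, ref_ids):
            raise ValueError("replica profiles cover different residues")
    stack = np.stack([p.rmsf for p in profiles])
    sem = (stack.std(axis=0, ddof=1) / np.sqrt(len(profiles))
           if len(profiles) > 1 else np.full(len(ref_ids), np.nan))
    return FlexibilityProfile(
        residue_ids=ref_ids,
        rmsf=stack.mean(axis=0),
        atom_subset=profiles[0].atom_subset,
        window_fraction=profiles[0].window_fraction,
        sem=sem,
    )


@dataclass
class DeltaRMSF:
    per_residue_percent: np.ndarray     # NaN where the reference RMSF is 0
    global_percent: float
    residue_ids: np.ndarray
    mode: str


def delta_rmsf(
    profile: FlexibilityProfile,
    reference: FlexibilityProfile,
    mode: str = "percent_of_global_mean",
) -> DeltaRMSF:
    """ΔRMSF(%) = 100·(RMSF − RMSF_ref)/RMSF_ref per residue.

    The global value is, by default, the percent change of the global-average
    RMSF; ``mode='mean_of_percent'`` averages the per-residue percent changes
    instead.  Residues with zero reference RMSF are flagged undefined and
    excluded from the global value with a warning.
    """
    if not np.array_equal(profile.residue_ids, reference.residue_ids):
        raise ValueError("profiles cover different residue sets")
    ref = reference.rmsf
    cur = profile.rmsf
    zero = ref <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} residue(s) with zero reference RMSF excluded",
            stacklevel=2,
        )
    per_res = np.full(len(ref), np.nan)
    per_res[~zero] = 100.0 * (cur[~zero] - ref[~zero]) / ref[~zero]
    if mode == "percent_of_global_mean":
        g_ref = float(np.mean(ref[~zero]))
        g_cur = float(np.mean(cur[~zero]))
        global_pct = 100.0 * (g_cur - g_ref) / g_ref
    elif mode == "mean_of_percent":
        global_pct = float(np.nanmean(per_res))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DeltaRMSF(
        per_residue_percent=per_res,
        global_percent=global_pct,
        residue_ids=profile.residue_ids,
        mode=mode,
    )


def delta_rmsf_by_group(
    profile: FlexibilityProfile,
    reference: FlexibilityProfile,
    groups: dict[str, np.ndarray],
) -> dict[str, float]:
    """Percent change of the group-average RMSF for residue groups (domain
    labels, exposed/buried classes ...); masks index the profile residues."""
    out = {}
    for name, mask in groups.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            out[name] = float("nan")
            continue
        g_ref = float(np.mean(reference.rmsf[mask]))
        g_cur = float(np.mean(profile.rmsf[mask]))
        out[name] = 100.0 * (g_cur - g_ref) / g_ref if g_ref > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# radius of gyration, SASA
# ---------------------------------------------------------------------------


def radius_of_gyration(
    coords: np.ndarray,
    masses: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> float:
    """√(Σ mᵢ|rᵢ−r_com|²/Σ mᵢ); unit masses when not mass-weighted."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 0:
        raise EmptySelectionError("radius of gyration of an empty selection")
    if not mass_weighted or masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    com = np.average(coords, axis=0, weights=masses)
    return float(np.sqrt(np.average(
        np.sum((coords - com) ** 2, axis=1), weights=masses
    )))


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


@dataclass
class SASAResult:
    per_atom: np.ndarray                # nm², aligned with the selection
    total: float                        # nm²
    probe_radius: float
    n_sphere_points: int
    atom_indices: np.ndarray


def sasa(
    system: MolecularSystem,
    coords: np.ndarray,
    selection: Selection | None = None,
    probe_radius: float = 0.14,
    n_points: int = 960,
) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area with a deterministic
    point set (default 960 points/atom, 0.14 nm probe)."""
    coords = np.asarray(coords, dtype=float)
    idx = selection.indices if selection is not None else np.arange(system.n_atoms)
    if len(idx) == 0:
        raise EmptySelectionError("SASA of an empty selection")
    radii = system.vdw_radii[idx]
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = idx[np.flatnonzero(~np.isfinite(radii) | (radii <= 0))[0]]
        raise ValueError(f"atom id {bad + 1} has no usable vdW radius")
    pts = sphere_points(n_points)
    pos = coords[idx]
    ext = radii + probe_radius
    tree = cKDTree(pos)
    max_ext = ext.max()
    areas = np.empty(len(idx))
    for i in range(len(idx)):
        r_i = ext[i]
        neighbours = tree.query_ball_point(pos[i], r_i + max_ext)
        neighbours = [j for j in neighbours if j != i]
        surface = pos[i] + r_i * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = surface - pos[j]
            accessible &= np.einsum("ij,ij->i", d, d) > ext[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * r_i ** 2 * accessible.mean()
    return SASAResult(
        per_atom=areas,
        total=float(areas.sum()),
        probe_radius=probe_radius,
        n_sphere_points=n_points,
        atom_indices=idx,
    )


def residue_relative_sasa(
    system: MolecularSystem,
    coords: np.ndarray,
    probe_radius: float = 0.14,
    n_points: int = 960,
) -> pd.Series:
    """Per-residue SASA in context divided by the same residue's SASA in
    isolation (its maximal reference area)."""
    prot = system.protein_heavy_indices()
    mol = system.protein_molecule()
    prot_all = np.flatnonzero(system.molecule_index == mol)
    full = sasa(system, coords, Selection(indices=prot_all, description="protein"),
                probe_radius, n_points)
    area_of = dict(zip(full.atom_indices, full.per_atom))
    out = {}
    for rid in np.unique(system.residue_ids[prot_all]):
        res_idx = prot_all[system.residue_ids[prot_all] == rid]
        iso = sasa(system, coords, Selection(indices=res_idx, description=f"res {rid}"),
                   probe_radius, n_points)
        in_context = sum(area_of[i] for i in res_idx)
        out[int(rid)] = in_context / iso.total if iso.total > 0 else np.nan
    return pd.Series(out, name="relative_sasa")


def classify_exposure(
    system: MolecularSystem,
    coords: np.ndarray,
    threshold: float = 0.25,
    **kwargs,
) -> pd.Series:
    """Exposed (True) vs buried residues by relative SASA ≥ threshold."""
    rel = residue_relative_sasa(system, coords, **kwargs)
    return rel >= threshold


# ---------------------------------------------------------------------------
# Cα principal component analysis
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    eigenvalues: np.ndarray             # nm², descending
    variance_fractions: np.ndarray
    components: np.ndarray              # (3N, n_modes), columns = modes
    mean_structure: np.ndarray          # (N, 3)
    projections: np.ndarray             # (n_frames, n_modes)
    residue_ids: np.ndarray
    total_variance: float = 0.0         # trace of the Cα covariance, nm²


class CalphaPCA(BaseEstimator):
    """Essential-dynamics PCA of Cα coordinates across concatenated replicas.

    ``fit`` concatenates the ensembles, iteratively superposes all frames on
    the Cα mean structure, and eigendecomposes the coordinate covariance.
    Fitted attributes: ``eigenvalues_``, ``variance_fractions_``,
    ``components_``, ``mean_structure_``, ``projections_``.
    """

    def __init__(self, max_iter: int = 20, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, ensembles: list[ConformationEnsemble]):
        if not ensembles:
            raise ValueError("need at least one ensemble")
        system = ensembles[0].system
        n_atoms = system.n_atoms
        for e in ensembles[1:]:
            if e.system.n_atoms != n_atoms:
                raise ValueError("ensembles do not share a topology")
        prot = system.protein_molecule()
        ca = np.flatnonzero(
            (system.molecule_index == prot) & (system.names == "CA")
        )
        if len(ca) < 3:
            raise ValueError("need at least 3 Cα atoms")
        X = np.concatenate([e.frames[:, ca, :] for e in ensembles], axis=0)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 total frames")

        ref = X[0]
        for _ in range(self.max_iter):
            for i in range(len(X)):
                X[i] = superpose(X[i], ref).apply(X[i])
            mean = X.mean(axis=0)
            if np.sqrt(np.mean((mean - ref) ** 2)) < self.tol:
                ref = mean
                break
            ref = mean

        flat = X.reshape(len(X), -1) - ref.ravel()
        cov = flat.T @ flat / (len(X) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        total = evals.sum()
        self.total_variance_ = float(np.trace(cov))
        self.eigenvalues_ = evals
        self.variance_fractions_ = (evals / total if total > 0
                                    else np.zeros_like(evals))
        self.components_ = evecs
        self.mean_structure_ = ref
        self.projections_ = flat @ evecs
        self._ca_indices_ = ca
        self._residue_ids_ = system.residue_ids[ca]
        return self

    def transform(self, ensemble: ConformationEnsemble) -> np.ndarray:
        X = ensemble.frames[:, self._ca_indices_, :].copy()
        for i in range(len(X)):
            X[i] = superpose(X[i], self.mean_structure_).apply(X[i])
        flat = X.reshape(len(X), -1) - self.mean_structure_.ravel()
        return flat @ self.components_


def pca_calpha(ensembles: list[ConformationEnsemble]) -> PCAResult:
    """Concatenate simulation replicas and extract the major Cα motions."""
    model = CalphaPCA().fit(ensembles)
    return PCAResult(
        eigenvalues=model.eigenvalues_,
        variance_fractions=model.variance_fractions_,
        components=model.components_,
        mean_structure=model.mean_structure_,
        projections=model.projections_,
        residue_ids=model._residue_ids_,
        total_variance=model.total_variance_,
    )
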