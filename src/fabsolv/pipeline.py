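"""Config-driven orchestration of the full analysis surface.

A TOML config defines a condition series (e.g. a glycine titration against a
citrate-only reference), pointing each condition at its structure, surface
and flexibility trajectories, and assay CSVs.  The three runners reproduce
the study's analysis layers per condition:

* surface:      Γ23, H-bond class counts, shell occupancy, displacement
                percentages vs the reference, contact maps, cluster fractions
* flexibility:  RMSD convergence, RMSF and ΔRMSF vs the reference, Cα PCA
* assay:        two-state melt fits (Tm, ΔHvh, ΔSvh) and first-order
                kinetics (ln v) tables

All outputs are CSV plus a provenance JSON (config hash, seed, version);
re-running an identical config reproduces them bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import conformation as conf
from . import hbonds as hb
from . import io as fio
from . import kinetics as kin
from . import melt as melt_mod
from . import preferential as pref
from .model import ConformationEnsemble
from .selection import select

log = logging.getLogger("fabsolv.pipeline")


@dataclass
class ConditionConfig:
    label: str
    structure: Path | None = None
    surface_trajectories: list[Path] = field(default_factory=list)
    flex_structure: Path | None = None
    flex_trajectories: list[Path] = field(default_factory=list)
    melt_csv: Path | None = None
    kinetics_csv: Path | None = None


@dataclass
class RunConfig:
    conditions: list[ConditionConfig]
    reference: str
    window_fraction: float = 2 / 3
    hb_distance: float = 0.35
    hb_angle: float = 30.0
    local_cutoff: float = 0.6
    shell_boundaries: tuple[float, float] = (0.35, 0.6)
    probe_radius: float = 0.14
    seed: int = 0
    outdir: Path = Path("fabsolv_out")
    config_hash: str = ""

    def validate(self) -> None:
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")
        for c in (self.hb_distance, self.hb_angle, self.local_cutoff,
                  self.probe_radius):
            if c <= 0:
                raise ValueError("cutoffs must be positive")
        labels = [c.label for c in self.conditions]
        if self.reference not in labels:
            raise ValueError(f"reference {self.reference!r} not among conditions")
        for c in self.conditions:
            for p in ([c.structure, c.flex_structure, c.melt_csv, c.kinetics_csv]
                      + c.surface_trajectories + c.flex_trajectories):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"condition {c.label}: missing {p}")

    def criteria(self) -> hb.HBondCriteria:
        return hb.HBondCriteria(
            distance_cutoff=self.hb_distance, angle_cutoff=self.hb_angle
        )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = path.read_bytes()
    data = tomllib.loads(raw.decode())
    base = path.parent

    def _p(v):
        return base / v if v is not None else None

    conditions = []
    for label, c in data.get("conditions", {}).items():
        conditions.append(ConditionConfig(
            label=label,
            structure=_p(c.get("structure")),
            surface_trajectories=[_p(v) for v in c.get("surface_trajectories", [])],
            flex_structure=_p(c.get("flex_structure")),
            flex_trajectories=[_p(v) for v in c.get("flex_trajectories", [])],
            melt_csv=_p(c.get("melt_csv")),
            kinetics_csv=_p(c.get("kinetics_csv")),
        ))
    cfg = RunConfig(
        conditions=conditions,
        reference=data.get("reference", conditions[0].label if conditions else ""),
        window_fraction=float(data.get("window_fraction", 2 / 3)),
        hb_distance=float(data.get("hb_distance", 0.35)),
        hb_angle=float(data.get("hb_angle", 30.0)),
        local_cutoff=float(data.get("local_cutoff", 0.6)),
        probe_radius=float(data.get("probe_radius", 0.14)),
        seed=int(data.get("seed", 0)),
        outdir=Path(data.get("outdir", base / "fabsolv_out")),
        config_hash=hashlib.sha256(raw).hexdigest()[:16],
    )
    if "shells" in data:
        cfg.shell_boundaries = tuple(float(v) for v in data["shells"])
    return cfg


def _write_provenance(cfg: RunConfig, stage: str, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "stage": stage,
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "window_fraction": cfg.window_fraction,
        "cutoffs": {
            "hb_distance_nm": cfg.hb_distance,
            "hb_angle_deg": cfg.hb_angle,
            "local_cutoff_nm": cfg.local_cutoff,
            "shells_nm": list(cfg.shell_boundaries),
            "probe_radius_nm": cfg.probe_radius,
        },
        "version": __version__,
    }
    (outdir / f"{stage}_provenance.json").write_text(json.dumps(meta, indent=2))


def _load_surface_replicas(c: ConditionConfig) -> list[ConformationEnsemble]:
    system = fio.load_structure(c.structure)
    out = []
    for rep, path in enumerate(c.surface_trajectories):
        out.append(fio.load_trajectory(system, path, replica_id=rep))
    return out


def run_surface_analysis(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Per-condition Γ23, H-bond class counts, hydration-shell occupancy
    (reference-relative displacement percentages) and contact maps."""
    cfg.validate()
    outdir = Path(cfg.outdir) / "surface"
    outdir.mkdir(parents=True, exist_ok=True)
    criteria = cfg.criteria()
    gamma_rows, shell_rows, count_rows, cluster_rows = [], [], [], []
    contact_tables = {}
    for c in cfg.conditions:
        if not c.surface_trajectories:
            log.warning("condition %s: no surface trajectories, skipped", c.label)
            continue
        replicas = _load_surface_replicas(c)
        system = replicas[0].system
        donors = select(system, "all")
        acceptors = select(system, "all")
        has_gly = len(system.molecules_of_species("glycine")) > 0
        per_rep_gamma, per_rep_counts = [], []
        for ens in replicas:
            if has_gly:
                g = pref.gamma23(
                    ens, "glycine", "water", cfg.local_cutoff,
                    window_fraction=cfg.window_fraction, seed=cfg.seed,
                )
                per_rep_gamma.append(g)
            records, frames = hb.detect_hbonds_ensemble(
                ens, donors, acceptors, criteria,
                exclude_same_molecule=True,
                window_fraction=cfg.window_fraction,
            )
            per_rep_counts.append(hb.count_hbonds_by_class(
                records,
                ["protein-glycine", "protein-citrate", "protein-water",
                 "glycine-glycine"],
                frames,
            ))
            if has_gly:
                gg = [r for r in records
                      if tuple(sorted(r.partner_classes)) == ("glycine", "glycine")]
                cl = hb.classify_clusters(
                    gg, len(system.molecules_of_species("glycine")),
                    system, frames,
                )
                cluster_rows.append({
                    "condition": c.label, "replica": ens.replica_id,
                    "monomer": cl.mean[0], "dimer": cl.mean[1],
                    "nmer": cl.mean[2],
                })
            occ = pref.shell_occupancy(
                ens, "water", cfg.shell_boundaries,
                window_fraction=cfg.window_fraction,
            )
            shell_rows.append({
                "condition": c.label, "replica": ens.replica_id,
                "first_shell": occ.mean_first, "second_shell": occ.mean_second,
                "first_sem": occ.sem_first, "second_sem": occ.sem_second,
            })
        if per_rep_gamma:
            means = np.array([g.gamma23 for g in per_rep_gamma])
            gamma_rows.append({
                "condition": c.label,
                "gamma23": means.mean(),
                "gamma23_integral": float(np.mean(
                    [g.gamma23_integral for g in per_rep_gamma])),
                "sem": (means.std(ddof=1) / np.sqrt(len(means))
                        if len(means) > 1 else per_rep_gamma[0].sem),
                "n_replicas": len(means),
            })
        summary = hb.summarize_counts(per_rep_counts)
        summary["condition"] = c.label
        count_rows.append(summary.reset_index(names="pair"))
        if has_gly:
            cmap = pref.contact_frequency(
                replicas[0], "glycine", cfg.local_cutoff,
                window_fraction=cfg.window_fraction,
            )
            contact_tables[c.label] = cmap.frequencies
            fio.write_pdb(
                system, outdir / f"contacts_{c.label}.pdb",
                bfactors=cmap.to_bfactors(system),
            )

    gamma = pd.DataFrame(gamma_rows)
    shells = pd.DataFrame(shell_rows)
    counts = pd.concat(count_rows, ignore_index=True) if count_rows else pd.DataFrame()
    clusters = pd.DataFrame(cluster_rows)

    # displacement vs the reference condition
    disp_rows = []
    if not shells.empty:
        agg = shells.groupby("condition")[["first_shell", "second_shell"]].mean()
        ref = agg.loc[cfg.reference]
        for label, row in agg.iterrows():
            disp_rows.append({
                "condition": label,
                "first_shell_displacement_pct":
                    pref.displacement_percent(ref.first_shell, row.first_shell).percent,
                "second_shell_displacement_pct":
                    pref.displacement_percent(ref.second_shell, row.second_shell).percent,
            })
    displacement = pd.DataFrame(disp_rows)

    gamma.to_csv(outdir / "gamma23.csv", index=False)
    shells.to_csv(outdir / "shell_occupancy.csv", index=False)
    counts.to_csv(outdir / "hbond_counts.csv", index=False)
    clusters.to_csv(outdir / "cluster_fractions.csv", index=False)
    displacement.to_csv(outdir / "displacement.csv", index=False)
    for label, table in contact_tables.items():
        table.to_csv(outdir / f"contact_frequency_{label}.csv")
    _write_provenance(cfg, "surface", outdir)
    return {
        "gamma23": gamma, "shell_occupancy": shells, "hbond_counts": counts,
        "cluster_fractions": clusters, "displacement": displacement,
        "contacts": contact_tables,
    }


def run_flexibility_analysis(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """RMSD convergence, per-residue RMSF / ΔRMSF vs the reference
    condition, and PCA across concatenated replicas per condition."""
    cfg.validate()
    outdir = Path(cfg.outdir) / "flexibility"
    outdir.mkdir(parents=True, exist_ok=True)
    profiles: dict[str, conf.FlexibilityProfile] = {}
    rmsd_rows, pca_rows = [], []
    for c in cfg.conditions:
        if not c.flex_trajectories:
            log.warning("condition %s: no flexibility trajectories, skipped",
                        c.label)
            continue
        system = fio.load_structure(c.flex_structure or c.structure)
        replicas = [
            fio.load_trajectory(system, p, replica_id=r)
            for r, p in enumerate(c.flex_trajectories)
        ]
        fit_sel = select(system, "backbone")
        per_rep = []
        for ens in replicas:
            if ens.n_frames < 2:
                raise ValueError(
                    f"condition {c.label}: single-frame ensemble cannot "
                    "support flexibility analysis"
                )
            series = conf.rmsd_series(ens, system.positions, fit_sel)
            rmsd_rows.append({
                "condition": c.label, "replica": ens.replica_id,
                "rmsd_min": series.rmsd_nm.min(),
                "rmsd_max": series.rmsd_nm.max(),
            })
            per_rep.append(conf.rmsf(
                ens, select(system, "protein"),
                window_fraction=cfg.window_fraction,
                fit_selection=fit_sel,
            ))
        profiles[c.label] = conf.average_profiles(per_rep)
        pca = conf.pca_calpha(replicas)
        pca_rows.append({
            "condition": c.label,
            "top_eigenvalue_nm2": pca.eigenvalues[0],
            "pc1_variance_fraction": pca.variance_fractions[0],
            "pc123_variance_fraction": float(pca.variance_fractions[:3].sum()),
        })

    ref_profile = profiles.get(cfg.reference)
    delta_rows = []
    for label, prof in profiles.items():
        if ref_profile is None:
            break
        d = conf.delta_rmsf(prof, ref_profile)
        delta_rows.append({
            "condition": label,
            "global_rmsf_nm": prof.global_mean,
            "global_delta_rmsf_pct": d.global_percent,
        })
        pd.DataFrame({
            "residue_id": d.residue_ids,
            "rmsf_nm": prof.rmsf,
            "delta_rmsf_pct": d.per_residue_percent,
        }).to_csv(outdir / f"rmsf_{label}.csv", index=False)
    rmsd = pd.DataFrame(rmsd_rows)
    deltas = pd.DataFrame(delta_rows)
    pca_df = pd.DataFrame(pca_rows)
    rmsd.to_csv(outdir / "rmsd_summary.csv", index=False)
    deltas.to_csv(outdir / "delta_rmsf.csv", index=False)
    pca_df.to_csv(outdir / "pca.csv", index=False)
    _write_provenance(cfg, "flexibility", outdir)
    return {"rmsd": rmsd, "delta_rmsf": deltas, "pca": pca_df}


def run_assay_analysis(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Tm/ΔSvh and ln v tables across the condition series."""
    cfg.validate()
    outdir = Path(cfg.outdir) / "assay"
    outdir.mkdir(parents=True, exist_ok=True)
    melt_rows, kin_rows = [], []
    for c in cfg.conditions:
        if c.melt_csv is not None:
            df = fio.read_melt_csv(c.melt_csv)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    series = melt_mod.series_from_table(df)
                    fit = melt_mod.fit_two_state(series)
                melt_rows.append({
                    "condition": c.label,
                    "Tm_C": fit.Tm_celsius,
                    "dHvh_kJ_mol": fit.dHvh,
                    "dSvh_kJ_molK": fit.dSvh,
                    "converged": fit.converged,
                })
            except Exception as exc:          # unfittable series: flag, continue
                log.warning("condition %s: melt fit failed (%s)", c.label, exc)
                melt_rows.append({
                    "condition": c.label, "Tm_C": np.nan, "dHvh_kJ_mol": np.nan,
                    "dSvh_kJ_molK": np.nan, "converged": False,
                })
        if c.kinetics_csv is not None:
            df = fio.read_kinetics_csv(c.kinetics_csv)
            groups = (df.groupby("replicate") if "replicate" in df.columns
                      else [(0, df)])
            fits = []
            for _rep, grp in groups:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fits.append(kin.fit_first_order(kin.MonomerLossSeries(
                        times=grp.time_days.to_numpy(),
                        monomer=grp.monomer_percent.to_numpy(),
                    )))
            lnv = [f.ln_v for f in fits if f.ln_v is not None]
            kin_rows.append({
                "condition": c.label,
                "M0_pct": float(np.mean([f.M0 for f in fits])),
                "kobs_per_day": float(np.mean([f.kobs for f in fits])),
                "v_pct_per_day": float(np.mean([f.v for f in fits])),
                "ln_v": float(np.mean(lnv)) if lnv else np.nan,
                "ln_v_sem": (float(np.std(lnv, ddof=1) / np.sqrt(len(lnv)))
                             if len(lnv) > 1 else np.nan),
            })
    melt_df = pd.DataFrame(melt_rows)
    kin_df = pd.DataFrame(kin_rows)
    melt_df.to_csv(outdir / "thermal_stability.csv", index=False)
    kin_df.to_csv(outdir / "aggregation_rates.csv", index=False)
    _write_provenance(cfg, "assay", outdir)
    return {"thermal": melt_df, "kinetics": kin_df}


def run_all(cfg: RunConfig) -> dict[str, dict]:
    return {
        "surface": run_surface_analysis(cfg),
        "flexibility": run_flexibility_analysis(cfg),
        "assay": run_assay_analysis(cfg),
    }
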