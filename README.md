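# fabsolv

Analysis toolkit for protein-formulation stability studies: how a small-molecule
excipient (e.g. glycine in a citrate buffer) interacts with a protein surface in
atomistic conformational ensembles, and how those interactions line up with
thermal-unfolding and aggregation-kinetics measurements.

It is aimed at formulation scientists and simulation practitioners who have
per-condition MD ensembles of a protein (such as an antibody Fab) plus
fluorescence melting curves and SEC monomer-loss time courses, and want the
standard statistics of that workflow computed reproducibly in one place.

## What it computes

**Ensemble side** (from PDB structures + XTC/DCD/TRR or multi-model PDB
trajectories):

- Geometric hydrogen bonds — distance cutoff on the donor–acceptor (d–a) or
  hydrogen–acceptor distance and an angle cutoff (H–D–A convention by default,
  deviation-from-linearity selectable), e.g. the 0.35 nm / 30° protein-surface
  criterion; per-class counts (protein–glycine, protein–citrate,
  protein–water, …), excipient cluster fractions (monomer / dimer / Nmer by
  per-molecule bond count) and per-bond or per-site occupancies.
- Preferential interaction coefficient
  Γ₂₃ = ⟨n₃(R) − (ρ₃/ρ₁)·n₁(R)⟩ over a local domain of R = 0.6 nm
  (≈ two hydration shells), cross-checked against the RDF-integral form
  ρ₃∫₀ᴿ[g₃(r) − g₁(r)]dV with Monte-Carlo shell volumes; positive Γ₂₃ =
  preferential binding, negative = preferential exclusion.
- Hydration-shell occupancy (first shell < 0.35 nm, second 0.35–0.6 nm, by
  proximal distance) and displacement percentages between conditions;
  per-residue contact-frequency maps (0.6 nm minimum-distance cutoff).
- Flexibility: RMSD convergence series, per-residue RMSF (mass-weighted, about
  the window mean after Kabsch superposition), ΔRMSF(%) relative to a
  reference condition with domain and exposed/buried breakdowns, radius of
  gyration, Shrake–Rupley SASA (0.14 nm probe, deterministic 960-point
  spheres) and Cα principal component analysis across concatenated replicas.

**Assay side** (from CSV tables):

- Two-state van't Hoff fit of the barycentric mean (BCM) of intrinsic
  fluorescence spectra (280–460 nm window):
  I(T) = [I_N(T) + I_D(T)·K(T)]/[1 + K(T)] with
  K(T) = exp[−(ΔH_vh/R)(1/T − 1/T_m)], yielding T_m, ΔH_vh and
  ΔS_vh = ΔH_vh/T_m.
- First-order monomer-loss fit M(t) = M₀·e^(−k_obs·t) with the initial
  aggregation rate v = M₀·k_obs and ln v reporting.

A `synth` module generates every input with planted ground truth (solvated
boxes with controlled near-surface excipient enrichment, Gaussian fluctuation
ensembles, melting curves, decay series), which is how the whole pipeline is
tested end to end.

## Worked example

```python
import fabsolv as fs
from fabsolv.datasets import fab_hydration_table
from fabsolv.preferential import displacement_percent

# displacement accounting on the bundled Fab hydration table
t = fab_hydration_table()
d1 = displacement_percent(t.loc[0, "first_shell_water"],
                          t.loc[10, "first_shell_water"])
d2 = displacement_percent(t.loc[0, "second_shell_water"],
                          t.loc[10, "second_shell_water"])
print(f"first-shell displacement:  {d1.percent:.1f}% (rounded {d1.percent_rounded}%)")
print(f"second-shell displacement: {d2.percent:.1f}% (rounded {d2.percent_rounded}%)")

# preferential interaction on a synthetic box with +8 planted local excipient
protein = fs.build_toy_protein(16, "helix")
ens = fs.solvate_ensemble(
    protein,
    fs.SolvationSpec(box_edge=6.0, n_water=600, n_excipient={"glycine": 50},
                     excess_local={"glycine": 8}, seed=7),
    n_frames=100)
g = fs.gamma23(ens, "glycine", "water")
print(f"Gamma23 = {g.gamma23:.2f} +/- {g.sem:.2f} "
      f"(RDF-integral route {g.gamma23_integral:.2f}, "
      f"planted truth {ens.provenance['gamma_truth']['glycine']:.2f})")

# assay fits on simulated data
fit = fs.fit_two_state(fs.simulate_melt(
    fs.MeltSimSpec(Tm_true=352.40, dHvh_true=480.0, noise_sigma=0.05, seed=3)))
print(f"Tm = {fit.Tm_celsius:.2f} C, dHvh = {fit.dHvh:.1f} kJ/mol, "
      f"dSvh = {fit.dSvh:.3f} kJ/(mol K)")
kfit = fs.fit_first_order(fs.simulate_monomer_loss(
    fs.KineticsSimSpec(M0_true=100.0, kobs_true=0.12, noise_sigma=0.4, seed=2)))
v, ln_v = fs.initial_rate(kfit)
print(f"kobs = {kfit.kobs:.4f} /day, v = {v:.2f} %/day, ln v = {ln_v:.2f}")
```

Output:

```
first-shell displacement:  51.8% (rounded 52%)
second-shell displacement: 73.4% (rounded 73%)
Gamma23 = 8.20 +/- 0.04 (RDF-integral route 8.18, planted truth 8.21)
Tm = 79.27 C, dHvh = 480.4 kJ/mol, dSvh = 1.363 kJ/(mol K)
kobs = 0.1192 /day, v = 11.90 %/day, ln v = 2.48
```

The displacement numbers say that on initial excipient binding roughly half of
the ~3000 first-shell waters and three quarters of the second-shell waters are
displaced; the Γ₂₃ run shows the counting and RDF-integral routes agreeing
with each other and with the generator's bookkeeping; the fits recover the
simulated melting midpoint (352.40 K = 79.25 °C) and rate constant within
noise.

## Command-line pipeline

A TOML config defines a condition series (reference condition, per-condition
structures, trajectories and assay CSVs):

```bash
fabsolv synth study_dir --seed 1      # generate a synthetic 3-condition study
fabsolv validate study_dir/config.toml
fabsolv all study_dir/config.toml     # surface + flexibility + assay stages
```

Each stage writes CSV tables (Γ₂₃, H-bond counts, shell occupancy and
displacement, contact maps, RMSF/ΔRMSF, PCA, T_m/ΔS_vh, ln v) plus a
provenance JSON (config hash, seed, cutoffs) under the output directory;
re-running an identical config reproduces the outputs bit-identically.
Cutoffs are overridable per run (`--hb-dist`, `--hb-angle`, `--local-cutoff`,
`--shells`, `--probe-radius`, `--window`, `--seed`).

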