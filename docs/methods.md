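# Methods

This note documents the models, conventions and numerical choices behind
fabsolv, and what its synthetic-data tests do and do not demonstrate.

## Units and data model

Internal units are nm, ps, K, amu and kJ/mol; ångström appears only at PDB
boundaries (Å→nm on read, nm→Å on write). Atom and residue numbering is
1-based, following PDB convention. A `MolecularSystem` partitions atoms into
molecules, each labelled with a species (protein, water, glycine, citrate,
ion, other); surface analyses require exactly one protein molecule. Species
are inferred from residue names; a GLY residue counts as protein when its
chain holds other amino acids and as the free glycine excipient when it
stands alone, and unknown residue names require an explicit override rather
than being guessed. Donors are N/O heavy atoms with at least one bonded
hydrogen (hydrogens are attached to their nearest heavy atom within
0.135 nm when the file provides no bonds); acceptors are all N/O. Distances
in periodic systems use the cubic minimum-image convention throughout.

Fab domain labels (VH, VL, CH1, CL) are supplied through a CSV annotation
(chain, res_start, res_end, label), since residue numbering schemes vary
between structures; the package treats the numbering of the input file as
authoritative.

## Hydrogen bonds

A bond is a (donor-hydrogen, acceptor) pair passing a distance and an angle
cutoff. Two distance definitions (donor–acceptor, hydrogen–acceptor) and two
angle conventions are implemented: the default is the H–D–A angle at the
donor ≤ cutoff (the common trajectory-tool convention); the alternative is
deviation from linearity at the hydrogen (180° − ∠D–H···A ≤ cutoff). The
protein-surface criterion is 0.35 nm (d–a) with 30°. The glycine–glycine
clustering criterion of 0.22 nm keeps its donor–acceptor form by default
even though a 0.22 nm D–A contact is sterically implausible; an option
reinterprets that cutoff as a hydrogen–acceptor distance. Cluster
classes follow the per-molecule intermolecular bond count: 0 → monomer,
1 → dimer, >1 → Nmer; fractions sum to 1 by construction every frame.

Candidate pairs come from a KD-tree (periodic via box-size wrapping) with
the cutoffs applied exactly afterwards; correctness is defined by exact
agreement with the O(N²) all-pairs oracle in the test suite, which is run
across all four criteria combinations on random boxes.

## Preferential interaction

The local domain is the region within R = 0.6 nm of the protein
(≈ two hydration shells). The default distance metric is *proximal*: a
molecule's distance is the minimum distance from its reference site (water
oxygen; heavy-atom centroid for excipients — configurable) to any protein
heavy atom. A centre-of-mass radial metric is retained as an option, but a
COM-centred 0.6 nm sphere cannot represent two hydration shells around a
multi-nanometre protein, so proximal is the physically meaningful default.

Γ₂₃ is computed two independent ways and both are reported:

- counting form: Γ₂₃ = ⟨n₃(R) − (ρ₃/ρ₁)·n₁(R)⟩, with the bulk density
  ratio taken from molecules farther than 2R = 1.2 nm from the protein
  (keeping the interface out of the bulk estimate);
- RDF-integral form: ρ₃·Σ_r [g₃(r) − g₁(r)]·V(r) up to R, where proximal
  shell volumes V(r) are estimated by uniform Monte-Carlo sampling of the
  box (2×10⁵ points, seeded) and bin width divides R exactly.

The two routes are algebraically equivalent in the limit of exact volumes,
so their agreement (≪ 2 % on the synthetic systems) validates the volume
estimation and binning rather than restating one computation.

Hydration shells are half-open intervals [0, 0.35) and [0.35, 0.6) nm of
proximal distance, so first + second shell equals the local-domain count
exactly and a molecule at exactly 0.35 nm falls in the second shell.
Displacement between conditions is 100·(ref − cond)/ref, reported raw and
rounded to the nearest integer percent. Contact frequency is the fraction
of frames in which any heavy atom of the species comes within 0.6 nm of any
heavy atom of a residue. Ensemble statistics default to the trailing
two-thirds of frames (the equilibrated-production convention); the window
fraction is configurable everywhere.

## Flexibility and PCA

Superposition is the Kabsch least-squares rigid transform with the
determinant sign corrected, so only proper rotations are returned;
degenerate (collinear) fit sets are rejected. RMSF is computed per atom
about the window-mean position after superposition (two alignment passes),
then aggregated per residue as the mass-weighted mean; replicas are
profiled independently and averaged with SEM, mirroring the
replica-then-average error convention. ΔRMSF(%) is the percent change
against a reference condition; the global value is the percent change of
the global-average RMSF (the per-residue-percent average is available as an
option). Residues with zero reference RMSF are flagged undefined and
excluded with a warning.

A caveat the test suite makes explicit: rigid-body superposition absorbs
part of the fluctuation variance (≈ 2/n_res of it for per-residue
displacements, more at chain ends through the rotational lever arm), so
recovered RMSF of an isotropic Gaussian ensemble sits 1–3 % below σ√3 at
the chain lengths used, and profile ratios between conditions are far more
accurate than absolute amplitudes (the absorption cancels in ΔRMSF).

Exposure classes come from relative per-residue SASA of the reference
frame — residue SASA in context divided by the same residue's SASA in
isolation — with exposed ≥ 25 % by default (threshold configurable). SASA
is Shrake–Rupley with a deterministic golden-spiral point set, 960
points/atom and a 0.14 nm probe; determinism was preferred over speed, and
the two-sphere spherical-cap closed form is the independent oracle.

PCA runs on Cα coordinates of all replicas concatenated, iteratively
superposed on the mean structure until convergence; the coordinate
covariance (uniform frame weights, no mass weighting) is eigendecomposed,
and the trace identity Σλ = tr(cov) is exact to numerical precision.

## Assay fits

The melting observable is the barycentric mean Σ(λ·I)/Σ(I) of the
fluorescence spectrum over 280–460 nm. The two-state model is
I(T) = [I_N(T) + I_D(T)·K(T)]/[1 + K(T)], K(T) = exp[−(ΔH_vh/R)(1/T −
1/T_m)], R = 8.314 J mol⁻¹ K⁻¹, with flat baselines by default and linear
(sloped) baselines as an option; the unfolded fraction at the fitted T_m is
0.5 by construction and ΔS_vh = ΔH_vh/T_m exactly. Fitting is bounded
trust-region least squares with T_m initialised at the steepest
finite-difference slope, ΔH_vh at 400 kJ/mol, and five jittered restarts;
the exponent is clipped at ±500 to keep the saturated tails finite. A fit
is accepted only when T_m lies in the interior of the temperature range,
ΔH_vh > 0 and the transition amplitude exceeds five times the residual
RMSE — a flat trace therefore comes back flagged unconverged instead of
with spurious parameters. Temperatures ≤ 150 in input tables are treated as
°C and converted to K; T_m is reported in °C in summaries.

Monomer loss is M(t) = M₀·e^(−k_obs·t) with both parameters free and
k_obs bounded at zero (an increasing series pins k_obs = 0 with a warning);
no plateau term by default, an offset variant exists but is off. Parameter
SEMs come from the Jacobian at the optimum. The initial rate is
v = M₀·k_obs, with ln v in (% day⁻¹) units; ln v SEM across replicates is
reported symmetrically. The ~2-minute sampling dead time of typical
time courses is negligible against multi-day series (property-tested at
0.1 % in k_obs) and is ignored.

## Synthetic systems and what they show

The generators define the study conditions for all tests:

- `build_toy_protein`: rigid helical (0.15 nm rise, 0.23 nm radius, 100°
  twist) or extended polypeptide with backbone N/H/CA/C/O plus a CB
  pseudo-atom, donors and acceptors flagged, alternating VH/VL pseudo-domain
  labels.
- `solvate`: waters placed uniformly in the accessible volume (minimum site
  separation 0.25 nm, preventing degenerate distances in the H-bond and RDF
  kernels); each excipient species either follows the same spatial law as
  water (excess 0 → Γ₂₃ = 0 in expectation) or is split so its local-domain
  count equals the bulk-proportional expectation plus the requested signed
  excess. Exact per-region counts and the implied per-frame Γ₂₃ truth are
  recorded, and the analysis is validated against that bookkeeping, not
  against the nominal excess. The local domain uses the same
  minimum-distance-to-protein-heavy-atom definition as the analysis, so
  generator truth and metric coincide.
- `fluctuate`: i.i.d. isotropic Gaussian displacements with per-residue σ
  applied to whole residues, optionally plus one collective mode
  (per-residue shape × Gaussian amplitude) orthogonalised against
  rigid-body motions so superposition cannot absorb it — that mode is the
  planted truth for the PCA eigenvalue checks.
- `simulate_melt` / `simulate_monomer_loss`: the forward models of the two
  fitters with seeded Gaussian noise.

All generators are bit-reproducible under their seed. What passing tests
show: the statistics, estimators and bookkeeping are implemented correctly
against closed forms, independent oracles and planted truth. What they do
not show: anything about force-field accuracy, sampling convergence of real
trajectories, correlated solvent structure (frames here are independent
re-solvations), or real fluorescence baselines — synthetic noise is
Gaussian and uncorrelated by design.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`, chosen as the
smallest sizes at which sampling error sits comfortably inside the stated
tolerances: Γ₂₃ boxes of ~3,700 atoms (1,000 waters, 80 glycines, 16-residue
protein) × 200 independently re-solvated frames; 100 random ≤ 480-atom boxes
for the H-bond oracle; 2,000-frame ensembles of a 60-residue helix for
RMSF/ΔRMSF and 5,000 frames of a 30-residue helix for PCA; a 4×4
(T_m, ΔH_vh) grid plus 50 noisy replicate fits for the melt; the
3-condition end-to-end study uses 260 waters, 36 glycines, 30 surface and
240 flexibility frames per condition.
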