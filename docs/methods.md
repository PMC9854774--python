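# Methods

Models, parameter choices and numerical decisions behind `bindkin`, with
what the synthetic generators do and do not emulate.

## 1. End-point binding free energies

### Estimators

For a ligand sampled in the protein-bound state (P) and free in water (W),
with ⟨·⟩ denoting trajectory averages of ligand–surroundings interaction
energies:

- **LIE**: `ΔG = α(⟨V_vdw⟩_P − ⟨V_vdw⟩_W) + β(⟨V_ele⟩_P − ⟨V_ele⟩_W)`
- **LRA**: `ΔG_LRA = ΔG_LIE + β ⟨V_ele⟩_P,q=0`, where the extra term is the
  bound-state ligand–protein electrostatic energy averaged with the ligand
  partial charges set to zero ("preorganization" of the binding site).

Defaults are α = 0.5 and β = 1.043. The widely used alternative
electrostatic coefficient β = 0.16 is exported as `AQVIST_BETA`; it is never
substituted silently — callers must construct `LIECoefficients(beta=...)`
explicitly. Replicate trajectories are averaged independently and
aggregated as mean ± sample SD (ddof = 1); a single replicate reports no SD.

### Ki conversion

`ΔG_exp = R T ln(Ki / c°)` with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹,
c° = 1 M, and **T = 310.15 K by default**. The temperature is an inference,
not a quoted condition: 310.15 K (37 °C, the assay temperature regime) is
the unique round-temperature choice that reproduces the reported ΔG values
to their printed 2 d.p. for every self-consistent Ki. One reported
DM109/GSH pair (Ki = 35.12 μM with ΔG = −5.96 kcal/mol) is internally
inconsistent with the conversion that reproduces all other rows (−5.96
would imply Ki ≈ 63 μM); it is excluded from the verification panel and
flagged here rather than "fixed".

Tolerances used in tests: ±0.05 kcal/mol for LIE/LRA recomputation (the
inputs are component means rounded to 2 d.p.; worst-case propagated
rounding error is ±(2α+2β)·0.005 ≈ ±0.015, plus the reported values' own
rounding) and ±0.01 kcal/mol for Ki conversions (printed precision; Ki
inputs carry 3 significant figures).

## 2. Inhibition kinetics

### Rate law

The general modifier mechanism — inhibitor binds free enzyme E with Ki and
the ES complex with Ki′; the ESI complex retains a fraction b of catalytic
activity:

```
v = Vmax·S·(1 + b·I/Ki′) / ( Km·(1 + I/Ki) + S·(1 + I/Ki′) )
```

Special cases: b = 0 → linear mixed inhibition; b = 0 and Ki = Ki′ → pure
non-competitive; 0 < b < 1 → partial (hyperbolic) mixed. Invariants
enforced: Vmax, Km, Ki, Ki′ > 0 and 0 ≤ b < 1.

### Lineweaver–Burk replot chain

1. **Primary**: ordinary least squares of 1/v on 1/S per inhibitor level
   (≥ 3 substrate points per level; groups below that are skipped with a
   warning; an I = 0 control group is mandatory). For the rate law above,
   `slope(I) = Km(1 + I/Ki)/(Vmax(1 + bI/Ki′))` and
   `intercept(I) = (1 + I/Ki′)/(Vmax(1 + bI/Ki′))`.
2. **Secondary**: slope and intercept vs I. For linear inhibition both are
   straight lines; for partial inhibition both are hyperbolic. Curvature is
   decided by a nested F-test (quadratic vs linear, α = 0.05 by default,
   ≥ 4 inhibitor levels required; fewer → "inconclusive"). Machine-precision
   guards: if the linear fit already explains everything
   (RSS ≤ 1e-18·TSS) the verdict is "linear" regardless of the F statistic.
3. **Tertiary** (partial inhibition): with Δx(I) = x(I) − x(0), both
   `1/Δslope` and `1/Δintercept` are exactly linear in 1/I:

   ```
   1/Δslope     = A_s/I + B_s   with  B_s/A_s = b/Ki′
   1/Δintercept = A_i/I + B_i   with  B_i/A_i = b/Ki′,  A_i = Vmax·Ki′/(1 − b)
   ```

   Straight-line fits of the two replots invert in closed form. With
   r = B_i/A_i (an estimate of b/Ki′) and C = A_i/Vmax (an estimate of
   Ki′/(1 − b)): `b = rC/(1 + rC)`, `Ki′ = C/(1 + rC)`, and
   `1/Ki = (Vmax/Km)/A_s + B_s/A_s`. Vmax and Km come from the
   uninhibited primary fit. A sign change of the reciprocal increments
   across inhibitor levels indicates data inconsistent with the mechanism
   and raises `InputError` (see `tertiary_replot_fit`).

**Known power limitation.** The curvature F-test loses essentially all
power on the slope replot when b·Ki ≈ Ki′ (then
slope(I) ∝ (1 + I/Ki)/(1 + bI/Ki′) is nearly constant), and the quadratic
alternative only approximates the hyperbolic shape. A noiseless instance
with b = 0.4, Ki = 3.69 μM, Ki′ = 1.45 μM (b/Ki′ = 0.276 vs 1/Ki = 0.271)
classifies "linear" at α = 0.05 with 7 inhibitor levels. Away from that
ridge (e.g. b = 0.3 with the same constants) classification is correct in
100/100 seeded noiseless runs.

### Global fit

`global_fit` fits the rate law directly with `scipy.optimize.least_squares`
(Levenberg–Marquardt). Positive parameters are fitted in log space; b is
fitted through a logistic map onto (0, 1) so constraints hold without
bounded optimization. Residuals are relative, `(v_obs − v_pred)/v_pred`,
matching the constant-CV error structure of initial-velocity assays
(absolute weighting is selectable). Three starting points seeded from the
replot chain reduce dependence on initialization. Standard errors come from
the delta method on (JᵀJ)⁻¹. In `model="auto"`, the secondary-replot
verdict selects partial vs linear, and an extra-sum-of-squares F-test
collapses linear mixed to pure non-competitive when Ki = Ki′ is not
rejected.

### IC50

Four-parameter logistic on log10 concentration:
`y = bottom + (top − bottom)/(1 + 10^(h·(log c − log IC50)))`, via
`scipy.optimize.curve_fit`, requiring ≥ 5 distinct concentrations; plateaus
can be fixed (`constrain=(top, bottom)`). Flat data raise `FitError`;
non-monotone data fit with a warning. For pure non-competitive inhibition
`v/v₀ = 1/(1 + I/Ki)` exactly, so IC50 = Ki at every substrate
concentration — used as an internal consistency check. Enzyme activity from
absorbance uses ΔA/(ε·l) with ε = 9600 L·mol⁻¹·cm⁻¹ (GSH–CDNB conjugate at
340 nm).

## 3. Trajectory geometry

- **Superposition**: Kabsch's closed-form solution via SVD of the
  cross-covariance of centered coordinates, with the determinant sign
  correction so the returned rotation is always proper (no reflections).
  Built by hand (it is part of the package's analytical core) and verified
  in tests against an independent quaternion-sampling + Nelder–Mead
  rotation search. Degenerate inputs (< 3 atoms, collinear selections) are
  rejected.
- **RMSD**: each frame is fitted to the reference on a fit selection (by
  default the active-site backbone: N/CA/C/O of residues with any atom
  within 10 Å of the ligand in the reference frame), then RMSD is measured
  on the ligand without refitting.
- **RMSF**: frames are aligned on the fit selection; per-atom RMSF is the
  RMS deviation from the time-mean position. For iid Gaussian jitter of
  per-coordinate SD σ, the expected RMSF is σ√3 — the synthetic ground
  truth.
- **Interactions**: geometric criteria with PLIP defaults — hydrogen bond:
  donor–acceptor heavy-atom distance ≤ 4.1 Å and D–H···A angle ≥ 100° (the
  angle criterion is skipped, with a logged warning, when the selection has
  no hydrogens, as in heavy-atom-only PDB files); hydrophobic contact:
  apolar carbon pair ≤ 4.0 Å; π-stacking: ring-centroid distance ≤ 5.5 Å,
  lateral offset ≤ 2.0 Å, plane angle in [0°, 30°] (parallel) or
  [60°, 90°] (T-shaped); π-cation: centroid–charge distance ≤ 6.0 Å.
  Chemistry is perceived geometrically on a reference frame: covalent bonds
  from distance cutoffs (1.75 Å heavy–heavy, 1.25 Å X–H), ligand rings as
  5/6-cycles of C/N in the bond graph (networkx minimum cycle basis),
  protein rings/cations from canonical residue atom names. Occurrence is
  `100 × (frames with ≥ 1 matching event)/frames` per (type, residue).

## 4. Synthetic generators — what they emulate

- **Energy series**: stationary AR(1), `x_t = μ + ρ(x_{t−1} − μ) + ε_t`,
  ε ~ N(0, σ²(1−ρ²)), x₀ ~ N(μ, σ²) — the minimal model of the strong
  autocorrelation of MD interaction-energy outputs. Effective sample size
  n(1−ρ)/(1+ρ) is exposed for test tolerances. Defaults σ = 1.5 kcal/mol,
  ρ = 0.8, 2000 frames, 4 replicates. *Not* emulated: drift,
  non-Gaussianity, cross-correlation between components.
- **Kinetics**: exact rate-law velocities on the standard assay grids
  (CDNB 14–1000 μM, GSH 37.5–3750 μM, inhibitor 0–50 μM) with
  multiplicative Gaussian noise (default CV 2 %, 3 replicates); optional
  additive noise. *Not* emulated: substrate depletion, instrument drift,
  outliers.
- **Trajectory**: a hard-coded 48-atom toy complex (six residues + a phenol
  ligand) with a built-in parallel π-stack and one hydrogen bond. Frames
  are template + iid N(0, σ²) jitter (frame 0 is the clean template /
  reference); a per-frame Bernoulli(p) draw toggles the hydrogen bond by
  swinging only the glutamine side-chain tip, so ligand RMSD/RMSF ground
  truths are independent of p. *Not* emulated: real protein flexibility,
  solvent, correlated motions. Published per-system RMSD/RMSF values and
  interaction distances from the original MD trajectories are **not
  reproducible at desk scale** (the trajectories are not deposited); the
  geometric machinery is therefore validated against oracles and synthetic
  ground truth instead.

All generators are pure functions of their spec (seed included):
identical specs give bit-identical output.

## 5. Numerical and design decisions

- Errors are a small typed hierarchy (`InputError`, `ParseError` with line
  numbers, `FitError`) with machine-readable categories; the CLI maps them
  to JSON on stderr and exit code 1.
- OLS for all straight-line fits (numpy); F-statistics and p-values from
  `scipy.stats`; nonlinear fits via `scipy.optimize` — standard numerics
  are delegated to the scientific stack, while the field-specific pieces
  (estimators, rate-law inversion, Kabsch, interaction criteria) are
  implemented and tested here.
- PDB I/O through biotite (multi-model); elements fall back to the first
  letter of the atom name when the element column is blank; author residue
  numbering is passed through verbatim.
- Free energies print at 2 d.p. by default (`--precision` to override).
- YAML run configuration with a single namespaced schema; CLI flags
  override config, config overrides built-in defaults.

## 6. Limitations

- T = 310.15 K for Ki→ΔG is inferred, not quoted (see §1); the one
  inconsistent reported Ki/ΔG pair is excluded, not corrected.
- The secondary-replot curvature test has vanishing power near
  b·Ki ≈ Ki′ and generally below 4 inhibitor levels (see §2).
- Interaction typing is heuristic (distance-based bonds, name-based protein
  rings); exotic ligands (charged ligands as π-cation donors, halogen
  bonds, salt bridges, water-mediated bonds) are out of scope.
- Only multi-model PDB trajectories are supported (no DCD/XTC).
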