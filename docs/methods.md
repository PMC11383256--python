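# Methods

## Signal model and units

The package models the diffusion coefficient *D* inside an ROI as
gamma-distributed, P(D) ∝ D^(κ−1) e^(−D/θ), and the DWI signal as its
Laplace transform, S(b) = S₀(1 + θb)^(−κ). κ is dimensionless; θ and
every diffusivity are stored internally in SI mm²/s. The brain-tumor
literature prints θ in units of 10⁻⁴ mm²/s (so a printed 74.55 means
74.55×10⁻⁴ mm²/s); writers convert at the boundary and every serialized
column carries a unit tag (`theta_1e-4_mm2_per_s`, `adc_mm2_per_s`).
This reading is the only one under which κθ lands in the ADC magnitude
range (κ = 0.05, θ = 74.55×10⁻⁴ gives mean diffusivity ≈ 3.7×10⁻⁴
mm²/s) and the cohort-mean staging fraction f1 lands near the reported
~83%.

The density is evaluated in log space (`gammaln`), because for the
κ ≪ 1 values typical of tumors it is singular (but integrable) at
D = 0. Area fractions go through the regularized lower incomplete gamma
function P(κ, x/θ) rather than quadrature, which is fragile near the
singularity; adaptive quadrature with an algebraic endpoint weight is
retained in the tests as an independent oracle. The perfusion fraction
f3 is computed as 1 − CDF(staging_high), never by truncated
integration, so f1 + f2 + f3 = 1 holds to machine precision.

## Thresholds

Staging cuts default to 1×10⁻⁴ and 3×10⁻⁴ mm²/s, grading cuts to
0.3/0.5/0.8×10⁻⁴ mm²/s, all configurable through
`DiffusionThresholds`, which enforces
0 < g₁ < g₂ < g₃ ≤ staging_low < staging_high. Some papers quote the
compartment boundaries an order of magnitude higher (10⁻³-scale); the
defaults here follow the 10⁻⁴-scale convention because it is the one
consistent with the fraction magnitudes above, and callers who want the
other convention pass it explicitly.

## Fitting

`fit_gamma_model` minimizes Σ_b (S_obs − S₀(1+θb)^(−κ))² with
`scipy.optimize.least_squares` (TRF, analytic Jacobian) under box
constraints κ ∈ [10⁻⁶, 10²], θ ∈ [10⁻⁶, 1] mm²/s,
S₀ ∈ [0.1, 10]·S(0). The objective is nearly flat along the κθ ridge
for κ ≪ 1, so the fit restarts from a deterministic grid
κ₀ ∈ {0.01, 0.05, 0.2, 1} × θ₀ ∈ {10, 75, 300}×10⁻⁴; best residual sum
of squares wins, ties break toward smaller κ. There is no randomness
anywhere in fitting: identical inputs give identical fits. Optimizer
failure is reported as `converged=False` with diagnostics, never an
exception; solutions pinned to a bound are flagged `at_bounds`.
Tolerances are set to 10⁻¹⁵ (ftol/xtol/gtol, max 500 evaluations);
noiseless model decays are recovered to ~10⁻¹² relative error.

ADC is provided in both conventions found in practice: the two-point
form −ln(S_b/S₀)/b and the log-linear OLS slope over all b-values
(identical on mono-exponential data; both are reported because
published workflows rarely state which they used). Negative ADCs
(signal increase with b, possible under noise) are flagged but not
clamped — clamping would bias group means downstream.

### Per-b-value protocols and identifiability

Clinical tables report a distinct κ at every b-value, yet a single
(0, b) signal pair cannot identify both κ and θ. Four protocols are
implemented; the choice matters a great deal under noise:

* **fixed-theta (default)** — θ is pinned at a global constant
  (74.55×10⁻⁴ mm²/s by default, configurable); S₀ comes from a
  two-parameter fit to the full decay and κ_b = ln(S₀/S_b)/ln(1+θb)
  at each b.
* **shared-theta** — θ and S₀ from one free per-ROI fit, κ_b by the
  same closed-form inversion.
* **cumulative** — refit on the b-prefix up to each row.
* **joint** — one free fit, constant rows.

The free three-parameter fit is *statistically* unidentifiable at
clinical noise: as κ → ∞ with κθ fixed, (1+θb)^(−κ) → e^(−κθb), so a
five-point decay constrains the product far better than the split. At
Rician SNR 50 the Cramér–Rao bound for κ (even with θ known) at
κ = 0.05 is σ_κ ≈ 0.0095 — a 19% standard error — and with θ free the
measured median |Δκ|/κ over the κ ∈ [0.01, 0.2] range is ~27%, versus
~7% with θ pinned. Pinning θ is also what the near-constant θ values
printed by clinical cohorts (identical mean across all b-values and
groups, small SD) imply their software effectively did. The practical
consequence: per-b κ and the fractions are estimated *conditionally on
the global θ*, and under the fixed-theta protocol κ_b and the fractions
at one b are monotone transforms of one another.

## Group comparison and ROC

All rank statistics use midranks for ties, making AUC ≡ U/(n₁n₂) exact
on every input. The Mann–Whitney p-value is exact (full enumeration of
labelings, two-sided by |U − n₁n₂/2|) for pooled n ≤ 12, else a normal
approximation with tie correction and 0.5 continuity correction. The
AUC standard error is Hanley–McNeil (1982); the AUC p-value is a
two-sided normal test against 0.5 using that SE — at AUC = 0.5 the HM
variance reduces to the exact Mann–Whitney null variance
(n₁+n₂+1)/(12n₁n₂), which is why the test is well calibrated (measured
rejection rate 0.057 at α = 0.05 over 2000 null replicates of 24 vs
42). Cutoffs minimize |sensitivity − specificity| over midpoints
between adjacent distinct scores plus ±∞ sentinels; ties break toward
larger sensitivity + specificity, then the smaller cutoff, so output is
deterministic. Per parameter, the score direction is chosen so the
reported AUC is ≥ 0.5 and recorded in the output. No multiple-testing
correction is applied; the per-row p-values are raw, as is conventional
in this table format.

## Synthetic data

`simulate_cohort` draws per-subject (κ, θ, S₀) from independent
truncated normals per group (redrawn until above a small positive
floor). Defaults model the published benign/malignant contrast at
b = 2000 s/mm²: meningioma n = 24, κ 0.0623 ± 0.021; glioma n = 42,
κ 0.0394 ± 0.038; θ 74.5 ± 5–6 (×10⁻⁴ mm²/s) in both groups;
S₀ 1000 ± 100 (arbitrary units, a typical 1.5 T ROI mean; the source
tables print no S₀, so this is the package's choice). A grading
scenario (18 low- vs 24 high-grade, κ 0.04/0.08 ± 0.05) is also
bundled. Noise defaults to Rician at SNR 50 referenced to S₀ —
magnitude-MR noise typical of 1.5 T DWI — with Gaussian and noise-free
modes available. Per-subject substreams are derived by hashing
(master seed, group label, subject index), so growing a cohort never
reshuffles existing subjects and everything is reproducible from one
integer.

What the generator deliberately does **not** emulate: within-subject
correlations between parameters (unknown in the source cohorts — κ and
θ are drawn independently, with no b-dependence of the generating κ),
partial-volume and edema effects, spatial noise correlation, and
scanner drift. Passing tests therefore demonstrate that the *analysis
chain* is correct and well calibrated under the stated statistical
structure — not that real cohort AUCs (which reflect the unknown joint
distribution and per-b biological variation) are reproduced. The
default-cohort AUC at b = 2000 is ~0.64 for every gamma-derived
parameter, the value implied by the overlap of the two κ
distributions; published clinical AUCs of 0.85–0.90 would require
between-group separation or within-subject structure the printed
summary statistics do not encode.

`simulate_phantom` embeds an ellipsoidal tumor in a uniform background
(default background: κ = 1, θ = 8×10⁻⁴ mm²/s — near-mono-exponential
tissue at ADC ≈ 0.8×10⁻³) purely to exercise the NIfTI/ROI-reduction
path; it makes no anatomical claims.

## Numerical and I/O choices

Masks and volumes are matched on voxel grid only; mismatch is a hard
error, never an implicit resample. CSV writers emit 17-significant-
digit floats with unit-tagged headers; readers refuse files without
them. Fractions are stored as [0, 1] proportions in machine outputs,
with a percent option for display. Pipeline outputs are byte-identical
across reruns with the same scenario and seed. Scenario JSON files
round-trip losslessly through `ScenarioConfig`.

Problem sizes used by the test and acceptance workloads (chosen to make
the statistical assertions sharp at interactive runtimes): 200 noiseless
+ 500 noisy decays for recovery, 1000 parameter draws for fraction
invariants, 2000 replicates for null calibration, 500 subjects per group
for the cohort direction checks, and the 66-subject bundled scenario for
the pipeline determinism check.

## Known limitations

* ROI-mean analysis only; a voxelwise mode is not a supported surface.
* The free (S₀, κ, θ) fit is ill-conditioned on 5-point decays at
  clinical SNR (see identifiability above); interpret free-fit κ/θ
  splits with caution and prefer the fixed-theta protocol for per-b
  reporting.
* The exact Mann–Whitney enumeration is O(C(n, n₁)) and is capped at
  pooled n = 12; beyond that the normal approximation is used.
* Gaussian noise mode clips at a small positive floor to keep decays
  valid; at very low SNR this introduces a slight positive bias
  (Rician mode, the physical one, does not need clipping).
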