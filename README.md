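# gammadwi

Gamma-distribution modelling of multi-b-value diffusion-weighted MRI
(DWI), for researchers studying how non-Gaussian diffusion parameters
separate tumor types — e.g. benign meningioma from malignant glioma, or
low- from high-grade glioma — from ROI-level signal decays.

## The model

The mono-exponential ADC model assumes a single diffusion coefficient
per voxel. Real tumor tissue is heterogeneous, so `gammadwi` instead
treats the diffusion coefficient *D* as gamma-distributed with shape κ
and scale θ (mm²/s):

    P(D) = D^(κ−1) exp(−D/θ) / (Γ(κ) θ^κ)

The measured DWI signal at diffusion weighting *b* is the Laplace
transform of that density:

    S(b) = S₀ (1 + θb)^(−κ)

Small κ (≈ 0.05 in tumors) piles probability mass near *D* = 0 —
heavily restricted, intracellular-like water. Area fractions of *P(D)*
quantify tissue compartments:

* **staging fractions** — f1 = P(D < 1×10⁻⁴), f2 = P(1–3×10⁻⁴),
  f3 = P(D > 3×10⁻⁴) mm²/s: intracellular, extracellular and perfusion
  components (f1 + f2 + f3 = 1);
* **grading fractions** — f11/f12/f13 = mass below 0.3/0.5/0.8 ×10⁻⁴
  mm²/s: graded degrees of heavily restricted diffusion.

On top of the per-ROI fits, the package runs the standard two-group
diagnostic workflow: Mann–Whitney U comparison and ROC analysis per
parameter per b-value (AUC, Hanley–McNeil standard error, p-value
against AUC = 0.5, and the cutoff balancing sensitivity against
specificity). A synthetic-data module generates cohorts and 4D NIfTI
phantoms with the same statistical structure, so the whole pipeline is
testable without patient data.

## Worked example

```python
from gammadwi import GammaParams, signal_model, staging_fractions

params = GammaParams.from_display(kappa=0.0623, theta_display=74.55)
print(signal_model(2000.0, 1000.0, params))
print(staging_fractions(params).as_percent())
```

prints a signal of `841.655…` — only 16% attenuation at b = 2000 s/mm²
despite the fast-diffusing tail — and fractions (in percent, rounded)
of f1 = 78.94, f2 = 5.46, f3 = 15.60, f11 = 73.27, f12 = 75.63,
f13 = 77.86: 79% of the water behaves as restricted/intracellular, 16%
as perfusion-like. Fitting simulated noisy ROIs and running the cohort
workflow:

```python
from gammadwi import analyze_cohort, simulate_cohort
from gammadwi.io import fit_decays, fits_to_cohort

decays, truth = simulate_cohort(seed=2024)   # 24 meningioma vs 42 glioma
fits = fit_decays(decays)
cohort = fits_to_cohort(fits, dict(zip(truth.subject_id, truth.group)))
print(analyze_cohort(cohort, positive_label="glioma").head())
```

yields one ROC row per parameter per b-value; at b = 2000 the κ row
reads `auc 0.586, cutoff 0.0522, sensitivity 0.643, specificity 0.625`
(glioma κ runs lower than meningioma κ, so `direction` is `less`).

The `examples/` directory holds one narrative script per capability
(model math, single-ROI fitting, cohort ROC, NIfTI phantom round trip);
each prints its numbers with a line on what they mean. A thin CLI wraps
the same stages:

```sh
gammadwi pipeline --outdir out            # bundled 66-subject scenario
gammadwi fit --decays decays.csv --out fits.csv
gammadwi analyze --cohort cohort.csv --out results.csv
```

## Scope

ROI-mean analysis, as in the clinical workflow this implements;
voxelwise maps, DICOM ingestion, registration and alternative
non-Gaussian models (IVIM, kurtosis, stretched exponential) are out of
scope. See `docs/methods.md` for the statistical model, fitting
protocols, identifiability analysis and known limitations.
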