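"""Fit the gamma model to one noisy ROI decay and report per b-value.

Simulates a malignant-tumor-like ROI at Rician SNR 50, fits the model,
and prints the per-b-value parameter table the clinical workflow
reports (ADC, kappa, fractions).
"""

from gammadwi import (
    GammaParams,
    NoiseSpec,
    fit_gamma_model,
    per_bvalue_report,
    simulate_decay,
)

truth = GammaParams.from_display(kappa=0.0394, theta_display=74.54)
decay = simulate_decay(truth, s0=1000.0, noise=NoiseSpec("rician", snr=50.0), seed=7)
print("observed mean ROI signal:")
for b, s in zip(decay.b_values, decay.signals):
    print(f"  b = {b:6.0f}  S = {s:8.2f}")

fit = fit_gamma_model(decay)  # free (S0, kappa, theta) fit
print(f"\nfree fit: kappa = {fit.params.kappa:.4f}, "
      f"theta = {fit.params.theta_display:.2f} x 1e-4 mm^2/s, "
      f"rss = {fit.rss:.2f}, converged = {fit.converged}")
print("(kappa and theta trade off along a ridge in noisy 5-point decays,")
print(" so the free-fit split between them is uncertain)")

report = per_bvalue_report(decay)  # default: theta pinned at 74.55e-4
print("\nper-b-value report (fixed-theta protocol):")
cols = ["b_value", "adc", "kappa", "f1", "f2", "f3"]
print(report[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(f"\ntrue kappa was {truth.kappa}; ADC is the two-point estimate vs b=0.")
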