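"""Synthetic benign/malignant cohort and ROC diagnostic performance.

Simulates the default 24-meningioma vs 42-glioma cohort, runs the full
fit -> fractions -> group-comparison pipeline in memory, and prints the
ROC rows at b = 2000 s/mm^2.
"""

from gammadwi import analyze_cohort, simulate_cohort
from gammadwi.io import fit_decays, fits_to_cohort

decays, truth = simulate_cohort(seed=2024)
print(f"simulated {len(decays)} subjects "
      f"({truth['group'].value_counts().to_dict()})")

fits = fit_decays(decays)
cohort = fits_to_cohort(fits, dict(zip(truth["subject_id"], truth["group"])))
results = analyze_cohort(cohort, positive_label="glioma")

at_b2000 = results[results["b_value"] == 2000.0]
cols = ["parameter", "direction", "auc", "auc_se", "auc_p_value",
        "cutoff", "sensitivity", "specificity"]
print("\nROC analysis at b = 2000 s/mm^2 (positive class: glioma):")
print(at_b2000[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nAUC is the probability a random glioma outranks a random meningioma")
print("on that parameter (direction auto-chosen so AUC >= 0.5); the cutoff")
print("balances sensitivity against specificity.  With 24 vs 42 subjects the")
print("AUCs scatter widely around the cohort-distribution value (~0.64).")
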