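"""Prognostic evaluation of grade calls on a simulated cohort.

Simulates a cohort in which the true HG3 class has twice the hazard of
HG1 (exponential survival, 20% censoring), classifies every sample
with the planted-pair signature at fidelity 0.9, and evaluates both
agreement with the pathological labels (confusion metrics, F-score)
and prognostic separation of the *reclassified* groups (log-rank test,
Cox hazard ratio with 95% CI, Harrell's C-index).
"""

import pandas as pd

from reograde import (
    Signature,
    SimulationConfig,
    c_index,
    classify_matrix,
    confusion_report,
    cox_hr,
    km_logrank,
    simulate_grade_cohort,
)

config = SimulationConfig(
    n_genes=40, n_planted_pairs=10, n_hg1=150, n_hg3=150,
    fidelity=0.9, hazard_ratio=2.0, censoring_rate=0.2, seed=42,
)
matrix, clinical, truth = simulate_grade_cohort(config)
signature = Signature.from_pairs(truth.planted_pairs)
calls = classify_matrix(matrix, signature)

report = confusion_report(calls, clinical["grade"])
print(
    f"agreement with pathological grade: sensitivity {report.sensitivity:.4f}, "
    f"specificity {report.specificity:.4f}, F-score {report.f_score:.4f}"
)

groups = pd.Series({c.sample_id: c.call for c in calls})
curves, stat, p = km_logrank(groups, clinical)
hr, lo, hi = cox_hr(groups, clinical)
risk = (groups == "HG3").astype(float)
print(f"log-rank: chi2 = {stat:.2f}, p = {p:.3g}")
print(f"Cox HR (HG3 vs HG1) = {hr:.2f}, 95% CI [{lo:.2f}, {hi:.2f}]")
print(f"C-index of the grade call = {c_index(risk, clinical):.3f}")
print(
    "\nThe HR near the simulated value of 2 and the small log-rank p show\n"
    "the transcriptional grade calls separate the survival experience of\n"
    "the two groups; the C-index > 0.5 quantifies the concordance of the\n"
    "call with observed event order under censoring."
)
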