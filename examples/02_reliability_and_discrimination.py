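"""Test–retest reliability and impairment discrimination on a synthetic cohort.

Simulates the study design — 14 patients with clinically relevant hand
motor impairment and 11 without, followed over four timepoints — then
computes the intraclass correlation between the first two visits for each
movement pattern, the weighted kappa for the ordinal INCAT arm sub-score,
the Welch group comparison at T2, and ROC analyses including the composite
z-score ROC pooling the three glove patterns.
"""

import numpy as np

from gloverom import CohortConfig, simulate_cohort
from gloverom.clinimetrics import (
    icc_absolute_agreement,
    roc_analysis,
    composite_roc,
    weighted_kappa,
    welch_from_samples,
)
from gloverom.simulate import ROM_COLUMNS

cohort = simulate_cohort(CohortConfig(seed=7))
t2 = cohort[cohort.timepoint == "T2"]
labels = (t2.group == "impaired").astype(int).to_numpy()

print("test-retest reliability (T1 vs T2)")
for col in ROM_COLUMNS.values():
    wide = cohort.pivot(index="subject_id", columns="timepoint", values=col)
    icc = icc_absolute_agreement(wide[["T1", "T2"]].to_numpy())
    lo, hi = icc.ci95
    print(f"  {col:28s} ICC(A,1)={icc.estimate:.2f} "
          f"[{lo:.2f}, {hi:.2f}] ({icc.rating})")
wide = cohort.pivot(index="subject_id", columns="timepoint", values="incat_arm")
kap = weighted_kappa(wide["T1"].astype(int), wide["T2"].astype(int))
print(f"  {'incat_arm':28s} kappa_w={kap.estimate:.2f} ({kap.rating})")

print("\ngroup comparison and ROC at T2 (impairment = positive class)")
for col in ROM_COLUMNS.values():
    w = welch_from_samples(
        t2.loc[t2.group == "impaired", col], t2.loc[t2.group == "control", col]
    )
    roc = roc_analysis(t2[col].to_numpy(), labels)
    print(f"  {col:28s} {w.mean1:6.1f} vs {w.mean2:6.1f} deg, p={w.p:.3f}; "
          f"AUC={roc.auc:.3f}, cutoff<={roc.cutoff:.1f} deg "
          f"(sens {roc.sensitivity:.2f} / spec {roc.specificity:.2f})")

comp = composite_roc(
    t2[list(ROM_COLUMNS.values())].reset_index(drop=True),
    labels,
    {c: True for c in ROM_COLUMNS.values()},
)
print(f"  composite z-score of the three patterns: AUC={comp.auc:.3f}")
# An ICC above 0.9 is rated excellent; an AUC near 0.8 means the glove
# separates impaired from non-impaired hands well at the study sample size.
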