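"""Pick an operating cutoff for a score without a published one.

Scans every candidate cutoff of the early-death index, printing weighted
sensitivity, specificity and Youden's J = sensitivity + specificity - 1
at each; the flagged row maximises J (lowest cutoff on ties), trading
missed deaths against false alarms symmetrically.
"""

from pewsval import CohortConfig, default_registry, generate_cohort
from pewsval.reporting import cutoff_scan

cohort = generate_cohort(CohortConfig(seed=42))
scan = cutoff_scan(default_registry()["PEDIA_early"], cohort)
print(scan.round(3).to_string(index=False))
best = scan[scan["optimal"]].iloc[0]
print(f"\nYouden-optimal cutoff: {int(best['cutoff'])} "
      f"(J = {best['youden_j']:.3f}); children scoring at or above it "
      "are flagged as at increased risk of inpatient death.")
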