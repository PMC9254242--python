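"""Generate a synthetic two-stage gastric-lesion cohort and look at its shape.

The bundle mirrors the design of a screening study: 200 discovery and 200
validation subjects along the SG -> CAG -> IM -> LGIN -> HGIN -> invasive GC
cascade, 624 plasma lipids (11 planted inverse markers), a prospectively
followed subset of 152 lesion subjects and pooled-plasma QC replicates.
"""

import numpy as np

from lipidcascade import GeneratorConfig, generate_cohort, progression_outcome

bundle = generate_cohort(GeneratorConfig(seed=1))
table = bundle.subject_table()

for cohort in ("discovery", "validation"):
    sub = table[table.cohort == cohort]
    print(f"{cohort}: n={len(sub)}, lesions={(sub.severity <= 4).sum()}, "
          f"HGIN={(sub.severity == 5).sum()}, invasive GC={(sub.severity == 6).sum()}")

print(f"lipid matrix: {bundle.lipids.values.shape} (mol/L), "
      f"planted signals: {bundle.truth['signal_ids'][:3]} ...")

subjects = {s.id: s for s in bundle.subjects["validation"]}
t = np.array([subjects[i].endpoint[0] for i in bundle.prospective_ids])
prog = np.mean([progression_outcome(subjects[i]) > 0
                for i in bundle.prospective_ids])
print(f"prospective cohort: n={len(t)}, median follow-up {np.median(t):.0f} days, "
      f"progression fraction {prog:.2f}")
# The progression fraction is the share of followed subjects whose endpoint
# histology is more severe than their baseline diagnosis.
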