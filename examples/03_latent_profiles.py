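"""Extract latent lipid profiles with the VAE + Elastic-Net procedure.

Many VAE fits are scored by how well their elastic-net-selected latent
dimensions linearly reconstruct the key lipids out of fold; the matrix with
the highest average R^2 wins. 10 repeats here (the full default is 200).
"""

import warnings

import numpy as np

warnings.simplefilter("ignore")

from lipidcascade import (GeneratorConfig, VAEConfig, generate_cohort,
                          log_normalize, vaen_run)

bundle = generate_cohort(GeneratorConfig(seed=1))
table = bundle.subject_table()
val_ids = table.index[table.cohort == "validation"]
X = log_normalize(bundle.lipids.subset(subject_ids=val_ids,
                                       lipid_ids=bundle.truth["signal_ids"]))
severity = table.loc[val_ids, "severity"].to_numpy(float)

profiles = vaen_run(X.values, response=severity, targets=X.values,
                    config=VAEConfig(n_repeats=10, seed=2))

print(f"winning repeat: {profiles.best_repeat} of 10, "
      f"average out-of-fold R^2 = {profiles.average_R2:.3f}")
print(f"selected latent dimensions: {profiles.selected_dims} "
      f"-> latent matrix {profiles.latent.shape}")
print(profiles.diagnostics[["repeat", "n_selected", "average_R2"]]
      .round(3).to_string(index=False))
# R^2 ~ 0.7 is the explainable ceiling here: the 11 signal lipids share about
# 55% common variance by construction, the rest is lipid-specific noise no
# latent code can reconstruct.
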