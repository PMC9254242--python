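"""Cluster subjects on latent lipid profiles and trace lesion-severity
trajectories over follow-up.

PAM (k-medoids) clusters the prospective subjects on their latent profiles,
the cluster count is chosen by silhouette, and each cluster gets a penalized
spline of severity against follow-up day plus a progression odds ratio versus
the lowest-risk cluster.
"""

import warnings

import pandas as pd

warnings.simplefilter("ignore")

from lipidcascade import (GeneratorConfig, VAEConfig, choose_k,
                          cluster_progression_or, fit_trajectories,
                          generate_cohort, log_normalize, pam_cluster,
                          progression_outcome, vaen_run)

bundle = generate_cohort(GeneratorConfig(seed=1))
table = bundle.subject_table()
val_ids = table.index[table.cohort == "validation"]
X = log_normalize(bundle.lipids.subset(subject_ids=val_ids,
                                       lipid_ids=bundle.truth["signal_ids"]))
profiles = vaen_run(X.values, table.loc[val_ids, "severity"].to_numpy(float),
                    X.values, VAEConfig(n_repeats=5, seed=3))

Z = profiles.latent.loc[bundle.prospective_ids]
k, sil = choose_k(Z, range(2, 7))
assign = pam_cluster(Z, k)
print(f"silhouette chose k={k}; mean widths per k: "
      + ", ".join(f"{kk}: {v:.2f}" for kk, v in sil.items()))

subjects = [s for s in bundle.subjects["validation"]
            if s.id in set(bundle.prospective_ids)]
flags = pd.Series({s.id: int(progression_outcome(s) > 0) for s in subjects})
rates = flags.groupby(assign.labels).mean().sort_values()
labels = assign.labels.map({old: new for new, old in
                            enumerate(rates.index, start=1)})

ors = cluster_progression_or(
    labels, flags, table.loc[flags.index][["age", "sex", "hp", "severity"]])
print("\ncluster progression ORs (cluster 1 = lowest observed risk):")
print(ors.round(3).to_string(index=False))
print(f"heterogeneity: ANOVA F = {ors.attrs['anova_F']:.2f} "
      f"(p = {ors.attrs['anova_p']:.2g})")

traj = fit_trajectories(subjects, labels)
print("\nper-cluster severity drift over follow-up (fitted end - start):")
print(traj.per_cluster_drift.round(2).to_string(index=False))
# A positive drift means the cluster's average lesion severity worsens over
# the follow-up window.
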