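# Methods

This note documents the statistical models implemented in `lipidcascade`,
the synthetic-cohort generator that drives them, the numerical choices made
where the design was genuinely open, and what the test suite does and does
not demonstrate about real data.

## The synthetic cohort

The generator (`lipidcascade.cohort`) emulates a two-stage targeted
lipidomics study of gastric precancerous lesions. Severity is coded 1–6 for
SG, CAG, IM, LGIN, HGIN and invasive GC; the analysis-level "GC group" is
severity ≥ 5. Default stage compositions are fixed counts: discovery
30/50/59/30/22/9 (169 lesions + 31 GC group) and validation
27/45/55/25/28/20 (152 lesions + 48 GC group), for 200 subjects per cohort.
The split of the lesion counts across SG/CAG/IM/LGIN is not dictated by the
study design and is configurable.

**Covariates.** Age is drawn around 45 + 2.2·severity (clipped to the
screening range 40–69), sex ~ Bernoulli(0.55), and *H. pylori* positivity is
logistic in severity around a high-prevalence baseline — so age and
*H. pylori* genuinely confound the lipid–outcome associations and the
adjusted models have something to adjust for.

**Lipids.** Abundances are generated directly on the log scale (no
simulation of spectra — that is out of scope) and exponentiated into mol/L
with per-lipid base levels spanning 1e-8–1e-4 mol/L and a log-scale SD of
`noise_sd` (default 0.5, a ~50% biological CV). The 624-lipid panel carries
a realistic class composition (199 TAG, 85+3 PC, 63 PE, …) and the 11
default signal lipids carry the names of known inverse markers of gastric
lesion progression (PC38:6(20:4), …, PA32:1). Signal lipids follow

    z_ij = −e′·z(severity_i) − c·u_i + w_g·g_i + w_e·ε_ij + a·z(age_i)

where `u` is the subject's latent progression risk, `g` a shared factor
drawn from a standardized Gaussian mixture over `n_clusters` planted
clusters (high-index clusters have higher risk and lower lipid levels), and
ε idiosyncratic noise. The weights solve a variance budget such that each
lipid has unit variance and every pair of signal lipids has exchangeable
correlation `signal_correlation` exactly (a quadratic in `w_g` because `u`
and `g` share the cluster direction). The severity slope e′ is calibrated so
that the *per-SD log-odds of the GC-vs-mild comparison* equals
`effect_size`: e′ = effect_size / Δz, with Δz the standardized severity gap
between the GC and mild groups under the configured stage distribution.
Because the grouped outcome is a mixture of stages, the logistic model is
mildly misspecified and the identity is second-order accurate; empirically
the adjusted estimate recovers the planted value well within 2 SE at
n ≈ 10⁴ (tested).

Defaults `effect_size = 1.3` (planted OR ≈ 0.27 per SD) and
`signal_correlation = 0.55` put the planted markers in the strong-biomarker
regime a two-stage design with an FDR gate can actually replicate: with only
11 non-null lipids among ~250 VIP survivors, Benjamini–Hochberg at q < 0.05
demands per-lipid p ≈ 0.002, i.e. |z| ≳ 3.5 at n = 200. Weaker plantings
(per-SD OR ≈ 0.5) make the discovery FDR gate the binding constraint and
whole cohorts fail it — a real feature of such designs, reproducible here by
lowering `effect_size`.

**Follow-up.** Times are log-normal with μ matched to the median (580 d) and
σ matched to the interquartile *width* (806 − 390 d) via the quantile
equations; median and IQR are the only two reported calibration targets and
a two-parameter family cannot match all three quartiles exactly (the implied
quartiles are ~410/824 d). The endpoint stage follows a transition model

    logit P(progress) = logit(base_rate) + γ·u + 0.5·(stage − 3)

with γ = 1 and base rate 0.25 (≈ 27% observed progression); non-progressors
regress one stage with probability logistic in −γ·u around 0.15, which keeps
the 3-level outcome proportional-odds-consistent. The severity term mirrors
the clinical fact (and the study structure) that baseline histology itself
predicts progression, giving the baseline prediction model genuine signal.
Stage-transition frequencies are not reported for the real cohort, so these
rates are tunable defaults, not calibrated quantities.

**Proteins.** For 104 validation subjects, 23 proteins (named after
lipid-metabolism proteins: PTGS1, ASAH1, …) are linear combinations of 1–3
linked signal lipids (the link table is emitted) plus Gaussian noise with SD
2.5. At n = 104 with an 11 × 23 CCA, even independent blocks yield a sample
first canonical correlation ≈ 0.70; the default noise places the coupled
generator's r₁ in the mid-0.8s — coupled, but in the weak-coupling regime a
cohort of this size actually operates in. Per-protein logistic associations
at this n and noise have limited power, so nominal (p < 0.05) counts are
more informative than FDR-surviving counts.

**What the generator does not emulate.** LC-MS artifacts (retention-time
drift, batch effects, censored low abundances, missingness), non-linear
lipid–outcome relationships, informative dropout during follow-up, and
between-lipid correlation structure beyond a single exchangeable block plus
shared factors. Tests passing on this generator show the *estimators* are
correct and the *design* behaves as analyzed — not that real plasma
lipidomics data satisfy these models.

## Analysis models and numerical choices

- **Log-normalization**: natural log, then per-lipid standardization with
  the population SD (divisor n) over the analysis cohort — applied per
  cohort, so ORs are per within-cohort SD. Zero-variance columns are flagged
  and set to NaN rather than fabricating a scale. The transform is a state
  machine: applying it twice is an error.
- **QC checks**: Spearman correlations (midranks for ties) among pooled
  plasma replicate rows, pass if min r ≥ 0.96; intensity drift relative to
  the first run ≤ 20%.
- **OPLS-DA VIP**: one predictive + one orthogonal component by default
  (NIPALS-style deflation); with a single predictive component
  VIP_j = √p·|w_j|, so ΣVIP² = p holds exactly. The component count is a
  convention; the gate VIP > 1 uses strict inequality, as do all p/q gates
  (a lipid exactly at a threshold is excluded).
- **Logistic/ordinal inference**: maximum likelihood with Wald CIs
  (symmetric on the log-odds scale, standard epidemiological reporting).
  Separation and non-convergence are detected (|β| > 15 or exploding SE) and
  raised as explicit errors; cluster models fall back to Firth's penalized
  likelihood (Jeffreys prior, damped Newton on the modified score). The
  ordinal model is a cumulative-logit proportional-odds fit with the
  3-level outcome ordered regression < no change < progression and the OR
  reported in the progression direction.
- **Meta-analysis**: fixed-effect inverse-variance pooling; with two stages
  a between-study variance is unidentifiable, so no random-effects variant.
- **VAE**: Gaussian encoder and decoder, one softplus hidden layer of width
  16, latent dimension 4, full-batch Adam (lr 0.01) for 500 epochs, KL
  weight 0.1. The mild KL weight reflects the latent matrix's role here as
  a denoised representation scored by reconstruction R², not a generative
  sampler; with unit KL weight the posterior over-regularizes an 11-input
  code and reconstruction quality caps well below the explainable variance.
  The latent representation passed downstream is the posterior mean, so
  clustering and scoring are deterministic given the seed. Losses are
  checked finite every step.
- **Elastic-net selection**: penalty by 5-fold CV minimum squared error at
  l1_ratio = α (default 0.5); a dimension counts as selected when its
  coefficient exceeds 5% of the largest absolute coefficient, which screens
  out the near-zero path coefficients the CV-minimum penalty retains (the
  1-SE rule alone recovers exact supports far less reliably). At the ridge
  boundary α = 0 all dimensions are returned. EN response and R² targets are
  configurable; the pipeline uses lesion severity (1–6) as the response and
  the key-lipid matrix as the multi-response target. With the default
  generator the winning average R² plateaus around 0.7 — the planted common
  variance of the signal lipids (≈ 0.55 exchangeable correlation plus shared
  severity/risk structure) is the ceiling; no latent code can reconstruct
  the idiosyncratic half of each lipid's variance.
- **PAM**: classic BUILD seeding plus steepest-descent SWAP on Euclidean
  distances, ties broken by lowest index; the objective is verified
  non-increasing and final medoid sets are locally optimal under single
  swaps. k is chosen over 2–8 by maximum mean silhouette (ties → smaller k).
  In the pipeline, cluster labels are re-ordered by ascending observed
  progression rate so cluster 1 is the low-risk reference.
- **Trajectories**: per-cluster penalized cubic B-spline GAM of severity on
  follow-up day (df ≤ 6, smoothing penalty by GCV over a log-spaced grid),
  pointwise ±2 SE bands, fits clipped to [1, 6]. Clusters with < 5 visit
  records or < 4 distinct days fall back to a flat mean with a warning.
- **Prediction**: XGBoost with depth 3, 200 rounds, learning rate 0.1,
  subsample/colsample 0.9, single thread (for bit-reproducibility). Fixed
  rounds rather than early stopping keep the harness deterministic and the
  comparison symmetric across arms. All AUCs are computed on stratified
  out-of-fold scores only; the risk score (forward stepwise by AIC, plus the
  always-emitted all-lipid model) is refit inside each training fold.
  Leakage is asserted (train ∩ test = ∅) on every fold. AUC CIs use the
  single-model DeLong variance.
- **CCA**: generalized symmetric eigenproblem on the within/cross
  covariances of standardized blocks; a relative ridge of 1e-6 is added only
  when a within-set covariance is numerically near-singular (warned). Wilks'
  λ = Π(1 − rᵢ²) exactly; its default inference is a permutation test of the
  protein rows with B = 999 (minimum attainable p = 0.001), with Rao's F
  approximation emitted alongside; sequential dimensionality uses the HLT F
  approximation on the trailing correlations.
- **Seeds**: one master seed per run; per-component streams are derived via
  `numpy` SeedSequence spawning, so adding a stage never perturbs another
  stage's draws. The orchestrated pipeline writes a manifest of content
  hashes; two runs with the same config and seed are byte-identical (wall
  times go to a separate log outside the hashed set).

## Problem sizes used by the tests and the acceptance script

The test suite runs every recovery and null simulation at sizes chosen for a
single CPU: cascade sensitivity and null false-survivor rates over 12 seeds
at full study scale (624 lipids, 200 + 200 + 152 subjects), Wilks-p
uniformity over 100 seeds with 199 permutations, the latent-factor recovery
at 20 VAE repeats (the analysis default is 200), the DeLong-vs-bootstrap
check at 10⁴ resamples of n = 200, and parameter-recovery fits at n = 5000.
The acceptance script runs the full pipeline once at study scale with 20 VAE
repeats and 999 permutations. Repeat counts are sizes, not tuning knobs: the
thresholds they are checked against are stated properties of the design.

## Known limitations

- The per-SD OR calibration is exact only for a two-group Gaussian
  discriminant structure; with six stages collapsed into groups it is
  accurate to second order (well within 2 SE at any realistic n).
- Missing abundances are not supported; the generator emits complete data
  and the transform errors on missingness rather than imputing.
- The VAE is a small fully-connected network with manual gradients; it is
  not meant for wide omics matrices or GPU-scale training.
- Sample canonical correlations at n ≈ 100 with 30+ variables are strongly
  biased upward; interpret CCA output through the permutation and HLT tests,
  not the raw correlations.
- The prediction harness evaluates discrimination only; no calibration
  analysis or hyperparameter search is included.
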