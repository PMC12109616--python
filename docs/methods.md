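# Methods

## Mixture model and bimodal index

Expression of one gene across a cohort is modeled as a two-component Gaussian
mixture with a shared variance: x ~ (1 − π)·N(μ₁, σ²) + π·N(μ₂, σ²). The
equal-variance restriction is what makes the dichotomization cutoff closed-form
and the bimodal index interpretable; it is also the model under which the EM
posterior is exactly logistic in x, which the implementation exploits (the
E-step and log-likelihood reduce to sufficient statistics, with a numba-jitted
per-gene kernel and a numerically identical pure-numpy path that remains the
reference implementation).

Fitting is plain EM, best of three starts initialized by quantile splits at
π₀ ∈ {0.25, 0.5, 0.75}. Convergence is a relative log-likelihood change below
1e-8 (cap 500 iterations; non-convergence is flagged, not raised). A σ floor of
1e-6 × SD(x) prevents variance collapse. Components are relabeled so μ₁ ≤ μ₂;
"high" is always the larger-mean component, and prognostic direction is
inferred downstream rather than assumed. Constant or shorter-than-10 input is a
degenerate-input error.

The bimodal index BI = δ·√(π(1−π)), δ = (μ₂−μ₁)/σ, summarizes separation and
balance together. One behavior worth knowing: for data from a *single*
Gaussian, the mixture MLE does not sit near δ = 0 at realistic n — it splits
the sample into two close halves (δ̂ ≈ 1.27, BI ≈ 0.64 at n = 1000–2000;
R mclust's equal-variance model reproduces the same values). δ̂ approaches the
δ = 0 boundary only at the n^(−1/4) rate. Unimodal genes therefore carry BI
around 0.6–1.1 at cohort sizes of ~100–300, which is why a single-cohort BI
ranking is noisy: in roughly one run in five a null gene out of 200 outscores a
true BI-1.37 target at n = 135. The study-level screen ranks genes by the
*median* BI across cohorts, which suppresses these cohort-idiosyncratic splits
(median null BI ≈ 0.86 vs ≈ 1.43 for the target) — consistent bimodality
across studies is the signal of interest in a multi-cohort design.

Dichotomization methods: *cluster* (threshold at the posterior-0.5 crossing
x\* = (μ₁+μ₂)/2 + σ²·ln((1−π)/π)/(μ₂−μ₁), equivalent to maximum-posterior
labels), *median* (ties at the median go low), and *quantile band* (strictly
above the hi quantile = high, strictly below the lo quantile = low, middle
excluded; type-7 linear-interpolation quantiles, so 100 distinct values under
the 0.8/0.7 defaults give exactly 20 high and 70 low).

## Survival modelling and pooling

Per cohort, Cox proportional-hazards fits use Newton–Raphson with step-halving
on the Efron-corrected partial likelihood; standard errors come from the
observed information and p-values are two-sided Wald. The solver is vectorized
(risk sets via cumulative sums over descending time, tied-event corrections via
`reduceat`), agrees with lifelines to ~1e-4 (lifelines' own convergence
tolerance), and runs in ~3 ms for n = 300, which is what makes the
replicate-heavy validation loops feasible. Monotone likelihoods (complete
separation) are reported as flagged non-convergent effects with an infinite
|log-HR| sentinel and excluded from pooling; fewer than two events is a
not-estimable error; collinear designs are a rank-deficiency error.
Kaplan–Meier estimation and the two-group log-rank test delegate to lifelines.

Cohort effects are pooled on the log-HR scale by DerSimonian–Laird random
effects: fixed-effect weights wᵢ = 1/seᵢ² give Q; τ² = max(0, (Q − (k−1)) /
(Σw − Σw²/Σw)); re-weighting by 1/(seᵢ² + τ²) gives the pooled estimate, its
SE, and a Wald p. I² = max(0, (Q − (k−1))/Q). DL is the classical default of
the meta-analysis literature; the implementation is the explicit formulas and
is cross-checked against `statsmodels.stats.meta_analysis.combine_effects` in
the tests. The dual-mode screen excludes cohorts with fewer than `min_n = 10`
patients before fitting and logs every exclusion.

Calibration of the pooled CI is validated with Cox fits on the *true* latent
component: dichotomizing by the fitted mixture attenuates the coefficient
(nondifferential misclassification; ≈ 14% of β at Δ = 3, π = 0.3), so
coverage of the generative β is a property of the meta-analysis machinery, not
of the dichotomization, and is tested as such. The dichotomization itself is
validated by the cluster-vs-median comparison (the cluster cutoff yields a
larger pooled |log-HR| than the median split in ~100% of replicate studies at
π = 0.2) and by the end-to-end loop, where the attenuated binary-mode effect
remains overwhelmingly significant.

## Genotype, association and enrichment screens

KEAP1/STK11 functional loss is the union of evidence sources: a retained
(non-excluded-class) mutation, copy number strictly below −1, the gene at a
fusion/translocation breakpoint, an RPPA protein level below the cutoff of a
bimodal mixture fit of the protein distribution, or a pre-classified external
call. Evidence union means added sources can only turn not-loss into loss,
never the reverse. A degenerate RPPA distribution drops only the RPPA
evidence, with a warning. The four-way oncogenotype partition (WT / single /
single / double) follows directly.

The Mann–Whitney U test uses scipy's exact distribution when n₁·n₂ ≤ 400 and
the pooled sample is tie-free; with ties, small cases (C(n, n₁) ≤ 2·10⁵) are
enumerated exactly over all group labelings; everything else uses the
tie-corrected normal approximation with continuity correction. Exact two-sided
p-values of a discrete statistic are superuniform (conservative) by
construction, so null calibration is asserted as a KS uniformity check on the
fine-grained asymptotic path plus validity (P(p ≤ α) ≤ α) on the exact path.
The oncogenotype screen gates candidates at ≥ 9 mutant samples (reported as
untested, not dropped) and reports both nominal and BH-adjusted p-values,
filtering on neither.

Pearson correlations use the exact t-transform with n − 2 df; zero-variance
features are flagged rather than dropped so output row counts are predictable.
The metabolite model is OLS of metabolite on expression-group + KEAP1 + STK11
with the expression-group term as the headline value. Pathway
over-representation is the upper-tail hypergeometric P(X ≥ k) after
intersecting sets with the universe, BH-adjusted across sets.

GSEA ranks genes by signal-to-noise (μ_A − μ_B)/(σ_A + σ_B) with per-class SD
floors σ ← max(σ, 0.2·|μ|, 0.2) (the convention of the original
implementation), ties broken by gene id for determinism. The enrichment score
is the maximum-magnitude excursion of the running sum with |metric|^w hit
increments (w = 1 by default) and 1/(N − N_H) miss decrements; the leading
edge is the set members at or before the extremum (at or after, for negative
ES). Significance permutes sample labels (n_perm = 1000 by default; pipelines
use 200): p = (1 + #{same-sign |ES_perm| ≥ |ES|}) / (1 + #{same-sign
ES_perm}), never zero; NES divides by the mean same-sign |ES_perm|. Set-size
filter [5, 500] after universe intersection.

## Synthetic studies

The generator emulates the structure the analysis assumes, per sample:
component z ~ Bernoulli(π); expression x = μ_low + zΔ + N(0, σ²); event time
~ Exponential(λ₀·e^{βz}) censored at min(administrative horizon, random
exponential censoring); KEAP1/STK11 mutations ~ Bernoulli(q_high if z else
q_low) plus background-mutated null candidate genes independent of z (so the
oncogenotype screen has a null field); metabolite = α + b·x + γ_K·mutK +
γ_S·mutS + N(0, τ²); null genes i.i.d. N(μ_low + Δπ, σ²). The exponential
baseline is chosen for closed-form checkability (the KM curve of the z = 0
stratum must track e^{−λ₀t}); the analysis itself only assumes proportional
hazards.

Defaults mirror the multi-cohort design the pipeline targets: 23 cohorts of
135 samples (~3100 cases total), mixture (μ_low 0, Δ 3, σ 1, π 0.3),
component log-HR ln 2, baseline hazard 0.1/year with a 10-year administrative
horizon and 0.05/year random censoring, mutation coupling q_high = 0.5 /
q_low = 0.05 with 50 null candidates at background rate 0.1, metabolite slope
0.5 with genotype effects 0.5 and unit noise. Cohorts draw from independent
`SeedSequence(seed, spawn_key=(cohort_index,))` substreams, so any subset of
cohorts regenerates bit-identically.

What the generator does *not* emulate — RNA-seq count noise, batch effects,
gene–gene correlation among nulls, copy-number-driven expression, informative
censoring — bounds what passing tests show about real data: they validate the
statistical machinery under the model's own assumptions, not robustness to
real-data artifacts.

## Numerical and validation choices

* Quantile normalization maps every column to the mean quantile profile; tied
  values receive the mean of the tied positions' quantile means. The operation
  is exactly idempotent on tie-free columns; tie-averaging perturbs per-column
  multisets, so idempotence with ties is approximate.
* All validation loops state their problem sizes: mixture recovery at
  n = 2000; cluster-vs-median over 200 replicate 10-cohort studies
  (n = 300, π = 0.2, Δ = 3, component HR 2.5); meta coverage over 100
  replicate 10-cohort studies; the end-to-end loop over 100 seeds of the
  default 23-cohort study, with the BI ranking computed from the first 7
  cohorts' median (ample margin at a fraction of the cost); GSEA null
  calibration from 5 × 100 null sets at 200 permutations.
* The pipeline's single master seed feeds named substreams per stage; run
  manifests record thresholds, seed, and sha256 hashes of every output.

## Limitations

Two mixture components only (no model selection over component counts or
unequal variances); no proportional-hazards diagnostics, time-varying
covariates, or competing risks; GSEA has no gene-permutation mode or FDR
q-values (nominal permutation p only); immune-infiltrate or other external
covariates are consumed as given, never deconvolved; the multi-study
leading-edge utility simply counts genes appearing in ≥ 2 leading-edge lists.
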