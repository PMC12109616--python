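# bimeta

Bimodal gene-expression biomarker discovery with multi-cohort survival
meta-analysis, oncogenotype screening, metabolite association, and gene set
enrichment — built for the common tumor-transcriptomics situation where a gene
(the motivating case is *KYNU*, kynureninase, in lung adenocarcinoma) is
expressed either very high or very low across tumors, and the two expression
states carry different prognoses and different driver-mutation backgrounds
(e.g. *KEAP1*/*STK11* loss).

## The model

Each gene's expression across a cohort is fitted with a two-component
equal-variance Gaussian mixture

x ~ (1 − π)·N(μ₁, σ²) + π·N(μ₂, σ²),  μ₁ ≤ μ₂,

by multi-start EM. Bimodality is quantified by the **bimodal index**

BI = δ·√(π(1 − π)),  δ = (μ₂ − μ₁)/σ,

which is large only when the components are both separated and reasonably
balanced. Samples are dichotomized at the posterior-0.5 crossing, which for
equal variances has the closed form

x\* = (μ₁ + μ₂)/2 + σ²·ln((1 − π)/π)/(μ₂ − μ₁),

or alternatively by the median or by a quantile band (> 80th percentile high,
< 70th percentile low, middle excluded).

Survival association is estimated per cohort by Cox proportional-hazards
regression (Newton maximization of the Efron-corrected partial likelihood,
observed-information standard errors) in two modes — binary (mixture
dichotomization) and continuous (per-gene z-scores) — and pooled across
cohorts by DerSimonian–Laird random-effects meta-analysis on the log-HR scale
(τ², Q, I² reported; cohorts with < 10 patients excluded). Downstream screens
cover: Mann–Whitney U mutation-vs-expression testing with a ≥ 9-mutant gate
and Benjamini–Hochberg adjustment; multi-evidence KEAP1/STK11 loss calling
(mutation, copy number < −1, fusion breakpoint, bimodal RPPA split); Pearson
correlation screens (optionally stratified or within dichotomy groups);
one-way ANOVA and adjusted OLS metabolite models; hypergeometric pathway
over-representation; and GSEA with signal-to-noise ranking and sample-label
permutation p-values.

A first-class synthetic-study generator produces multi-cohort datasets with
exactly this structure (mixture-distributed target gene, proportional-hazards
survival, component-coupled mutations, linearly coupled metabolites, unimodal
null genes) from reproducible per-cohort seed substreams, so the whole
pipeline is testable without any external data.

## Worked example

```python
from bimeta import SyntheticConfig, simulate_study, screen_bimodal_study, run_survival_screen

study = simulate_study(SyntheticConfig(n_cohorts=8, n_samples=150, seed=11))
ranking = screen_bimodal_study([c.expression for c in study.cohorts])
print(ranking.iloc[0][["gene", "BI"]].tolist())

screen = run_survival_screen(study.survival_inputs(), ["KYNU"], min_n=10)
meta = screen.results["KYNU"].meta_binary
print(f"HR={meta.pooled_hr:.2f} p={meta.pooled_p:.2e} k={meta.k}")
```

Running `python examples/02_survival_meta.py` prints

```
    binary: HR = 1.87 (95% CI 1.57-2.23), p = 2.44e-12, tau2 = 0.009, I2 = 0.14, k = 8
continuous: HR = 1.33 (95% CI 1.23-1.44), p = 1.05e-12, tau2 = 0.001, I2 = 0.11, k = 8
```

— the binary-mode pooled hazard ratio estimates the generative
between-component HR of 2.0 (mildly attenuated by dichotomization
misclassification), and the continuous coefficient is per SD of expression.
The `examples/` directory has one short script per capability (bimodal
screen, survival meta-analysis, genotype screen, associations, GSEA, full
pipeline); each builds a small synthetic input, runs the method, and explains
the numbers it prints.

A thin CLI wraps the same library calls:

```bash
bimeta simulate --outdir study --seed 1 --n-cohorts 5 --n-samples 150
bimeta run-all --outdir run --seed 1        # or --config run.yaml, --skip gsea
```

Every run writes a `manifest.json` with sha256 hashes of all outputs;
identical config + seed reproduces the hashes bit-for-bit.

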