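"""Rank genes by bimodal index across a small simulated multi-cohort study.

The target gene is drawn from a two-component mixture (Delta = 3 sigma,
pi = 0.3) and should top the ranking; the null genes are unimodal Gaussians
whose fitted indices stay well below it.
"""

from bimeta import SyntheticConfig, screen_bimodal_study, simulate_study

config = SyntheticConfig(n_cohorts=5, n_samples=150, n_null_genes=50, seed=7)
study = simulate_study(config)

ranking = screen_bimodal_study([c.expression for c in study.cohorts])
print(ranking.head(5)[["gene", "BI", "BI_iqr_low", "BI_iqr_high", "n_converged"]]
      .to_string(index=False))

top = ranking.iloc[0]
print(f"\nTop gene: {top['gene']} with median BI = {top['BI']:.2f} across "
      f"{int(top['n_cohorts'])} cohorts.")
print("BI = delta * sqrt(pi(1-pi)); values above ~1.1 indicate a split worth "
      "dichotomizing, and the truly bimodal target clears the unimodal field.")
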