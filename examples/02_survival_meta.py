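"""Dual-mode survival screen: per-cohort Cox fits pooled by random effects.

Binary mode dichotomizes each cohort at the fitted mixture cutoff; continuous
mode uses z-scored expression. Both are pooled on the log hazard-ratio scale
with DerSimonian-Laird weights.
"""

import numpy as np

from bimeta import SyntheticConfig, run_survival_screen, simulate_study

config = SyntheticConfig(n_cohorts=8, n_samples=150, n_null_genes=5, seed=11)
study = simulate_study(config)

screen = run_survival_screen(study.survival_inputs(), ["KYNU"], min_n=10)
result = screen.results["KYNU"]

for mode, meta in (("binary", result.meta_binary),
                   ("continuous", result.meta_continuous)):
    lo, hi = meta.ci()
    print(f"{mode:>10}: HR = {meta.pooled_hr:.2f} "
          f"(95% CI {np.exp(lo):.2f}-{np.exp(hi):.2f}), "
          f"p = {meta.pooled_p:.2e}, tau2 = {meta.tau2:.3f}, "
          f"I2 = {meta.I2:.2f}, k = {meta.k}")

print("\nThe generative hazard ratio between mixture components is 2.0; the "
      "binary-mode pooled HR estimates it directly (attenuated only by the "
      "small dichotomization misclassification), while the continuous-mode "
      "coefficient is per SD of expression and therefore smaller.")
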