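"""Call tumor-suppressor loss status and screen mutations against expression.

KEAP1/STK11 loss is the union of evidence (mutation, deep copy-number loss,
fusion breakpoint, low RPPA protein); mutants are then compared with wild-type
target-gene expression by Mann-Whitney U with a >= 9-mutant gate and BH
adjustment.
"""

import pandas as pd

from bimeta import (
    SyntheticConfig,
    assign_genotype_group,
    call_tsg_status,
    oncogenotype_screen,
    simulate_study,
)

config = SyntheticConfig(n_cohorts=1, n_samples=200, n_null_genes=5, seed=3)
cohort = simulate_study(config).cohorts[0]

status = call_tsg_status(cohort.expression.sample_ids,
                         mutations=cohort.mutations)
groups = assign_genotype_group(status)
print("Oncogenotype counts:")
print(groups.value_counts().to_string())

candidates = sorted(set(cohort.mutations.data["gene"]))
hits = oncogenotype_screen(cohort.expression, "KYNU", cohort.mutations,
                           candidates, min_mut=9)
tested = hits[hits.tested]
with pd.option_context("display.float_format", "{:.3g}".format):
    print("\nTop screen hits (mutant vs wild-type expression):")
    print(tested.head(4)[["gene", "n_mut", "n_wt", "U", "p", "p_adj",
                          "direction"]].to_string(index=False))

print("\nKEAP1 and STK11 mutations are enriched in the expression-high mixture "
      "component by construction, so they dominate the screen; background-"
      "mutated null genes stay near p ~ uniform.")
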