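"""Benchmark a linear against a non-linear classifier on epistatic data.

Generates a threshold-epistasis cohort (the hardest form for linear
models: penetrance takes just two levels, so marginal per-allele effects
carry only part of the signal), then evaluates L1-logistic regression and
gradient-boosted trees with repeated stratified 60:40 holdout.
"""

import warnings

warnings.filterwarnings("ignore")

from epibench import cross_validate, gametes_experiment, theoretical_auc
from epibench import LinearEffectModel, MixedPhenotypeModel
import numpy as np

cohort = gametes_experiment("threshold", target_h2=0.25, mafs=(0.25, 0.25),
                            replicates=1, n=4_000, total_snps=100, seed=7)[0]

for family in ("lasso_logistic", "gradient_boosting"):
    report = cross_validate(family, cohort, cycles=3, seed=1)
    agg = report.aggregate["auc_roc"]
    print(f"{family:20s} AUC-ROC = {agg['mean']:.3f} ± {agg['sd']:.3f}")

from epibench import solve_penetrance

table = solve_penetrance("threshold", (0.25, 0.25), 0.25)
model = MixedPhenotypeModel(alpha=0.0,
                            linear=LinearEffectModel(0.0, np.empty(0)),
                            epistatic=table, linear_columns=(),
                            epistatic_columns=(0, 1))
print(f"{'theoretical ceiling':20s} AUC-ROC = "
      f"{theoretical_auc(model, 'exact'):.3f}")
print("\nBoosted trees recover most of the interaction signal; the")
print("linear model captures only the marginal allele effects.")
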