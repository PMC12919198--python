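"""Inverse-probability weights and the weighted finite population bootstrap.

IPTW makes the two period exposures independent of their measured
confounders; the final analysis weight multiplies in the survey sampling
weight. WFPBB then converts the weighted sample into unit-weight replicates
whose means are unbiased for the Hajek (weighted) mean.
"""

import numpy as np

import lifecourse as lc

cohort, _ = lc.generate_cohort(lc.GeneratorConfig(n_subjects=2000, seed=11))
ws = lc.compute_weights(cohort, covariate_set="base", exposure="cumulative")
diag = lc.weight_diagnostics(ws)

print("stabilized total IPTW: mean "
      f"{diag['iptw_total']['mean']:.3f} (should be ~1), "
      f"max {diag['iptw_total']['max']:.2f}")
print(f"Kish effective sample size of the final weight: "
      f"{diag['final_weight']['kish_ess']:.0f} of {len(cohort)}")

reps = lc.generate_replicates(ws.final_weight, n_replicates=200, seed=12)
y = cohort["outcome"].to_numpy()
rep_means = np.array([y[r.indices].mean() for r in reps])
hajek = (ws.final_weight * y).sum() / ws.final_weight.sum()
print(f"average replicate mean {rep_means.mean():.4f} vs Hajek weighted mean {hajek:.4f}")
# Agreement between the two demonstrates that the Polya-urn expansion plus
# equal-size redraw preserves the weighted population structure while giving
# every subject unit weight, which is what lets an unweighted Bayesian model
# be fitted on each replicate.
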