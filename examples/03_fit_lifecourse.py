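"""Fit the Bayesian relevant life-course model and read off the estimand.

The outcome model is E(Y|Child,Adult) = beta0 + delta*(w*Child + (1-w)*Adult)
with w in [0,1]: delta is the life-course effect of one unit of weighted
adversity and (w, 1-w) are the childhood/adulthood contributions. The
posterior is pooled over WFPBB replicates.
"""

import lifecourse as lc

cohort, truth = lc.generate_cohort(
    lc.GeneratorConfig(n_subjects=2000, seed=1, truth_beta0=0.0, truth_delta=1.0,
                       truth_w_childhood=0.8, residual_sd=1.0)
)
ws = lc.compute_weights(cohort)
pooled, fit = lc.fit_wfpbb(cohort, ws.final_weight, n_replicates=50, seed=3)

print(f"delta: {fit.delta_mean:.3f} years per unit "
      f"(95% CrI {fit.delta_cri[0]:.3f}, {fit.delta_cri[1]:.3f}; truth {truth.delta})")
print(f"PP(delta > 0) = {fit.pp_delta_gt0:.3f}")
print(f"w_childhood: {fit.w_childhood_mean:.3f} "
      f"(95% CrI {fit.w_childhood_cri[0]:.3f}, {fit.w_childhood_cri[1]:.3f}; "
      f"truth {truth.w_childhood})")
print(f"w_adulthood: {fit.w_adulthood_mean:.3f}")

ed = lc.ed_posterior(pooled)
print("ED posterior means:", {k: round(v, 3) for k, v in ed.mean.items()})
print(f"most compatible non-pathway hypothesis: {ed.most_compatible}")
# A PP near 1 is strong evidence that adversity increases age acceleration;
# the reference vector with the smallest posterior-mean Euclidean distance to
# (w, 1-w) names the best-fitting life-course hypothesis.
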