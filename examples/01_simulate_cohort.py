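"""Generate a synthetic life-course cohort and inspect its margins.

The generator draws subjects along the assumed causal graph (baseline
confounders -> childhood adversity -> education/income -> adulthood
adversity -> epigenetic age acceleration) and returns the ground truth that
downstream stages should recover.
"""

import lifecourse as lc

cfg = lc.GeneratorConfig(n_subjects=5000, seed=7, truth_delta=0.9, truth_w_childhood=0.2)
cohort, truth = lc.generate_cohort(cfg)

print(f"subjects: {len(cohort)}")
print(f"childhood deprivation prevalence: {cohort['child_deprivation'].mean():.3f} "
      f"(target {cfg.prevalence[('child', 'deprivation')]})")
print(f"adulthood deprivation prevalence: {cohort['adult_deprivation'].mean():.3f} "
      f"(target {cfg.prevalence[('adult', 'deprivation')]})")
print(f"cumulative score distribution (childhood): "
      f"{cohort['child_score'].value_counts(normalize=True).sort_index().round(3).to_dict()}")
print(f"ground truth: delta={truth.delta} (years per unit weighted adversity), "
      f"w_childhood={truth.w_childhood}, w_adulthood={truth.w_adulthood}")
# The outcome here plays the role of AgeAccelGrim: the residual, in years, of
# epigenetic age regressed on chronological age. delta is the causal effect of
# one unit of the weighted life-course adversity score on that residual.
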