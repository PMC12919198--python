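"""Conventional marginal structural model as a cross-check of the Bayesian fit.

A weighted linear regression of the outcome on the childhood and adulthood
exposures, using the final analysis weight (IPTW x sampling weight),
estimates period-specific effects beta_child and beta_adult. Their sum is
the additive life-course effect and, when both share a sign, the normalized
betas are implied period weights comparable to the Bayesian posterior
weights. Robust (HC1 sandwich) standard errors are reported alongside
subject-level bootstrap CIs with within-replicate weight re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .weights import (
    FittingError,
    PositivityError,
    _exposure_columns,
    compute_weights,
)


@dataclass
class MSMResult:
    beta_child: float
    beta_adult: float
    lifecourse_effect: float
    implied_w_childhood: float | None   # None when the betas disagree in sign
    robust_se: dict
    beta_child_ci: tuple[float, float] | None = None
    beta_adult_ci: tuple[float, float] | None = None
    lifecourse_ci: tuple[float, float] | None = None
    n_boot: int = 0
    exposure: str = "cumulative"
    outcome: str = "outcome"

    def to_dict(self) -> dict:
        return {
            "beta_child": self.beta_child,
            "beta_adult": self.beta_adult,
            "lifecourse_effect": self.lifecourse_effect,
            "implied_w_childhood": self.implied_w_childhood,
            "robust_se": self.robust_se,
            "ci_95": {
                "beta_child": list(self.beta_child_ci) if self.beta_child_ci else None,
                "beta_adult": list(self.beta_adult_ci) if self.beta_adult_ci else None,
                "lifecourse_effect": list(self.lifecourse_ci) if self.lifecourse_ci else None,
            },
            "n_boot": self.n_boot,
            "exposure": self.exposure,
            "outcome": self.outcome,
        }


def _wls_betas(cohort: pd.DataFrame, w: np.ndarray, exposure: str, outcome_col: str):
    child_col, adult_col, _ = _exposure_columns(exposure)
    X = sm.add_constant(cohort[[child_col, adult_col]].to_numpy(float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular MSM design (no exposure variation)")
    return sm.WLS(cohort[outcome_col].to_numpy(float), X, weights=w).fit()


def fit_msm(
    cohort: pd.DataFrame,
    final_weights: np.ndarray | None = None,
    exposure: str = "cumulative",
    outcome_col: str = "outcome",
    n_boot: int = 200,
    seed: int | None = 0,
    covariate_set: str = "base",
    stabilized: bool = True,
) -> MSMResult:
    """Weighted least squares of the outcome on (child, adult) exposure scores.

    When ``final_weights`` is None they are estimated from the cohort. The
    bootstrap (set ``n_boot=0`` to skip) resamples subjects and re-estimates
    the weights inside each replicate.
    """
    if final_weights is None:
        final_weights = compute_weights(
            cohort, covariate_set=covariate_set, exposure=exposure, stabilized=stabilized
        ).final_weight
    fit = _wls_betas(cohort, np.asarray(final_weights, float), exposure, outcome_col)
    robust = fit.get_robustcov_results(cov_type="HC1")
    bc, ba = float(fit.params[1]), float(fit.params[2])
    total = bc + ba
    implied = bc / total if (bc * ba > 0 or (bc >= 0 and ba >= 0 and total != 0)) else None

    cis = {}
    kept = 0
    if n_boot >= 2:
        rng = np.random.default_rng(seed)
        n = len(cohort)
        rows = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            boot = cohort.iloc[idx].reset_index(drop=True)
            try:
                w = compute_weights(boot, covariate_set=covariate_set,
                                    exposure=exposure, stabilized=stabilized).final_weight
                f = _wls_betas(boot, w, exposure, outcome_col)
            except (FittingError, PositivityError, ValueError):
                continue
            rows.append([f.params[1], f.params[2], f.params[1] + f.params[2]])
        if len(rows) >= 2:
            arr = np.asarray(rows)
            lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
            cis = {
                "beta_child": (float(lo[0]), float(hi[0])),
                "beta_adult": (float(lo[1]), float(hi[1])),
                "lifecourse": (float(lo[2]), float(hi[2])),
            }
            kept = len(rows)

    se = np.asarray(robust.bse)
    return MSMResult(
        beta_child=bc,
        beta_adult=ba,
        lifecourse_effect=total,
        implied_w_childhood=None if implied is None else float(implied),
        robust_se={"beta_child": float(se[1]), "beta_adult": float(se[2])},
        beta_child_ci=cis.get("beta_child"),
        beta_adult_ci=cis.get("beta_adult"),
        lifecourse_ci=cis.get("lifecourse"),
        n_boot=kept,
        exposure=exposure,
        outcome=outcome_col,
    )
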