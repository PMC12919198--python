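"""Weighting-based causal mediation of childhood adversity through adulthood adversity.

Adulthood adversity is an intermediate on the path from childhood adversity
to the outcome, and its confounders (own education, household income) are
themselves affected by childhood adversity. Natural direct/indirect effects
are not identified under such exposure-induced mediator-outcome confounding,
so the randomized interventional analogues are estimated instead: the
mediator is drawn from its interventional distribution P(M | A = a) rather
than its subject-specific natural value. Confounding is handled by the final
analysis weight (IPTW x sampling weight), not by regression adjustment.

With a 4-level mediator the analogue effects have exact closed forms:

    rNDE = sum_m [E(Y | a, m) - E(Y | a*, m)] P(M = m | a*)
    rNIE = sum_m  E(Y | a, m) [P(M = m | a) - P(M = m | a*)]
    TE   = rNDE + rNIE                      (additive by construction)

E(Y | a, m) comes from a weighted linear outcome model with an optional
exposure-mediator interaction; P(M | a) from a saturated weighted multinomial
model (weighted empirical frequencies within exposure level). CIs are
percentile bootstrap over subjects, with the analysis weights re-estimated
inside every bootstrap replicate so that weight-estimation uncertainty is
propagated.
"""

from __future__ import annotations

import warnings
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


class DegenerateSampleError(ValueError):
    """A (re)sample lacks the exposure or mediator variation the estimator needs."""


@dataclass
class MediatorModel:
    """Interventional mediator distribution P(M = m | A = a), saturated in A."""

    levels: np.ndarray                 # mediator levels m
    probs: dict                        # exposure level a -> P(M = . | a)

    def p_given(self, a) -> np.ndarray:
        if a not in self.probs:
            raise DegenerateSampleError(
                f"exposure level {a!r} absent from the data; observed: {sorted(self.probs)}"
            )
        return self.probs[a]


@dataclass
class OutcomeModel:
    """Weighted linear model E[Y | A, M] = th0 + th1 A + th2 M (+ th3 A M)."""

    params: np.ndarray
    interaction: bool

    def predict(self, a: float, m: np.ndarray) -> np.ndarray:
        m = np.asarray(m, float)
        mu = self.params[0] + self.params[1] * a + self.params[2] * m
        if self.interaction:
            mu = mu + self.params[3] * a * m
        return mu


@dataclass
class MediationResult:
    """TE / rNDE / rNIE for the contrast a vs a*, with percentile bootstrap CIs."""

    a: float
    a_star: float
    te: float
    rnde: float
    rnie: float
    te_ci: tuple[float, float] | None = None
    rnde_ci: tuple[float, float] | None = None
    rnie_ci: tuple[float, float] | None = None
    n_boot: int = 0
    n_skipped: int = 0
    interaction: bool = True
    exposure: str = "cumulative"
    outcome: str = "outcome"

    def to_dict(self) -> dict:
        d = {
            "contrast": {"a": self.a, "a_star": self.a_star},
            "te": {"estimate": self.te, "ci_95": list(self.te_ci) if self.te_ci else None},
            "rnde": {"estimate": self.rnde, "ci_95": list(self.rnde_ci) if self.rnde_ci else None},
            "rnie": {"estimate": self.rnie, "ci_95": list(self.rnie_ci) if self.rnie_ci else None},
            "n_boot": self.n_boot,
            "n_skipped": self.n_skipped,
            "interaction": self.interaction,
            "exposure": self.exposure,
            "outcome": self.outcome,
        }
        return d


def fit_mediator_model(
    exposure: np.ndarray, mediator: np.ndarray, weights: np.ndarray
) -> MediatorModel:
    """Saturated weighted multinomial model of the mediator given the exposure.

    Weighted empirical frequencies within each exposure level are the MLE of
    the saturated multinomial logistic model, so no iterative fit is needed.
    """
    a = np.asarray(exposure)
    m = np.asarray(mediator)
    w = np.asarray(weights, float)
    levels = np.unique(m)
    probs = {}
    for val in np.unique(a):
        sel = a == val
        tot = w[sel].sum()
        if tot <= 0:
            raise DegenerateSampleError(f"no weight at exposure level {val!r}")
        probs[val] = np.array([w[sel & (m == lv)].sum() / tot for lv in levels])
    return MediatorModel(levels=levels, probs=probs)


def fit_outcome_model(
    exposure: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    weights: np.ndarray,
    interaction: bool = True,
) -> OutcomeModel:
    """Weighted least squares of Y on A, M and (optionally) A x M."""
    a = np.asarray(exposure, float)
    m = np.asarray(mediator, float)
    cols = [np.ones_like(a), a, m] + ([a * m] if interaction else [])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateSampleError("outcome model design is rank deficient")
    fit = sm.WLS(np.asarray(outcome, float), X, weights=np.asarray(weights, float)).fit()
    return OutcomeModel(params=np.asarray(fit.params), interaction=interaction)


def estimate_effects(
    mediator_model: MediatorModel,
    outcome_model: OutcomeModel,
    a: float = 1.0,
    a_star: float = 0.0,
) -> tuple[float, float, float]:
    """(TE, rNDE, rNIE) for the contrast ``a`` vs ``a_star`` by closed-form
    summation over the mediator levels."""
    if a == a_star:
        raise ValueError("the exposure contrast requires a != a_star")
    m = mediator_model.levels.astype(float)
    p_a = mediator_model.p_given(a)
    p_astar = mediator_model.p_given(a_star)
    ey_a = outcome_model.predict(a, m)
    ey_astar = outcome_model.predict(a_star, m)
    rnde = float(np.sum((ey_a - ey_astar) * p_astar))
    rnie = float(np.sum(ey_a * (p_a - p_astar)))
    return rnde + rnie, rnde, rnie


def _point_estimate(
    cohort: pd.DataFrame,
    exposure: str,
    outcome_col: str,
    interaction: bool,
    a: float,
    a_star: float,
    covariate_set: str,
    stabilized: bool,
) -> tuple[float, float, float]:
    child_col, adult_col, _ = _exposure_columns(exposure)
    ws = compute_weights(cohort, covariate_set=covariate_set, exposure=exposure,
                         stabilized=stabilized)
    sampling = cohort["sampling_weight"].to_numpy(float)
    aa = cohort[child_col].to_numpy()
    mm = cohort[adult_col].to_numpy()
    yy = cohort[outcome_col].to_numpy(float)
    # interventional mediator distribution: exposure deconfounded by the
    # childhood IPTW, mediator left at its population law given A -- the
    # mediator's own IPTW must NOT enter here, or its stabilization numerator
    # (the crude P(M|A)) would re-impose the confounded association
    med = fit_mediator_model(aa, mm, ws.iptw_child * sampling)
    # outcome model needs both exposure and mediator deconfounded: full weight
    out = fit_outcome_model(aa, mm, yy, ws.final_weight, interaction=interaction)
    return estimate_effects(med, out, a=a, a_star=a_star)


def mediate(
    cohort: pd.DataFrame,
    exposure: str = "cumulative",
    outcome_col: str = "outcome",
    interaction: bool = True,
    a: float = 1.0,
    a_star: float = 0.0,
    n_boot: int = 500,
    seed: int | None = 0,
    covariate_set: str = "base",
    stabilized: bool = True,
    skip_warn_frac: float = 0.05,
) -> MediationResult:
    """Point estimates plus percentile bootstrap CIs for TE, rNDE and rNIE.

    The default contrast is a one-unit increase of the childhood cumulative
    score (a* = 0 vs a = 1). Bootstrap replicates resample subjects and
    re-estimate the IPTW from scratch; replicates whose resample is
    degenerate (an exposure or mediator level vanished, propensity model
    separation) are skipped and counted, with a warning if more than
    ``skip_warn_frac`` of replicates were lost.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    te, rnde, rnie = _point_estimate(
        cohort, exposure, outcome_col, interaction, a, a_star, covariate_set, stabilized
    )
    rng = np.random.default_rng(seed)
    n = len(cohort)
    stats = np.empty((n_boot, 3))
    skipped = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boot = cohort.iloc[idx].reset_index(drop=True)
        try:
            stats[b - skipped] = _point_estimate(
                boot, exposure, outcome_col, interaction, a, a_star,
                covariate_set, stabilized,
            )
        except (DegenerateSampleError, FittingError, PositivityError):
            skipped += 1
    kept = stats[: n_boot - skipped]
    if skipped > skip_warn_frac * n_boot:
        warnings.warn(
            f"{skipped}/{n_boot} bootstrap replicates skipped as degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    if kept.shape[0] < 2:
        raise RuntimeError("fewer than 2 usable bootstrap replicates")
    lo, hi = np.percentile(kept, [2.5, 97.5], axis=0)
    return MediationResult(
        a=a, a_star=a_star, te=te, rnde=rnde, rnie=rnie,
        te_ci=(float(lo[0]), float(hi[0])),
        rnde_ci=(float(lo[1]), float(hi[1])),
        rnie_ci=(float(lo[2]), float(hi[2])),
        n_boot=int(kept.shape[0]), n_skipped=skipped,
        interaction=interaction, exposure=exposure, outcome=outcome_col,
    )
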