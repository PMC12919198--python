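"""Inverse-probability-of-treatment weights for the two-period exposures.

Exposure at each period is either the cumulative adversity score (0-3,
multinomial propensity model) or a single binary adversity type (binomial).
The childhood model conditions on baseline confounders only; the adulthood
model additionally conditions on the intermediate confounders (own education,
household income) and the childhood exposure history, respecting the assumed
time ordering. The final analysis weight is the product of the total IPTW and
the survey sampling weight.

Propensity models are unpenalized (multinomial) logistic regressions; see
``covariate_columns`` for the exact conditioning sets of the three covariate
configurations (``base``, ``base+cells``, ``base+smoking``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .io import (
    ADVERSITY_TYPES,
    BASELINE_CONFOUNDERS,
    CELL_COLS,
    CHILD_COLS,
    INTERMEDIATE_CONFOUNDERS,
)

COVARIATE_SETS = ("base", "base+cells", "base+smoking")
EXPOSURES = ("cumulative",) + tuple(ADVERSITY_TYPES)


class FittingError(RuntimeError):
    """A propensity model failed to converge."""


class PositivityError(ValueError):
    """Predicted exposure probabilities fell below the positivity floor."""


@dataclass
class WeightSet:
    """Per-subject IPTW components and the final analysis weight."""

    iptw_child: np.ndarray
    iptw_adult: np.ndarray
    stabilized: bool
    covariate_set_id: str
    exposure: str
    final_weight: np.ndarray | None = None

    @property
    def iptw_total(self) -> np.ndarray:
        return self.iptw_child * self.iptw_adult

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "iptw_child": self.iptw_child,
                "iptw_adult": self.iptw_adult,
                "iptw_total": self.iptw_total,
            }
        )
        if self.final_weight is not None:
            out["final_weight"] = self.final_weight
        return out


@dataclass
class ExposureModels:
    """Fitted period-specific propensity models and stabilization numerators."""

    exposure: str
    covariate_set_id: str
    child_model: LogisticRegression
    adult_model: LogisticRegression
    child_cols: list
    adult_cols: list
    child_marginal: np.ndarray        # P(A1 = a), numerator for period 1
    adult_num_model: LogisticRegression  # P(A2 = a | A1), numerator for period 2


def _exposure_columns(exposure: str) -> tuple[str, str, list[str]]:
    """(child exposure col, adult exposure col, child history cols for period-2 model)."""
    if exposure == "cumulative":
        return "child_score", "adult_score", list(CHILD_COLS)
    if exposure in ADVERSITY_TYPES:
        return f"child_{exposure}", f"adult_{exposure}", [f"child_{exposure}"]
    raise ValueError(f"unknown exposure {exposure!r}; expected one of {EXPOSURES}")


def covariate_columns(covariate_set: str, cohort: pd.DataFrame) -> list[str]:
    """Baseline conditioning columns of a named covariate configuration."""
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(
            f"unknown covariate set {covariate_set!r}; expected one of {COVARIATE_SETS}"
        )
    cols = list(BASELINE_CONFOUNDERS)
    if covariate_set == "base+cells":
        missing = [c for c in CELL_COLS if c not in cohort.columns]
        if missing:
            raise ValueError(f"covariate set 'base+cells' needs columns {missing}")
        cols += CELL_COLS[:-1]  # drop one proportion: they sum to 1
    elif covariate_set == "base+smoking":
        if "smoking" not in cohort.columns:
            raise ValueError("covariate set 'base+smoking' needs a 'smoking' column")
        cols += ["smoking"]
    return cols


def _design(cohort: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = cohort[[c for c in cols if c != "smoking"]].to_numpy(float)
    if "smoking" in cols:
        smk = cohort["smoking"].to_numpy(int)
        X = np.column_stack([X, (smk == 1).astype(float), (smk == 2).astype(float)])
    # standardize for optimizer conditioning; fitted probabilities are invariant
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _fit_logit(X: np.ndarray, y: np.ndarray, label: str) -> LogisticRegression:
    model = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-7)  # unpenalized
    model.fit(X, y)
    if int(np.max(model.n_iter_)) >= 2000:
        raise FittingError(f"propensity model {label!r} did not converge (possible separation)")
    return model


def fit_exposure_models(
    cohort: pd.DataFrame,
    covariate_set: str = "base",
    exposure: str = "cumulative",
) -> ExposureModels:
    """Fit the two time-ordered propensity models plus stabilization numerators.

    Missing values in any used column are rejected (imputation is out of scope).
    """
    child_col, adult_col, child_hist = _exposure_columns(exposure)
    base_cols = covariate_columns(covariate_set, cohort)
    adult_cols = base_cols + INTERMEDIATE_CONFOUNDERS + child_hist

    used = sorted(set(base_cols + adult_cols + [child_col, adult_col]))
    sub = cohort[used]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}; imputation is out of scope")

    a1 = cohort[child_col].to_numpy(int)
    a2 = cohort[adult_col].to_numpy(int)

    child_model = _fit_logit(_design(cohort, base_cols), a1, f"childhood {exposure}")
    adult_model = _fit_logit(_design(cohort, adult_cols), a2, f"adulthood {exposure}")
    # numerators: marginal P(A1) and P(A2 | A1)
    marginal = np.bincount(a1, minlength=int(a1.max()) + 1) / a1.size
    adult_num = _fit_logit(a1.reshape(-1, 1).astype(float), a2, f"adulthood {exposure} numerator")

    return ExposureModels(
        exposure=exposure,
        covariate_set_id=covariate_set,
        child_model=child_model,
        adult_model=adult_model,
        child_cols=base_cols,
        adult_cols=adult_cols,
        child_marginal=marginal,
        adult_num_model=adult_num,
    )


def _prob_of_observed(model: LogisticRegression, X: np.ndarray, a: np.ndarray) -> np.ndarray:
    probs = model.predict_proba(X)
    col = {c: j for j, c in enumerate(model.classes_)}
    idx = np.array([col[v] for v in a])
    return probs[np.arange(a.size), idx]


def compute_iptw(
    cohort: pd.DataFrame,
    models: ExposureModels,
    stabilized: bool = True,
    prob_floor: float = 1e-6,
) -> WeightSet:
    """Per-subject period weights s / P(A = a | history).

    With ``stabilized`` the numerators are the marginal P(A1) and the
    conditional P(A2 | A1); otherwise 1. Any denominator at or below
    ``prob_floor`` violates positivity and raises rather than being clipped.
    """
    child_col, adult_col, _ = _exposure_columns(models.exposure)
    a1 = cohort[child_col].to_numpy(int)
    a2 = cohort[adult_col].to_numpy(int)

    p1 = _prob_of_observed(models.child_model, _design(cohort, models.child_cols), a1)
    p2 = _prob_of_observed(models.adult_model, _design(cohort, models.adult_cols), a2)
    for name, p in (("childhood", p1), ("adulthood", p2)):
        low = np.flatnonzero(p <= prob_floor)
        if low.size:
            raise PositivityError(
                f"{name} exposure probabilities at or below {prob_floor:g} for "
                f"subjects {low[:20].tolist()} (positivity violated)"
            )

    if stabilized:
        s1 = models.child_marginal[a1]
        s2 = _prob_of_observed(models.adult_num_model, a1.reshape(-1, 1).astype(float), a2)
    else:
        s1 = np.ones_like(p1)
        s2 = np.ones_like(p2)

    return WeightSet(
        iptw_child=s1 / p1,
        iptw_adult=s2 / p2,
        stabilized=stabilized,
        covariate_set_id=models.covariate_set_id,
        exposure=models.exposure,
    )


def combine_weights(iptw_total: np.ndarray, sampling_weight: np.ndarray) -> np.ndarray:
    """Final analysis weight: elementwise IPTW x sampling weight."""
    t = np.asarray(iptw_total, float)
    s = np.asarray(sampling_weight, float)
    if (t <= 0).any() or (s <= 0).any() or not (np.isfinite(t).all() and np.isfinite(s).all()):
        raise ValueError("weights must be finite and strictly positive")
    return t * s


def compute_weights(
    cohort: pd.DataFrame,
    covariate_set: str = "base",
    exposure: str = "cumulative",
    stabilized: bool = True,
    prob_floor: float = 1e-6,
) -> WeightSet:
    """Convenience: fit propensity models, compute IPTW, attach final weights."""
    models = fit_exposure_models(cohort, covariate_set, exposure)
    ws = compute_iptw(cohort, models, stabilized=stabilized, prob_floor=prob_floor)
    ws.final_weight = combine_weights(ws.iptw_total, cohort["sampling_weight"].to_numpy())
    return ws


def kish_ess(w: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(w, float)
    return float(w.sum() ** 2 / np.square(w).sum())


def weight_diagnostics(weightset: WeightSet) -> dict:
    """Summary statistics of the total IPTW and (if set) final weight."""
    out = {}
    for name, w in (("iptw_total", weightset.iptw_total), ("final_weight", weightset.final_weight)):
        if w is None:
            continue
        out[name] = {
            "mean": float(np.mean(w)),
            "min": float(np.min(w)),
            "max": float(np.max(w)),
            "p99": float(np.percentile(w, 99)),
            "kish_ess": kish_ess(w),
        }
    out["stabilized"] = weightset.stabilized
    out["covariate_set_id"] = weightset.covariate_set_id
    return out


def truncate_weights(weightset: WeightSet, lower_pct: float = 1.0, upper_pct: float = 99.0) -> WeightSet:
    """Clip period weights at the given percentiles of the total IPTW; opt-in."""
    lo, hi = np.percentile(weightset.iptw_total, [lower_pct, upper_pct])
    total = np.clip(weightset.iptw_total, lo, hi)
    # rescale the adult component so child * adult equals the clipped total
    adult = total / weightset.iptw_child
    new = replace(weightset, iptw_adult=adult)
    if weightset.final_weight is not None:
        sampling = weightset.final_weight / weightset.iptw_total
        new.final_weight = combine_weights(new.iptw_total, sampling)
    return new
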