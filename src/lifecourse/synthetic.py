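"""Synthetic cohort generator with the causal structure of the life-course analysis.

Generation follows the assumed directed acyclic graph in causal order:

    baseline confounders (sex, age, parental education, nativity)
      -> childhood adversity (three binary types, cumulative score 0-3)
      -> intermediate confounders (own education, household income)
      -> adulthood adversity (three types, each with a carryover effect
         from its childhood counterpart -- the "chained exposure" pathway)
      -> continuous outcome (epigenetic age acceleration)

Exposure and intermediate models are logistic; the outcome is linear in the
simplex-weighted life-course exposure ``w_c * child_score + (1 - w_c) *
adult_score`` plus additive baseline-confounder terms and Gaussian noise, so
the ground-truth life-course effect ``delta`` and period weight
``w_childhood`` are known exactly and recoverable.

Logistic intercepts are calibrated by root-finding so the realized marginal
prevalence of each indicator matches its configured target given the drawn
upstream variables; prevalence targets therefore behave like study
conditions, not loose tendencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import (
    ADVERSITY_TYPES,
    BASELINE_CONFOUNDERS,
    CELL_COLS,
    validate_cohort,
)


class ConfigError(ValueError):
    """A generator configuration field is invalid."""


def cumulative_score(indicators) -> np.ndarray:
    """Within-period cumulative adversity score: the sum of three binaries (0-3).

    ``indicators`` is a length-3 sequence of binary scalars or aligned arrays.
    """
    arrs = [np.asarray(a) for a in indicators]
    if len(arrs) != 3:
        raise ConfigError("cumulative_score expects exactly three indicators")
    for a in arrs:
        if not np.isin(a, (0, 1)).all():
            raise ConfigError("adversity indicators must be binary 0/1")
    return sum(a.astype(int) for a in arrs)


def pool_abuse(physical, sexual) -> np.ndarray:
    """Pool physical and sexual abuse into one indicator: 1 iff either occurred.

    Mirrors the common practice of combining rare abuse items within a period.
    """
    p, s = np.asarray(physical), np.asarray(sexual)
    for a in (p, s):
        if not np.isin(a, (0, 1)).all():
            raise ConfigError("abuse indicators must be binary 0/1")
    return np.maximum(p.astype(int), s.astype(int))


# Default prevalence targets. Deprivation and the demographic margins follow a
# large US Hispanic/Latino cohort profile; substance abuse by someone close
# and (pooled physical/sexual) abuse use plausible mid-range values, with
# adult abuse deliberately uncommon.
_DEFAULT_PREV = {
    ("child", "substance"): 0.35,
    ("adult", "substance"): 0.25,
    ("child", "deprivation"): 0.542,
    ("adult", "deprivation"): 0.520,
    ("child", "abuse"): 0.30,
    ("adult", "abuse"): 0.12,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with ground truth made explicit.

    Coefficients on exposures/intermediates are on the log-odds scale; outcome
    coefficients are in outcome units (years for AgeAccelGrim, years/calendar
    year for DunedinPACE).
    """

    n_subjects: int = 1000
    seed: int = 0

    # demographic margins
    p_female: float = 0.614
    age_mean: float = 50.5
    age_sd: float = 12.91
    p_parental_education: float = 0.553
    p_nativity: float = 0.186

    # marginal prevalence targets, keyed by (period, type)
    prevalence: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_PREV)
    )

    # log-odds effects of baseline confounders on each adversity indicator
    exposure_confounder_coefs: Mapping[str, float] = field(
        default_factory=lambda: {
            "sex": 0.3,
            "age_std": 0.3,
            "parental_education": -0.4,
            "nativity": 0.2,
        }
    )
    # childhood adversity -> own adulthood counterpart, log-odds (pathway strength)
    carryover_strength: Mapping[str, float] = field(
        default_factory=lambda: {t: 0.8 for t in ADVERSITY_TYPES}
    )

    # intermediate confounders: targets, baseline coefs, and childhood-score coef
    p_own_education: float = 0.631
    p_household_income: float = 0.279
    intermediate_confounder_coefs: Mapping[str, float] = field(
        default_factory=lambda: {
            "sex": 0.2,
            "age_std": -0.3,
            "parental_education": 0.8,
            "nativity": 0.3,
        }
    )
    intermediate_child_coef: float = -0.3
    # log-odds effects of intermediates on adulthood adversity
    adult_intermediate_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"own_education": -0.4, "household_income": -0.4}
    )

    # outcome ground truth
    truth_beta0: float = 0.0
    truth_delta: float = 0.9
    truth_w_childhood: float = 0.2
    residual_sd: float = 3.5
    outcome_kind: str = "AgeAccelGrim"
    outcome_confounder_coefs: Mapping[str, float] = field(
        default_factory=lambda: {
            "sex": 0.3,
            "age_std": 0.5,
            "parental_education": -0.3,
            "nativity": 0.2,
        }
    )
    # optional direct effects of intermediates on the outcome (off by default so
    # the marginal ground truth stays transparent; switch on for mediation tests)
    intermediate_outcome_coefs: Mapping[str, float] = field(default_factory=dict)

    sampling_weight_dispersion: float = 0.4

    include_smoking: bool = False
    include_cells: bool = False
    smoking_probs: tuple[float, float, float] = (0.618, 0.213, 0.169)
    smoking_adversity_coef: float = 0.3

    def validate(self) -> "GeneratorConfig":
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be at least 2")
        for name in (
            "p_female",
            "p_parental_education",
            "p_nativity",
            "p_own_education",
            "p_household_income",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1); got {v}")
        for key, v in self.prevalence.items():
            if not 0 < v < 1:
                raise ConfigError(f"prevalence[{key}] must lie in (0, 1); got {v}")
        if not 0 <= self.truth_w_childhood <= 1:
            raise ConfigError(
                f"truth_w_childhood must lie in [0, 1]; got {self.truth_w_childhood}"
            )
        if self.residual_sd <= 0:
            raise ConfigError(f"residual_sd must be positive; got {self.residual_sd}")
        if self.sampling_weight_dispersion <= 0:
            raise ConfigError("sampling_weight_dispersion must be positive")
        if self.outcome_kind not in ("AgeAccelGrim", "DunedinPACE"):
            raise ConfigError(f"unknown outcome_kind {self.outcome_kind!r}")
        if abs(sum(self.smoking_probs) - 1) > 1e-8:
            raise ConfigError("smoking_probs must sum to 1")
        return self

    # -- scenario factories -------------------------------------------------

    @classmethod
    def pathway_scenario(cls, n_subjects: int = 2000, seed: int = 0, **kw) -> "GeneratorConfig":
        """Strong childhood->adulthood carryover with a mostly-adulthood effect:
        the indirect (mediated) path is real, so the pathway verdict is correct."""
        kw.setdefault("carryover_strength", {t: 2.0 for t in ADVERSITY_TYPES})
        kw.setdefault("truth_delta", 2.0)
        kw.setdefault("truth_w_childhood", 0.15)
        kw.setdefault("residual_sd", 2.0)
        return cls(n_subjects=n_subjects, seed=seed, **kw)

    @classmethod
    def accumulation_scenario(cls, n_subjects: int = 2000, seed: int = 0, **kw) -> "GeneratorConfig":
        """No carryover and equal period weights: both periods contribute
        equally and independently, the accumulation hypothesis."""
        kw.setdefault("carryover_strength", {t: 0.0 for t in ADVERSITY_TYPES})
        kw.setdefault("intermediate_child_coef", 0.0)  # no indirect path either
        kw.setdefault("truth_delta", 2.0)
        kw.setdefault("truth_w_childhood", 0.5)
        kw.setdefault("residual_sd", 2.0)
        return cls(n_subjects=n_subjects, seed=seed, **kw)

    @classmethod
    def dunedinpace(cls, n_subjects: int = 1000, seed: int = 0, **kw) -> "GeneratorConfig":
        """Pace-of-aging outcome calibrated to marginal mean 1.08, SD 0.12.

        The intercept absorbs the expected exposure and confounder
        contributions; the residual SD absorbs what the small systematic terms
        do not explain of the target variance.
        """
        delta = kw.pop("truth_delta", 0.013)
        w = kw.pop("truth_w_childhood", 0.5)
        coefs = kw.pop(
            "outcome_confounder_coefs",
            {"sex": 0.004, "age_std": 0.006, "parental_education": -0.004, "nativity": 0.002},
        )
        cfg = cls(
            n_subjects=n_subjects,
            seed=seed,
            outcome_kind="DunedinPACE",
            truth_delta=delta,
            truth_w_childhood=w,
            outcome_confounder_coefs=coefs,
            truth_beta0=0.0,
            residual_sd=1.0,
            **kw,
        )
        prev = cfg.prevalence
        e_child = sum(prev[("child", t)] for t in ADVERSITY_TYPES)
        e_adult = sum(prev[("adult", t)] for t in ADVERSITY_TYPES)
        e_expo = delta * (w * e_child + (1 - w) * e_adult)
        e_conf = (
            coefs.get("sex", 0.0) * cfg.p_female
            + coefs.get("parental_education", 0.0) * cfg.p_parental_education
            + coefs.get("nativity", 0.0) * cfg.p_nativity
        )
        # variance of the weighted score, treating types as independent within period
        v_child = sum(p * (1 - p) for p in (prev[("child", t)] for t in ADVERSITY_TYPES))
        v_adult = sum(p * (1 - p) for p in (prev[("adult", t)] for t in ADVERSITY_TYPES))
        v_sys = delta**2 * (w**2 * v_child + (1 - w) ** 2 * v_adult) + sum(
            c**2 for c in coefs.values()
        )
        cfg.truth_beta0 = 1.08 - e_expo - e_conf
        cfg.residual_sd = float(np.sqrt(max(0.12**2 - v_sys, 1e-6)))
        return cfg


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort, for recovery tests and audit."""

    beta0: float
    delta: float
    w_childhood: float
    w_adulthood: float
    residual_sd: float
    carryover_strength: dict
    marginal_prevalence: dict
    outcome_kind: str

    def to_dict(self) -> dict:
        return asdict(self)


def _calibrate_intercept(linpred: np.ndarray, target: float) -> float:
    """Intercept a such that mean(expit(a + linpred)) == target."""
    f = lambda a: expit(a + linpred).mean() - target
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw a cohort from the configured data-generating process.

    Returns the validated cohort table and the ground-truth record.
    Bit-reproducible for a fixed config (single seeded generator, fixed
    draw order).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    sex = rng.binomial(1, cfg.p_female, n)
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18.0, 95.0)
    parental_education = rng.binomial(1, cfg.p_parental_education, n)
    nativity = rng.binomial(1, cfg.p_nativity, n)
    age_std = (age - cfg.age_mean) / cfg.age_sd

    base = {"sex": sex, "age_std": age_std, "parental_education": parental_education,
            "nativity": nativity}
    b = cfg.exposure_confounder_coefs
    lin_base = sum(b.get(k, 0.0) * v for k, v in base.items())
    lin_base = np.broadcast_to(np.asarray(lin_base, dtype=float), (n,))

    child = {}
    for t in ADVERSITY_TYPES:
        a = _calibrate_intercept(lin_base, cfg.prevalence[("child", t)])
        child[t] = rng.binomial(1, expit(a + lin_base))
    child_score = cumulative_score([child[t] for t in ADVERSITY_TYPES])

    c = cfg.intermediate_confounder_coefs
    lin_int = sum(c.get(k, 0.0) * v for k, v in base.items())
    lin_int = np.broadcast_to(np.asarray(lin_int, dtype=float), (n,))
    lin_int = lin_int + cfg.intermediate_child_coef * child_score
    own_education = rng.binomial(
        1, expit(_calibrate_intercept(lin_int, cfg.p_own_education) + lin_int)
    )
    household_income = rng.binomial(
        1, expit(_calibrate_intercept(lin_int, cfg.p_household_income) + lin_int)
    )

    d = cfg.adult_intermediate_coefs
    lin_adult_shared = lin_base + d.get("own_education", 0.0) * own_education + d.get(
        "household_income", 0.0
    ) * household_income
    adult = {}
    for t in ADVERSITY_TYPES:
        lp = lin_adult_shared + cfg.carryover_strength.get(t, 0.0) * child[t]
        a = _calibrate_intercept(lp, cfg.prevalence[("adult", t)])
        adult[t] = rng.binomial(1, expit(a + lp))
    adult_score = cumulative_score([adult[t] for t in ADVERSITY_TYPES])

    g = cfg.outcome_confounder_coefs
    lin_out = sum(g.get(k, 0.0) * v for k, v in base.items())
    lin_out = np.broadcast_to(np.asarray(lin_out, dtype=float), (n,)).copy()
    for k, v in cfg.intermediate_outcome_coefs.items():
        lin_out += v * {"own_education": own_education, "household_income": household_income}[k]
    w = cfg.truth_w_childhood
    outcome = (
        cfg.truth_beta0
        + cfg.truth_delta * (w * child_score + (1 - w) * adult_score)
        + lin_out
        + rng.normal(0.0, cfg.residual_sd, n)
    )

    s = cfg.sampling_weight_dispersion
    sampling_weight = rng.lognormal(mean=-0.5 * s**2, sigma=s, size=n)  # unit mean

    df = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "parental_education": parental_education,
            "nativity": nativity,
            **{f"child_{t}": child[t] for t in ADVERSITY_TYPES},
            "child_score": child_score,
            "own_education": own_education,
            "household_income": household_income,
            **{f"adult_{t}": adult[t] for t in ADVERSITY_TYPES},
            "adult_score": adult_score,
            "outcome": outcome,
            "sampling_weight": sampling_weight,
        }
    )

    if cfg.include_smoking:
        # ordinal latent shifted by adulthood adversity; thresholds placed at the
        # empirical quantiles implied by the configured marginal distribution
        z = cfg.smoking_adversity_coef * (adult_score - adult_score.mean()) + rng.normal(size=n)
        q = np.quantile(z, [cfg.smoking_probs[0], cfg.smoking_probs[0] + cfg.smoking_probs[1]])
        df["smoking"] = np.digitize(z, q)
    if cfg.include_cells:
        means = np.array([0.06, 0.06, 0.17, 0.08, 0.08, 0.55])
        cells = rng.dirichlet(60.0 * means, size=n)
        for j, col in enumerate(CELL_COLS):
            df[col] = cells[:, j]

    truth = TruthRecord(
        beta0=cfg.truth_beta0,
        delta=cfg.truth_delta,
        w_childhood=w,
        w_adulthood=1.0 - w,
        residual_sd=cfg.residual_sd,
        carryover_strength=dict(cfg.carryover_strength),
        marginal_prevalence={f"{p}_{t}": v for (p, t), v in cfg.prevalence.items()},
        outcome_kind=cfg.outcome_kind,
    )
    return validate_cohort(df), truth
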