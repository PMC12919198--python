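import numpy as np
import pandas as pd
import pytest

from lifecourse import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate confounded cohort with known truth (delta=1, w=0.8)."""
    cfg = GeneratorConfig(
        n_subjects=2000, seed=11, truth_beta0=0.0, truth_delta=1.0,
        truth_w_childhood=0.8, residual_sd=1.0,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture
def toy_weighted_sample():
    """Tiny fixed sample with heterogeneous weights for bootstrap checks."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=200)
    w = rng.lognormal(mean=0.5, sigma=0.6, size=200)
    return x, w


def make_saturated_cohort():
    """Cohort built from exact cell counts for hand-computable propensities.

    Binary exposure type 'substance'. The only varying baseline confounder is
    sex (=L). P(child_substance=1 | L=1) = 0.8, P(... | L=0) = 0.2, halves of
    the sample at each L, so the marginal is 0.5. The adulthood indicator is
    balanced within every cell so its propensities are 0.5 everywhere.
    """
    rows = []
    for L, p1 in ((1, 0.8), (0, 0.2)):
        n_cell = 40
        n_a1 = int(round(p1 * n_cell))
        for i in range(n_cell):
            a1 = 1 if i < n_a1 else 0
            a2 = i % 2
            rows.append((L, a1, a2))
    df = pd.DataFrame(rows, columns=["sex", "child_substance", "adult_substance"])
    n = len(df)
    rng = np.random.default_rng(3)
    df["age"] = 50.0
    df["parental_education"] = 0
    df["nativity"] = 0
    df["child_deprivation"] = 0
    df["child_abuse"] = 0
    df["child_score"] = df[["child_substance", "child_deprivation", "child_abuse"]].sum(axis=1)
    df["own_education"] = rng.binomial(1, 0.5, n)
    df["household_income"] = rng.binomial(1, 0.5, n)
    df["adult_deprivation"] = 0
    df["adult_abuse"] = 0
    df["adult_score"] = df[["adult_substance", "adult_deprivation", "adult_abuse"]].sum(axis=1)
    df["outcome"] = rng.normal(size=n)
    df["sampling_weight"] = 1.0
    return df


@pytest.fixture
def saturated_cohort():
    return make_saturated_cohort()
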