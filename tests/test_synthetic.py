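"""Generator: coding rules, calibration to target margins, and causal structure."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lifecourse import GeneratorConfig, cumulative_score, generate_cohort, pool_abuse
from lifecourse.synthetic import ConfigError


@pytest.mark.parametrize(
    "indicators, expected",
    [((0, 0, 0), 0), ((1, 1, 1), 3), ((1, 0, 1), 2), ((0, 1, 0), 1)],
)
def test_cumulative_score_sums_within_period(indicators, expected):
    assert cumulative_score(indicators) == expected


def test_cumulative_score_rejects_non_binary():
    with pytest.raises(ConfigError, match="binary"):
        cumulative_score((0, 2, 1))


@pytest.mark.parametrize(
    "phys, sexual, expected",
    [(0, 0, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)],
)
def test_pool_abuse_is_logical_or(phys, sexual, expected):
    assert pool_abuse(phys, sexual) == expected


@pytest.mark.parametrize(
    "field, value, match",
    [
        ("n_subjects", 1, "n_subjects"),
        ("residual_sd", -1.0, "residual_sd"),
        ("truth_w_childhood", 1.5, "truth_w_childhood"),
        ("p_female", 0.0, "p_female"),
        ("sampling_weight_dispersion", 0.0, "sampling_weight_dispersion"),
    ],
)
def test_config_validation_names_the_field(field, value, match):
    with pytest.raises(ConfigError, match=match):
        GeneratorConfig(**{field: value}).validate()


def test_invalid_prevalence_rejected():
    cfg = GeneratorConfig()
    cfg.prevalence[("child", "abuse")] = 1.2
    with pytest.raises(ConfigError, match="prevalence"):
        cfg.validate()


def test_identical_seeds_bit_identical():
    a, _ = generate_cohort(GeneratorConfig(n_subjects=300, seed=42))
    b, _ = generate_cohort(GeneratorConfig(n_subjects=300, seed=42))
    pd.testing.assert_frame_equal(a, b)
    c, _ = generate_cohort(GeneratorConfig(n_subjects=300, seed=43))
    assert not a["outcome"].equals(c["outcome"])


def test_prevalence_calibration_hits_targets():
    """Deprivation margins of 54.2% (child) / 52.0% (adult) are realized."""
    cohort, _ = generate_cohort(GeneratorConfig(n_subjects=10_000, seed=1))
    assert abs(cohort["child_deprivation"].mean() - 0.542) < 0.02
    assert abs(cohort["adult_deprivation"].mean() - 0.520) < 0.02
    # every configured target, both periods
    cfg = GeneratorConfig()
    for (period, typ), target in cfg.prevalence.items():
        assert abs(cohort[f"{period}_{typ}"].mean() - target) < 0.02


def test_scores_are_sums_and_in_range(default_cohort):
    cohort, _ = default_cohort
    for period in ("child", "adult"):
        cols = [f"{period}_{t}" for t in ("substance", "deprivation", "abuse")]
        assert (cohort[f"{period}_score"] == cohort[cols].sum(axis=1)).all()
        assert cohort[f"{period}_score"].between(0, 3).all()


def test_sampling_weights_positive_unit_mean(default_cohort):
    cohort, _ = default_cohort
    w = cohort["sampling_weight"]
    assert (w > 0).all()
    assert abs(w.mean() - 1.0) < 0.05


def test_dunedinpace_margins():
    """Pace-of-aging outcome calibrated to mean 1.08, SD 0.12."""
    cfg = GeneratorConfig.dunedinpace(n_subjects=10_000, seed=2)
    cohort, truth = generate_cohort(cfg)
    assert truth.outcome_kind == "DunedinPACE"
    assert abs(cohort["outcome"].mean() - 1.08) < 0.01
    assert abs(cohort["outcome"].std() - 0.12) < 0.01


def test_zero_carryover_decouples_periods():
    """With no carryover, no intermediate path and no shared confounder
    effects the two period scores are independent by construction."""
    cfg = GeneratorConfig(
        n_subjects=10_000, seed=3,
        exposure_confounder_coefs={},
        carryover_strength={t: 0.0 for t in ("substance", "deprivation", "abuse")},
        intermediate_child_coef=0.0,
        adult_intermediate_coefs={},
    )
    cohort, _ = generate_cohort(cfg)
    r = np.corrcoef(cohort["child_score"], cohort["adult_score"])[0, 1]
    assert abs(r) < 0.03


def test_carryover_induces_dependence():
    cfg = GeneratorConfig(
        n_subjects=10_000, seed=3,
        exposure_confounder_coefs={},
        carryover_strength={t: 2.0 for t in ("substance", "deprivation", "abuse")},
        intermediate_child_coef=0.0,
        adult_intermediate_coefs={},
    )
    cohort, _ = generate_cohort(cfg)
    r = np.corrcoef(cohort["child_score"], cohort["adult_score"])[0, 1]
    assert r > 0.2


def test_outcome_regression_recovers_truth():
    """OLS of outcome on both scores plus confounders recovers
    delta*w_childhood and delta*w_adulthood at large n."""
    cfg = GeneratorConfig(
        n_subjects=50_000, seed=4, truth_delta=1.0, truth_w_childhood=0.8,
        residual_sd=1.0,
    )
    cohort, truth = generate_cohort(cfg)
    X = sm.add_constant(
        np.column_stack(
            [
                cohort["child_score"],
                cohort["adult_score"],
                cohort["sex"],
                (cohort["age"] - cfg.age_mean) / cfg.age_sd,
                cohort["parental_education"],
                cohort["nativity"],
            ]
        )
    )
    fit = sm.OLS(cohort["outcome"].to_numpy(), X).fit()
    assert abs(fit.params[1] - truth.delta * truth.w_childhood) < 0.05
    assert abs(fit.params[2] - truth.delta * truth.w_adulthood) < 0.05


def test_optional_columns_present_and_valid():
    cfg = GeneratorConfig(n_subjects=3000, seed=5, include_smoking=True, include_cells=True)
    cohort, _ = generate_cohort(cfg)
    assert set(cohort["smoking"].unique()) <= {0, 1, 2}
    # marginal smoking distribution near the configured one
    assert abs((cohort["smoking"] == 0).mean() - 0.618) < 0.03
    cells = cohort[[c for c in cohort.columns if c.startswith("cell_")]]
    assert cells.shape[1] == 6
    np.testing.assert_allclose(cells.sum(axis=1), 1.0, atol=1e-6)


def test_truth_record_simplex():
    _, truth = generate_cohort(GeneratorConfig(n_subjects=100, seed=6, truth_w_childhood=0.3))
    assert truth.w_childhood + truth.w_adulthood == pytest.approx(1.0)
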