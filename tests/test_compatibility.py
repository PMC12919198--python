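"""Euclidean-distance scoring and the step-wise verdict rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifecourse.compatibility import (
    REFERENCE_VECTORS,
    EDResult,
    classify_lifecourse,
    ed_posterior,
    euclidean_distance,
)
from lifecourse.mediation import MediationResult
from lifecourse.model import LifecourseFit, PooledPosterior


def _pooled(w_draws):
    w = np.asarray(w_draws, float)
    z = np.zeros_like(w)
    return PooledPosterior(beta0=z, delta=z + 1, w_childhood=w, sigma=z + 1,
                          replicate_ids=np.zeros(w.size, int), n_replicates=1,
                          draws_per_replicate=w.size)


def _fit(w_mean=0.5, cri=(0.2, 0.8)):
    return LifecourseFit(
        delta_mean=1.0, delta_cri=(0.5, 1.5), pp_delta_gt0=0.99,
        w_childhood_mean=w_mean, w_childhood_cri=cri,
        w_adulthood_mean=1 - w_mean, w_adulthood_cri=(1 - cri[1], 1 - cri[0]),
        sigma_mean=1.0, n_replicates=10, n_draws=1000,
    )


def _mediation(rnie_ci, exposure="cumulative", outcome="outcome"):
    lo, hi = rnie_ci
    mid = (lo + hi) / 2
    return MediationResult(a=1, a_star=0, te=1.0, rnde=1.0 - mid, rnie=mid,
                           te_ci=(0.5, 1.5), rnde_ci=(0.1, 1.2), rnie_ci=rnie_ci,
                           n_boot=500, exposure=exposure, outcome=outcome)


@pytest.mark.parametrize(
    "w, ref, expected",
    [
        (0.5, "accumulation", 0.0),
        (1.0, "critical_adulthood", np.sqrt(2)),
        (0.56, "accumulation", np.sqrt(2) * 0.06),
        (0.0, "critical_adulthood", 0.0),
        (1.0, "critical_childhood", 0.0),
    ],
)
def test_euclidean_distance_values(w, ref, expected):
    assert euclidean_distance(w, ref) == pytest.approx(expected, abs=1e-9)


@settings(max_examples=200, deadline=None)
@given(
    w=st.floats(min_value=0.0, max_value=1.0),
    ref=st.sampled_from(sorted(REFERENCE_VECTORS)),
)
def test_simplex_identity(w, ref):
    """On the simplex the 2-D distance collapses to sqrt(2)|w - ref_child|."""
    rc = REFERENCE_VECTORS[ref][0]
    assert euclidean_distance(w, ref) == pytest.approx(np.sqrt(2) * abs(w - rc), abs=1e-12)


def test_reference_vectors_are_the_five_canonical_points():
    assert REFERENCE_VECTORS == {
        "critical_childhood": (1.0, 0.0),
        "critical_adulthood": (0.0, 1.0),
        "accumulation": (0.5, 0.5),
        "sensitive_childhood": (0.67, 0.33),
        "sensitive_adulthood": (0.33, 0.67),
    }
    for rc, ra in REFERENCE_VECTORS.values():
        assert rc + ra == pytest.approx(1.0)


def test_out_of_range_and_unknown_reference_rejected():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        euclidean_distance(1.2, "accumulation")
    with pytest.raises(ValueError, match="unknown reference"):
        euclidean_distance(0.5, "pathway")


def test_ed_posterior_minimizer_and_cri():
    rng = np.random.default_rng(31)
    ed = ed_posterior(_pooled(np.clip(rng.normal(0.52, 0.05, 4000), 0, 1)))
    assert ed.most_compatible == "accumulation"
    for name, (lo, hi) in ed.cri.items():
        assert 0 <= lo <= hi
        assert ed.mean[name] >= 0
    assert min(ed.mean, key=ed.mean.get) == "accumulation"


def test_ed_posterior_draw_order_invariant():
    rng = np.random.default_rng(32)
    w = rng.uniform(0.6, 0.9, 1000)
    e1 = ed_posterior(_pooled(w))
    e2 = ed_posterior(_pooled(w[::-1]))
    for name in e1.mean:
        assert e1.mean[name] == pytest.approx(e2.mean[name], abs=1e-12)
    assert e1.most_compatible == e2.most_compatible


def test_tie_breaks_toward_accumulation():
    # 0.585 is equidistant from accumulation (0.5) and sensitive_childhood (0.67)
    ed = ed_posterior(_pooled(np.full(100, 0.585)))
    assert ed.mean["accumulation"] == pytest.approx(ed.mean["sensitive_childhood"])
    assert ed.most_compatible == "accumulation"


class TestVerdictRule:
    def test_rnie_excluding_zero_forces_pathway(self):
        ed = ed_posterior(_pooled(np.full(100, 0.3)))
        v = classify_lifecourse(_fit(0.3), _mediation((0.09, 0.37)), ed)
        assert v.verdict == "pathway"
        assert v.pathway_supported
        assert v.ed_most_compatible == "sensitive_adulthood"  # still surfaced

    def test_null_rnie_with_central_weights_is_accumulation(self):
        ed = ed_posterior(_pooled(np.full(100, 0.5)))
        v = classify_lifecourse(_fit(0.5), _mediation((-0.1, 0.2)), ed)
        assert v.verdict == "accumulation"
        assert not v.pathway_supported

    def test_null_rnie_with_extreme_weights_is_critical(self):
        ed = ed_posterior(_pooled(np.full(100, 0.02)))
        v = classify_lifecourse(_fit(0.02), _mediation((-0.1, 0.2)), ed)
        assert v.verdict == "critical_adulthood"
        assert v.weight_comparison == "w_childhood < w_adulthood"

    def test_negative_rnie_also_supports_pathway(self):
        ed = ed_posterior(_pooled(np.full(100, 0.5)))
        v = classify_lifecourse(_fit(0.5), _mediation((-0.4, -0.1)), ed)
        assert v.verdict == "pathway"

    def test_inconsistent_labels_rejected(self):
        ed = ed_posterior(_pooled(np.full(100, 0.5)))
        med = _mediation((-0.1, 0.1), exposure="abuse")
        with pytest.raises(ValueError, match="inconsistent"):
            classify_lifecourse(_fit(0.5), med, ed)

    def test_missing_rnie_ci_rejected(self):
        ed = ed_posterior(_pooled(np.full(100, 0.5)))
        med = _mediation((-0.1, 0.1))
        med.rnie_ci = None
        with pytest.raises(ValueError, match="CI"):
            classify_lifecourse(_fit(0.5), med, ed)


def test_verdict_serialization_mirrors_summary_columns():
    ed = ed_posterior(_pooled(np.full(100, 0.5)))
    v = classify_lifecourse(_fit(0.5), _mediation((-0.1, 0.2)), ed)
    d = v.to_dict()
    assert {"verdict", "rnie_excludes_zero", "weight_comparison", "smallest_ed"} <= set(d)
    assert d["smallest_ed"] == "accumulation"
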