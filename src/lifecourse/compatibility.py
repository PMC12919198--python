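"""Life-course hypothesis compatibility: Euclidean distance and the verdict rule.

Five reference points on the period-weight simplex encode the competing
non-pathway hypotheses:

    critical_childhood    (1, 0)       all effect in childhood
    critical_adulthood    (0, 1)       all effect in adulthood
    accumulation          (0.5, 0.5)   equal contributions
    sensitive_childhood   (0.67, 0.33) childhood contributes more
    sensitive_adulthood   (0.33, 0.67) adulthood contributes more

For each posterior draw of the childhood weight w, the Euclidean distance to
a reference (r_c, r_a) is sqrt((w - r_c)^2 + ((1 - w) - r_a)^2); because both
points lie on the simplex this reduces exactly to sqrt(2) * |w - r_c|. The
reference with the smallest posterior-mean ED is the most compatible
non-pathway hypothesis.

The overall verdict follows the step-wise rule: if the bootstrap 95% CI of
the randomized interventional indirect effect (rNIE) excludes zero, the
pathway hypothesis is supported and overrides; otherwise the smallest-ED
reference wins, with ties broken toward accumulation as the most
parsimonious reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mediation import MediationResult
from .model import LifecourseFit, PooledPosterior

REFERENCE_VECTORS: dict[str, tuple[float, float]] = {
    "critical_childhood": (1.0, 0.0),
    "critical_adulthood": (0.0, 1.0),
    "accumulation": (0.5, 0.5),
    "sensitive_childhood": (0.67, 0.33),
    "sensitive_adulthood": (0.33, 0.67),
}

# tie-break order: accumulation first (most parsimonious)
_TIE_ORDER = [
    "accumulation",
    "sensitive_childhood",
    "sensitive_adulthood",
    "critical_childhood",
    "critical_adulthood",
]

VERDICTS = ("pathway",) + tuple(REFERENCE_VECTORS)


@dataclass
class EDResult:
    """Posterior ED summaries per reference and the minimizing reference."""

    mean: dict
    cri: dict
    most_compatible: str

    def to_dict(self) -> dict:
        return {
            "ed_mean": self.mean,
            "ed_cri_95": {k: list(v) for k, v in self.cri.items()},
            "most_compatible": self.most_compatible,
        }


@dataclass
class ModelVerdict:
    """Final life-course verdict plus all supporting evidence."""

    verdict: str
    pathway_supported: bool
    ed_most_compatible: str
    weight_comparison: str
    fit: LifecourseFit
    mediation: MediationResult
    ed: EDResult

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "rnie_excludes_zero": self.pathway_supported,
            "weight_comparison": self.weight_comparison,
            "smallest_ed": self.ed_most_compatible,
            "lifecourse_fit": self.fit.to_dict(),
            "mediation": self.mediation.to_dict(),
            "euclidean_distance": self.ed.to_dict(),
        }


def euclidean_distance(w_childhood, reference: str) -> np.ndarray | float:
    """ED from the weight vector (w, 1-w) to a named reference vector."""
    if reference not in REFERENCE_VECTORS:
        raise ValueError(
            f"unknown reference {reference!r}; expected one of {sorted(REFERENCE_VECTORS)}"
        )
    w = np.asarray(w_childhood, float)
    if (w < 0).any() or (w > 1).any():
        raise ValueError("w_childhood must lie in [0, 1]")
    rc, ra = REFERENCE_VECTORS[reference]
    d = np.sqrt((w - rc) ** 2 + ((1.0 - w) - ra) ** 2)
    return float(d) if d.ndim == 0 else d


def ed_posterior(pooled: PooledPosterior) -> EDResult:
    """ED posterior per reference; minimizer by posterior mean, ties to the
    most parsimonious reference (accumulation first)."""
    w = pooled.w_childhood
    if w.size == 0:
        raise ValueError("empty pooled posterior")
    means, cris = {}, {}
    for name in REFERENCE_VECTORS:
        d = euclidean_distance(w, name)
        means[name] = float(np.mean(d))
        lo, hi = np.percentile(d, [2.5, 97.5])
        cris[name] = (float(lo), float(hi))
    best = min(_TIE_ORDER, key=lambda k: means[k])
    return EDResult(mean=means, cri=cris, most_compatible=best)


def _weight_comparison(fit: LifecourseFit) -> str:
    wc, wa = fit.w_childhood_mean, fit.w_adulthood_mean
    if abs(wc - wa) < 0.1:
        return "w_childhood ~ w_adulthood"
    return "w_childhood > w_adulthood" if wc > wa else "w_childhood < w_adulthood"


def classify_lifecourse(
    fit: LifecourseFit,
    mediation: MediationResult,
    ed: EDResult,
) -> ModelVerdict:
    """Apply the step-wise verdict rule to one exposure/outcome pair.

    The three inputs must describe the same exposure and outcome; a pathway
    verdict fires iff the rNIE 95% CI excludes zero, otherwise the
    smallest-ED reference is returned.
    """
    if fit.exposure != mediation.exposure or fit.outcome != mediation.outcome:
        raise ValueError(
            f"inconsistent analysis labels: fit is ({fit.exposure}, {fit.outcome}), "
            f"mediation is ({mediation.exposure}, {mediation.outcome})"
        )
    if mediation.rnie_ci is None:
        raise ValueError("mediation result lacks a bootstrap CI for rNIE")
    lo, hi = mediation.rnie_ci
    pathway = (lo > 0) or (hi < 0)
    verdict = "pathway" if pathway else ed.most_compatible
    return ModelVerdict(
        verdict=verdict,
        pathway_supported=bool(pathway),
        ed_most_compatible=ed.most_compatible,
        weight_comparison=_weight_comparison(fit),
        fit=fit,
        mediation=mediation,
        ed=ed,
    )
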