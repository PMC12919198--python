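"""End-to-end orchestration of the life-course verdict pipeline.

Stages, in order: analysis weights (IPTW x sampling weight) -> WFPBB
replicates -> Bayesian life-course fit per replicate, pooled -> causal
mediation of the childhood exposure through its adulthood counterpart ->
Euclidean-distance compatibility and the final verdict; optionally the
conventional MSM cross-check. The report carries every intermediate summary,
the per-stage seeds, and explicit units, and is deterministic given the
configuration seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import compatibility, mediation, model, msm, weights

_UNITS = {"AgeAccelGrim": "years", "DunedinPACE": "years per calendar year"}


@dataclass
class PipelineConfig:
    exposure: str = "cumulative"
    outcome_col: str = "outcome"
    outcome_kind: str = "AgeAccelGrim"
    covariate_set: str = "base"
    stabilized: bool = True
    truncate_pct: tuple[float, float] | None = None
    n_replicates: int = 200
    draws: int = 1000
    warmup: int = 1000
    n_boot: int = 500
    interaction: bool = True
    a: float = 1.0
    a_star: float = 0.0
    pop_factor: float = 10.0
    run_msm: bool = False
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for name in ("n_replicates", "draws", "warmup", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.exposure not in weights.EXPOSURES:
            raise ValueError(f"unknown exposure {self.exposure!r}")
        return self


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def _stage_seeds(seed: int) -> dict:
    state = np.random.SeedSequence(seed).generate_state(3)
    return {k: int(v % 2**31) for k, v in zip(("wfpbb_fit", "mediation", "msm"), state)}


def run_pipeline(cohort: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Run the full verdict pipeline on a validated cohort table.

    Returns a JSON-serializable report with the verdict and every stage
    summary. Any stage failure raises ``StageError`` naming the stage.
    """
    cfg = (config or PipelineConfig()).validate()
    seeds = _stage_seeds(cfg.seed)
    report: dict = {
        "config": asdict(cfg),
        "stage_seeds": seeds,
        "units": _UNITS.get(cfg.outcome_kind, "outcome units"),
        "n_subjects": int(len(cohort)),
    }

    try:
        ws = weights.compute_weights(
            cohort, covariate_set=cfg.covariate_set, exposure=cfg.exposure,
            stabilized=cfg.stabilized,
        )
        if cfg.truncate_pct is not None:
            ws = weights.truncate_weights(ws, *cfg.truncate_pct)
        report["weights"] = weights.weight_diagnostics(ws)
    except Exception as e:
        raise StageError(f"stage 'weights' failed: {e}") from e

    try:
        sampler = model.SamplerConfig(draws=cfg.draws, warmup=cfg.warmup)
        pooled, fit = model.fit_wfpbb(
            cohort, ws.final_weight, exposure=cfg.exposure, outcome_col=cfg.outcome_col,
            n_replicates=cfg.n_replicates, sampler=sampler,
            seed=seeds["wfpbb_fit"], pop_factor=cfg.pop_factor,
        )
        report["lifecourse_fit"] = fit.to_dict()
    except Exception as e:
        raise StageError(f"stage 'wfpbb/fit' failed: {e}") from e

    try:
        med = mediation.mediate(
            cohort, exposure=cfg.exposure, outcome_col=cfg.outcome_col,
            interaction=cfg.interaction, a=cfg.a, a_star=cfg.a_star,
            n_boot=cfg.n_boot, seed=seeds["mediation"],
            covariate_set=cfg.covariate_set, stabilized=cfg.stabilized,
        )
        report["mediation"] = med.to_dict()
    except Exception as e:
        raise StageError(f"stage 'mediation' failed: {e}") from e

    try:
        ed = compatibility.ed_posterior(pooled)
        verdict = compatibility.classify_lifecourse(fit, med, ed)
        report["euclidean_distance"] = ed.to_dict()
        report["verdict"] = verdict.verdict
        report["verdict_detail"] = {
            "rnie_excludes_zero": verdict.pathway_supported,
            "weight_comparison": verdict.weight_comparison,
            "smallest_ed": verdict.ed_most_compatible,
        }
    except Exception as e:
        raise StageError(f"stage 'compatibility' failed: {e}") from e

    if cfg.run_msm:
        try:
            res = msm.fit_msm(
                cohort, ws.final_weight, exposure=cfg.exposure,
                outcome_col=cfg.outcome_col, n_boot=min(cfg.n_boot, 200),
                seed=seeds["msm"], covariate_set=cfg.covariate_set,
                stabilized=cfg.stabilized,
            )
            report["msm"] = res.to_dict()
        except Exception as e:
            raise StageError(f"stage 'msm' failed: {e}") from e

    return report
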