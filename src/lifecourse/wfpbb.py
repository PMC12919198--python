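"""Weighted finite population Bayesian bootstrap (WFPBB).

Each replicate (i) reforms the finite target population from the weighted
sample by imputing the unobserved units with a weighted Polya urn -- unit i
enters the urn with mass w_i - 1 (itself already observed) and the urn adds
(N - n)/n mass per draw over the N - n imputation draws -- and (ii) draws a
simple random sample of the original size n from the reformed population, in
which every unit has weight one. Fitting an unweighted model on each
replicate and pooling across replicates propagates the weight-induced
sampling uncertainty into the posterior.

The sequential urn is sampled through its exact Dirichlet-multinomial
representation (urn mass vector alpha, increment c, m draws  <=>  counts ~
DirMult(m, alpha / c)), which costs O(n) per replicate instead of O(N n).

Survey expansion weights should sum to the population size; weights that are
merely relative (e.g. stabilized IPTW x unit-mean sampling weights, whose sum
is about n) are rescaled to a nominal population of ``pop_factor * n``, which
approximates the infinite-population weighted Bayesian bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Replicate:
    """One WFPBB redraw: row indices into the source cohort, all unit weight."""

    replicate_id: int
    indices: np.ndarray  # length n, with multiplicity

    def __len__(self) -> int:
        return self.indices.size


def polya_expand(weights: np.ndarray, pop_size: int, rng: np.random.Generator) -> np.ndarray:
    """Counts per observed unit in one reformed population of ``pop_size``.

    ``weights`` must be positive and sum to ``pop_size`` (the caller
    normalizes). Each unit contributes itself once plus a Polya number of
    imputed copies; counts sum exactly to ``pop_size`` and have marginal
    expectation equal to the unit's weight. Units with weight below one get
    urn mass zero: they represent no one beyond themselves.
    """
    w = np.asarray(weights, float)
    n = w.size
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    if pop_size < n:
        raise ValueError(f"pop_size {pop_size} is smaller than the sample size {n}")
    if abs(w.sum() - pop_size) > 1e-6 * max(pop_size, 1):
        raise ValueError("weights must be normalized to sum to pop_size")
    m = pop_size - n
    if m == 0:
        return np.ones(n, dtype=np.int64)
    alpha = np.maximum(w - 1.0, 0.0) * (n / m)
    g = rng.gamma(alpha)  # gamma(shape=0) is exactly 0: zero-mass units get no copies
    p = g / g.sum()
    return 1 + rng.multinomial(m, p)


def draw_replicate(
    counts: np.ndarray,
    n: int,
    rng: np.random.Generator,
    replicate_id: int = 0,
    with_replacement: bool = False,
) -> Replicate:
    """Equal-size unit-weight redraw from the reformed population.

    Simple random sampling without replacement by default; with replacement
    available as an option.
    """
    counts = np.asarray(counts)
    pop = int(counts.sum())
    if n > pop:
        raise ValueError(f"cannot draw {n} units from a population of {pop}")
    expanded = np.repeat(np.arange(counts.size), counts)
    idx = rng.choice(expanded, size=n, replace=with_replacement)
    return Replicate(replicate_id=replicate_id, indices=np.sort(idx))


def generate_replicates(
    final_weights: np.ndarray,
    n_replicates: int = 200,
    seed: int | np.random.Generator | None = 0,
    pop_size: int | None = None,
    pop_factor: float = 10.0,
    with_replacement: bool = False,
) -> list[Replicate]:
    """Generate the WFPBB replicates (default 200) for a weighted sample.

    ``pop_size`` defaults to round(sum of weights) when the weights are
    genuine expansion weights (total at least ``pop_factor * n``); relative
    weights are rescaled to a nominal population of ``pop_factor * n`` first.
    Deterministic for a fixed integer seed.
    """
    w = np.asarray(final_weights, float)
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("final weights must be finite and strictly positive")
    n = w.size
    if pop_size is None:
        pop_size = int(round(max(w.sum(), pop_factor * n)))
    if pop_size < n:
        raise ValueError(f"pop_size {pop_size} is smaller than the sample size {n}")
    w = w * (pop_size / w.sum())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = []
    for b in range(n_replicates):
        counts = polya_expand(w, pop_size, rng)
        reps.append(draw_replicate(counts, n, rng, replicate_id=b,
                                   with_replacement=with_replacement))
    return reps


def replicate_frame(cohort: pd.DataFrame, replicate: Replicate) -> pd.DataFrame:
    """Materialize a replicate as a unit-weight cohort table."""
    return cohort.iloc[replicate.indices].reset_index(drop=True)
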