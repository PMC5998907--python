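"""Monte Carlo lineage simulation — the independent stochastic oracle.

A replicate starts from a single mutant and steps through the per-cycle stage
sequence: each growth stage replaces n individuals by Poisson(n * mean) (the
superposition of n independent Poisson broods), each sampling stage by
Binomial(n, survival).  A replicate counts as *surviving* once the lineage
reaches the establishment threshold — conditional on reaching ~1000 copies a
beneficial lineage is essentially certain to fix under branching-process
independence — or if it is still alive when the cycle budget runs out (a
logged edge case).

Replicates are simulated vectorised in fixed-size batches, each batch on its
own deterministic substream (``SeedSequence.spawn``), so growing the
replicate count extends rather than reshuffles earlier draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .pgf import FixationResult, PGFSequence, StageKind, _pgf_at

__all__ = ["MonteCarloSpec", "monte_carlo_fixation"]

logger = logging.getLogger(__name__)

_BATCH = 10_000
_Z99 = 2.5758293035489004  # two-sided 99% normal quantile


@dataclass(frozen=True)
class MonteCarloSpec:
    """Replication plan for the lineage simulator."""

    replicates: int
    seed: int
    establishment_threshold: int = 1000
    max_cycles: int = 5000

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if self.establishment_threshold < 100:
            raise ValueError("establishment_threshold must be at least 100")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be positive")


def _simulate_batch(
    at, n_reps: int, spec: MonteCarloSpec, rng: np.random.Generator
) -> tuple[int, int]:
    """Run one batch; returns (survivors, censored-alive-at-horizon)."""
    sizes = np.ones(n_reps, dtype=np.int64)
    survived = 0
    for k in range(spec.max_cycles):
        comp = at(k)
        for st in comp.stages:
            if st.kind is StageKind.GROWTH:
                sizes = rng.poisson(st.mean_offspring * sizes)
            else:
                sizes = rng.binomial(sizes, st.survival_prob)
        big = sizes >= spec.establishment_threshold
        survived += int(np.count_nonzero(big))
        sizes = sizes[~big & (sizes > 0)]
        if sizes.size == 0:
            return survived, 0
    return survived + sizes.size, sizes.size


def monte_carlo_fixation(
    stage_sequence: PGFSequence,
    spec: MonteCarloSpec,
) -> FixationResult:
    """Survival fraction of independent mutant lineages, with a 99% CI.

    ``stage_sequence`` maps cycle index to a :class:`CompositePGF`; finite
    sequences continue in their final environment, matching the numeric
    iterators.  Lineages still alive (below threshold) after ``max_cycles``
    cycles are counted as survivors and logged.
    """
    at = _pgf_at(stage_sequence)
    ss = np.random.SeedSequence(spec.seed)
    n_batches = math.ceil(spec.replicates / _BATCH)
    children = ss.spawn(n_batches)
    survived = 0
    censored = 0
    left = spec.replicates
    for child in children:
        n = min(_BATCH, left)
        s, c = _simulate_batch(at, n, spec, np.random.default_rng(child))
        survived += s
        censored += c
        left -= n
    warnings: tuple[str, ...] = ()
    if censored:
        msg = (
            f"{censored} lineage(s) alive but below threshold after "
            f"{spec.max_cycles} cycles; counted as survived"
        )
        logger.warning(msg)
        warnings = (msg,)
    p_hat = survived / spec.replicates
    ci = _Z99 * math.sqrt(max(p_hat * (1.0 - p_hat), 0.0) / spec.replicates)
    return FixationResult(
        p=p_hat,
        q=1.0 - p_hat,
        method="monte_carlo",
        iterations_or_reps=spec.replicates,
        ci_halfwidth=ci,
        warnings=warnings,
    )
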