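"""Machinery for "generation time" mutants.

A generation-time mutant produces the same mean offspring number as the wild
type (r per generation) but completes each generation in a fraction
``t_g = 1/(1 + s~)`` of a wild-type generation, where ``s~ = log_r(1 + s)`` is
the selective advantage rescaled to the per-generation time axis.  Between two
serial-passage bottlenecks (tau wild-type generations apart) the mutant
lineage therefore intermittently fits in a whole *extra* growth generation:
after n bottlenecks it has accumulated floor(n tau s~) extra generations, the
i-th of them first fitting at bottleneck n_i = ceil(i / (s~ tau)).

The advantage of this mutant enters *only* through those extra growth stages;
within each stage it draws the same Poisson(r) offspring as the wild type.
This is the defining contrast with "fecundity" mutants, whose growth mean is
inflated to r(1+s) every generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .pgf import CompositePGF, FixationResult, StagePGF, time_dependent_extinction

__all__ = [
    "GenTimeParams",
    "ExtraGenerationSchedule",
    "scaled_advantage",
    "generation_time_of",
    "extra_generation_schedule",
    "GenTimeCycleFactory",
    "build_stage_sequence",
    "gentime_fixation_numeric",
]

# Relative slack when comparing an accumulated advantage against an integer
# count of extra generations.  The bottleneck inequality is non-strict, so an
# exactly-integer i/(s~ tau) counts at that bottleneck; the slack keeps the
# float evaluation of such ties on the non-strict side.
_TIE_EPS = 1e-9


def scaled_advantage(s: float, r: float) -> float:
    """Selective advantage on the generation-time axis, ``log_r(1 + s)``.

    For small s this is approximately ``s / ln r``.
    """
    if s <= -1.0:
        raise ValueError("s must exceed -1")
    if r <= 1.0:
        raise ValueError("wild-type offspring mean r must exceed 1")
    return math.log1p(s) / math.log(r)


def generation_time_of(s_tilde: float) -> float:
    """Mutant generation time in wild-type units, ``1 / (1 + s~)``."""
    if s_tilde < 0:
        raise ValueError("s_tilde must be nonnegative (deleterious mutants out of scope)")
    return 1.0 / (1.0 + s_tilde)


@dataclass(frozen=True)
class GenTimeParams:
    """Constant-environment parameters of a generation-time mutant.

    s: selective advantage (> 0, assumed small);
    r: wild-type mean offspring per generation (> 1);
    tau: bottleneck interval in wild-type generations (>= 1).
    """

    s: float
    r: float = 2.0
    tau: int = 1

    def __post_init__(self) -> None:
        # s = 0 (the neutral boundary) is admitted so degenerate limits can
        # be expressed; every genuine computation assumes s > 0
        if self.s < 0:
            raise ValueError("s must be nonnegative")
        if self.r <= 1:
            raise ValueError("r must exceed 1")
        if self.tau < 1 or int(self.tau) != self.tau:
            raise ValueError("tau must be a positive integer")

    @property
    def s_tilde(self) -> float:
        return scaled_advantage(self.s, self.r)

    @property
    def bottleneck_survival(self) -> float:
        """Survival probability at the bottleneck, r**(-tau).

        Chosen so the wild-type composite mean over one cycle is exactly 1
        (population-size conservation over tau growth generations).
        """
        return self.r ** (-self.tau)


@dataclass(frozen=True)
class ExtraGenerationSchedule:
    """When the mutant lineage first fits each extra growth generation.

    ``extra_at[i-1]`` is the bottleneck index n_i (1-based) at which the i-th
    extra generation first fits, n_i = ceil(i / (s~ tau)); ties (exact
    integers) count at that bottleneck because the fitting condition
    ``(n_i tau + i) t_g <= n_i tau`` is non-strict.
    """

    s_tilde: float
    t_g: float
    extra_at: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.extra_at, self.extra_at[1:])):
            raise ValueError("extra_at must be strictly increasing")


def extra_generation_schedule(
    s_tilde: float, tau: int, n_bottlenecks: int
) -> ExtraGenerationSchedule:
    """Minimal bottleneck indices n_i = ceil(i / (s~ tau)) up to ``n_bottlenecks``."""
    if s_tilde <= 0 or tau < 1:
        raise ValueError("require s_tilde > 0 and tau >= 1")
    if n_bottlenecks < 1:
        raise ValueError("n_bottlenecks must be positive")
    rate = s_tilde * tau
    extra_at: list[int] = []
    i = 1
    while True:
        v = i / rate
        n_i = math.ceil(v * (1.0 - _TIE_EPS))
        if n_i > n_bottlenecks:
            break
        extra_at.append(n_i)
        i += 1
    return ExtraGenerationSchedule(
        s_tilde=s_tilde, t_g=generation_time_of(s_tilde), extra_at=tuple(extra_at)
    )


SPerGeneration = Union[Sequence[float], np.ndarray, Callable[[int], float]]


class GenTimeCycleFactory:
    """Lazy ``cycle index -> CompositePGF`` map for a generation-time mutant.

    Cycle k (0-based; bottleneck k+1) normally holds tau growth stages of mean
    r followed by one sampling stage; extra growth stages are inserted when
    the accumulated advantage crosses an integer.  The accumulated advantage
    after g wild-type generations is D_g = sum_{j<g} s~_j — the mutant
    completes 1 + s~_j generations per wild-type generation j — and cycle k
    receives floor(D_{(k+1)tau}) - floor(D_{k tau}) extra stages.  For
    constant s this reproduces n_i = ceil(i/(s~ tau)) exactly.

    ``survival`` may be a scalar (default r**-tau) or a callable giving the
    per-cycle bottleneck survival (used for changing population size).
    """

    def __init__(
        self,
        r: float = 2.0,
        tau: int = 1,
        s: float | None = None,
        s_per_generation: SPerGeneration | None = None,
        survival: float | Callable[[int], float] | None = None,
    ):
        if (s is None) == (s_per_generation is None):
            raise ValueError("provide exactly one of s or s_per_generation")
        if r <= 1 or tau < 1:
            raise ValueError("require r > 1 and tau >= 1")
        self.r = float(r)
        self.tau = int(tau)
        self._log_r = math.log(r)
        self._s_const = s
        if s is not None and s < 0:
            raise ValueError("s must be nonnegative")
        self._s_fn: Callable[[int], float] | None = None
        self._cumsum: list[float] = [0.0]  # D at generation boundaries
        if s_per_generation is not None:
            if callable(s_per_generation):
                self._s_fn = s_per_generation
            else:
                arr = np.asarray(s_per_generation, dtype=float)
                if arr.ndim != 1 or arr.size == 0:
                    raise ValueError("s_per_generation must be a nonempty 1-d sequence")
                if np.any(arr <= 0):
                    raise ValueError("all per-generation selective advantages must be positive")
                # past the end of an explicit trajectory the environment stays
                # in its final state
                self._s_fn = lambda k, _a=arr: float(_a[min(k, _a.size - 1)])
        if survival is None:
            survival = self.r ** (-self.tau)
        self._survival = survival
        self._cache: dict[int, CompositePGF] = {}

    def _s_tilde_at(self, gen: int) -> float:
        if self._s_const is not None:
            return math.log1p(self._s_const) / self._log_r
        s_k = self._s_fn(gen)  # type: ignore[misc]
        if s_k <= 0:
            raise ValueError(f"selective advantage at generation {gen} must be positive")
        return math.log1p(s_k) / self._log_r

    def _deficit_at(self, gen: int) -> float:
        """D_gen = sum of s~_j over generations j < gen."""
        if self._s_const is not None:
            # closed form avoids cumulative float drift in the constant case
            return gen * (math.log1p(self._s_const) / self._log_r)
        while len(self._cumsum) <= gen:
            j = len(self._cumsum) - 1
            self._cumsum.append(self._cumsum[-1] + self._s_tilde_at(j))
        return self._cumsum[gen]

    def extra_stages_in_cycle(self, k: int) -> int:
        lo = math.floor(self._deficit_at(k * self.tau) + _TIE_EPS)
        hi = math.floor(self._deficit_at((k + 1) * self.tau) + _TIE_EPS)
        return hi - lo

    def survival_at(self, k: int) -> float:
        c = self._survival(k) if callable(self._survival) else self._survival
        if not (0.0 < c <= 1.0):
            raise ValueError(f"bottleneck survival at cycle {k} out of (0, 1]: {c}")
        return c

    def cycle_signature(self, k: int) -> tuple[tuple[float, ...], float]:
        """Compact (growth means, bottleneck survival) of cycle k.

        Consumed by the fast inner loop of the nested extinction iteration.
        """
        n_growth = self.tau + self.extra_stages_in_cycle(k)
        return (self.r,) * n_growth, self.survival_at(k)

    def __call__(self, k: int) -> CompositePGF:
        if k < 0:
            raise IndexError("cycle index must be nonnegative")
        comp = self._cache.get(k)
        if comp is None:
            means, c = self.cycle_signature(k)
            comp = CompositePGF(
                [StagePGF.growth(m) for m in means] + [StagePGF.sampling(c)]
            )
            if len(self._cache) < 65536:  # bound memory at deep horizons
                self._cache[k] = comp
        return comp


def build_stage_sequence(
    params: GenTimeParams,
    n_bottlenecks: int,
    s_per_generation: SPerGeneration | None = None,
) -> list[CompositePGF]:
    """Per-cycle pgfs for ``n_bottlenecks`` cycles of a generation-time mutant.

    Cycle k is ``y_{tau+1} o z`` whenever a scheduled extra generation falls
    in cycle k and ``y_tau o z`` otherwise; growth stages use the wild-type
    Poisson mean r throughout.  With ``s_per_generation`` given, the extra
    stages follow the cumulative-advantage rule (constant trajectories
    reproduce the constant-s schedule exactly).
    """
    if n_bottlenecks < 1:
        raise ValueError("n_bottlenecks must be positive")
    if s_per_generation is None:
        factory = GenTimeCycleFactory(r=params.r, tau=params.tau, s=params.s)
    else:
        factory = GenTimeCycleFactory(
            r=params.r, tau=params.tau, s_per_generation=s_per_generation
        )
    return [factory(k) for k in range(n_bottlenecks)]


def gentime_fixation_numeric(
    params: GenTimeParams,
    horizon: int = 2**22,
    tol: float = 1e-10,
    s_per_generation: SPerGeneration | None = None,
    survival: float | Callable[[int], float] | None = None,
) -> FixationResult:
    """Fixation probability of a generation-time mutant by nested iteration.

    Builds the per-cycle stage sequence and accumulates the backward nested
    extinction value, doubling the truncation horizon until it stabilises to
    ``tol``.  The constant-s case is simply the time-homogeneous special case
    of the same computation.
    """
    if s_per_generation is None:
        if params.s == 0.0 and survival is None:
            # neutral mutant: never earns an extra generation, every cycle is
            # exactly critical, and the lineage is lost almost surely
            return FixationResult(p=0.0, q=1.0, method="nested", iterations_or_reps=0)
        factory = GenTimeCycleFactory(
            r=params.r, tau=params.tau, s=params.s, survival=survival
        )
    else:
        factory = GenTimeCycleFactory(
            r=params.r, tau=params.tau, s_per_generation=s_per_generation, survival=survival
        )
    return time_dependent_extinction(factory, horizon=horizon, tol=tol)
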