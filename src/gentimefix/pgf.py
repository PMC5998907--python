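"""Probability-generating-function algebra for branching-process lineages.

A mutant lineage in a serial-passage (or constant-size) population alternates
between *growth* stages — each individual draws a Poisson number of offspring —
and *sampling* stages — each offspring independently survives a dilution
bottleneck with some probability.  The generating function of the compound
process is the functional composition of the stage generating functions, with
the *last* biological stage innermost: growth with pgf ``y`` followed by
sampling with pgf ``z`` has overall pgf ``y(z(x))``.

The probability that a lineage founded by a single mutant eventually dies out
is the smallest fixed point of the per-cycle pgf on [0, 1]; the fixation
probability is its complement.  In a changing environment the per-cycle pgfs
differ across cycles and the extinction probability is the limit of the nested
backward composition phi_0(phi_1(...phi_n(0))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence, Union

__all__ = [
    "StageKind",
    "StagePGF",
    "CompositePGF",
    "FixationResult",
    "ConvergenceError",
    "growth_pgf",
    "sampling_pgf",
    "compose_cycle",
    "extinction_probability",
    "time_dependent_extinction",
]

_X_TOL = 1e-12          # slack for argument-domain checks at x = 1
_CRITICAL_TOL = 1e-12   # mean <= 1 + this  ->  certain extinction


class StageKind(str, Enum):
    GROWTH = "growth"
    SAMPLING = "sampling"


class ConvergenceError(RuntimeError):
    """Fixed-point or nested iteration failed to stabilise.

    Carries the last iterate(s) so callers can inspect how far the
    computation got.
    """

    def __init__(self, message: str, last_value: float, previous_value: float | None = None):
        super().__init__(message)
        self.last_value = last_value
        self.previous_value = previous_value


def _check_x(x: float) -> float:
    if not (-_X_TOL <= x <= 1.0 + _X_TOL):
        raise ValueError(f"pgf argument must lie in [0, 1], got {x!r}")
    return min(max(x, 0.0), 1.0)


@dataclass(frozen=True)
class StagePGF:
    """One reproduction or sampling stage of a lineage cycle.

    Growth stages have Poisson offspring with mean ``mean_offspring``
    (pgf ``exp(m (x - 1))``); sampling stages thin each individual
    independently with ``survival_prob`` (pgf ``1 - c + c x``).
    """

    kind: StageKind
    mean_offspring: float | None = None
    survival_prob: float | None = None

    def __post_init__(self) -> None:
        if self.kind is StageKind.GROWTH:
            if self.mean_offspring is None or self.mean_offspring <= 0:
                raise ValueError("growth stage requires mean_offspring > 0")
        elif self.kind is StageKind.SAMPLING:
            if self.survival_prob is None or not (0.0 < self.survival_prob <= 1.0):
                raise ValueError("sampling stage requires survival_prob in (0, 1]")
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unknown stage kind {self.kind!r}")

    @classmethod
    def growth(cls, mean: float) -> "StagePGF":
        return cls(StageKind.GROWTH, mean_offspring=float(mean))

    @classmethod
    def sampling(cls, survival: float) -> "StagePGF":
        return cls(StageKind.SAMPLING, survival_prob=float(survival))

    @property
    def mean(self) -> float:
        """Derivative at 1: the stage's net multiplication factor."""
        if self.kind is StageKind.GROWTH:
            return self.mean_offspring  # type: ignore[return-value]
        return self.survival_prob  # type: ignore[return-value]

    def __call__(self, x: float) -> float:
        x = _check_x(x)
        if self.kind is StageKind.GROWTH:
            return math.exp(self.mean_offspring * (x - 1.0))
        return 1.0 - self.survival_prob + self.survival_prob * x

    def derivative(self, x: float) -> float:
        x = _check_x(x)
        if self.kind is StageKind.GROWTH:
            return self.mean_offspring * math.exp(self.mean_offspring * (x - 1.0))
        return self.survival_prob


def growth_pgf(mean: float, x: float) -> float:
    """Poisson-offspring growth-stage pgf ``exp(mean (x - 1))``."""
    return StagePGF.growth(mean)(x)


def sampling_pgf(survival: float, x: float) -> float:
    """Binomial-thinning sampling-stage pgf ``1 - c + c x``."""
    return StagePGF.sampling(survival)(x)


@dataclass(frozen=True)
class CompositePGF:
    """Ordered stages of one lineage cycle, listed in biological order.

    ``stages[0]`` happens first in time; evaluation composes them with the
    last stage innermost, so a growth stage followed by a sampling stage
    evaluates as ``y(z(x))``.
    """

    stages: tuple[StagePGF, ...]

    def __init__(self, stages: Sequence[StagePGF]):
        stages = tuple(stages)
        if not stages:
            raise ValueError("CompositePGF requires at least one stage")
        object.__setattr__(self, "stages", stages)

    @classmethod
    def cycle(cls, n_growth: int, growth_mean: float, survival: float) -> "CompositePGF":
        """``n_growth`` growth stages followed by one bottleneck sampling."""
        if n_growth < 1:
            raise ValueError("a cycle needs at least one growth stage")
        return cls([StagePGF.growth(growth_mean)] * n_growth + [StagePGF.sampling(survival)])

    @property
    def mean(self) -> float:
        m = 1.0
        for st in self.stages:
            m *= st.mean
        return m

    def __call__(self, x: float) -> float:
        x = _check_x(x)
        for st in reversed(self.stages):
            x = st(x)
        return x

    def derivative(self, x: float) -> float:
        """Chain-rule derivative of the full composition at ``x``."""
        x = _check_x(x)
        inner: list[float] = [x]
        for st in reversed(self.stages[1:]):
            inner.append(st(inner[-1]))
        d = 1.0
        for st, xi in zip(self.stages, reversed(inner)):
            d *= st.derivative(xi)
        return d


def compose_cycle(pgf: CompositePGF, x: float) -> float:
    """Evaluate a stage composition at ``x`` (innermost = last stage)."""
    return pgf(x)


@dataclass(frozen=True)
class FixationResult:
    """Fixation probability with provenance.

    ``p`` is the probability that a lineage founded by one mutant escapes
    stochastic loss; ``q = 1 - p`` the extinction probability.  ``method``
    records how the number was obtained; Monte Carlo results carry a
    normal-approximation 99% confidence half-width.
    """

    p: float
    q: float
    method: str
    iterations_or_reps: int
    ci_halfwidth: float | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of [0, 1]: {self.p}")
        if self.iterations_or_reps < 0:
            raise ValueError("iterations_or_reps must be nonnegative")


def extinction_probability(
    pgf: CompositePGF,
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> FixationResult:
    """Smallest fixed point of a per-cycle pgf by forward iteration from 0.

    The iterates ``x <- phi(x)`` increase monotonically to the extinction
    probability.  A (sub)critical cycle — composite mean at most 1 — dies out
    almost surely, so ``p = 0`` is returned without iterating.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if pgf.mean <= 1.0 + _CRITICAL_TOL:
        return FixationResult(p=0.0, q=1.0, method="fixed_point", iterations_or_reps=0)
    x = 0.0
    for it in range(1, max_iter + 1):
        x_new = pgf(x)
        if abs(x_new - x) < tol:
            q = x_new
            return FixationResult(p=1.0 - q, q=q, method="fixed_point", iterations_or_reps=it)
        x = x_new
    raise ConvergenceError(
        f"fixed-point iteration did not converge in {max_iter} iterations", last_value=x
    )


PGFSequence = Union[Sequence[CompositePGF], Callable[[int], CompositePGF]]


def _pgf_at(seq: PGFSequence) -> Callable[[int], CompositePGF]:
    if callable(seq):
        return seq
    def at(k: int, _s=seq) -> CompositePGF:
        if k < len(_s):
            return _s[k]
        return _s[-1]  # finite sequences continue in their final environment
    return at


def time_dependent_extinction(
    pgf_sequence: PGFSequence,
    horizon: int = 2**22,
    tol: float = 1e-10,
    initial_horizon: int = 256,
) -> FixationResult:
    """Extinction probability of a time-inhomogeneous branching process.

    Computes ``q = lim_n phi_0(phi_1(... phi_n(0)))`` by backward accumulation
    (``x_n = 0``, ``x_k = phi_k(x_{k+1})``), doubling the truncation horizon
    until successive values of ``p`` differ by less than ``tol``.  ``horizon``
    bounds the largest truncation attempted.

    ``pgf_sequence`` is either a callable ``k -> CompositePGF`` (cycles are
    requested lazily) or a finite sequence, whose final element is reused past
    its end.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    at = _pgf_at(pgf_sequence)
    # factories may expose a compact per-cycle signature so the inner loop
    # avoids building composite objects at large horizons
    sig = getattr(pgf_sequence, "cycle_signature", None)

    # A finite sequence that is (sub)critical in every cycle (the final
    # environment repeats) makes the lineage a nonnegative supermartingale:
    # extinction is certain, and the q_n -> 1 approach is O(1/n), too slow to
    # stabilise.  Only decidable for finite sequences; a lazily-indexed
    # callable could always turn supercritical beyond any examined prefix.
    if not callable(pgf_sequence):
        if all(c.mean <= 1.0 + _CRITICAL_TOL for c in pgf_sequence):
            return FixationResult(p=0.0, q=1.0, method="nested", iterations_or_reps=0)

    if sig is not None:
        def q_of(n: int) -> float:
            x = 0.0
            exp = math.exp
            for k in range(n, -1, -1):
                means, c = sig(k)
                x = 1.0 - c + c * x
                for m in reversed(means):
                    x = exp(m * (x - 1.0))
            return x
    else:
        def q_of(n: int) -> float:
            x = 0.0
            for k in range(n, -1, -1):
                x = at(k)(x)
            return x

    n = max(1, initial_horizon)
    q_prev = q_of(n)
    while True:
        n *= 2
        if n > horizon:
            raise ConvergenceError(
                f"nested iteration not stable within horizon {horizon}",
                last_value=q_prev,
                previous_value=None,
            )
        q = q_of(n)
        if abs(q - q_prev) < tol:
            return FixationResult(p=1.0 - q, q=q, method="nested", iterations_or_reps=n)
        q_prev = q
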