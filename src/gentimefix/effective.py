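"""Effective selective advantage in a changing environment.

The fixation probability of a weakly beneficial mutant in a slowly varying
environment can be condensed into a single number.  Around a constant
*reference* environment with advantage s_bar (the Cesaro mean of the
per-generation advantages s_k) the nested extinction recursion linearises to

    p  ~  p_bar + p_bar * sum_k (s_k - s_bar) sigma**k,     sigma ~ 1 - s_bar,

which rearranges to p ~ s_e / ln 2 for generation-time mutants (p ~ 2 s_e for
fecundity mutants) with the effective advantage

    s_e = sum_k w_k s_k,        w_k = s_bar (1 - s_bar)**k.

The geometric weights w_k sum to one and decay with k: only the environments
the lineage experiences while still rare matter, early generations most.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LN2",
    "SelectionTrajectory",
    "reference_advantage",
    "geometric_weights",
    "truncation_horizon",
    "effective_advantage",
    "fixation_approx",
    "perturbation_series",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SelectionTrajectory:
    """Per-generation selective advantages plus their reference value.

    ``s[k]`` is the advantage in generation k (0-indexed, all positive and
    small); ``s_bar`` is the reference (long-run average) advantage.  Beyond
    the stored horizon the trajectory is taken to sit at ``s_bar`` — all
    scenario trajectories converge there, and the geometric weights make the
    tail contribution negligible once ``(1 - s_bar)**len(s)`` is small.
    """

    s: np.ndarray
    s_bar: float
    source: str = "explicit"
    meta: dict | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.s, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("trajectory must be a nonempty 1-d array")
        if np.any(arr <= 0):
            raise ValueError("all s_k must be positive")
        if not (self.s_bar > 0):
            raise ValueError("s_bar must be positive")
        object.__setattr__(self, "s", arr)

    def __len__(self) -> int:
        return self.s.size

    def value_at(self, k: int) -> float:
        return float(self.s[k]) if k < self.s.size else self.s_bar


def reference_advantage(
    s: Sequence[float] | np.ndarray | SelectionTrajectory,
    horizon: int = 2**24,
    tol: float = 1e-6,
) -> float:
    """Cesaro mean (1/n) sum_{k<n} s_k, with doubling-n stabilisation.

    The running mean converges only as O(1/n) for oscillating trajectories,
    so ``tol`` is a stopping rule on the successive relative change, not a
    bound on the distance to the true limit.  Scenario constructors carry
    their analytic limits; this estimator is the generic fallback for
    explicit trajectories.
    """
    if isinstance(s, SelectionTrajectory):
        arr = s.s
    else:
        arr = np.asarray(s, dtype=float)
    if arr.size == 0:
        raise ValueError("empty trajectory")
    n = min(64, arr.size)
    prev = float(np.mean(arr[:n]))
    if n == arr.size:
        return prev
    while True:
        n = min(2 * n, arr.size)
        cur = float(np.mean(arr[:n]))
        if abs(cur - prev) <= tol * max(abs(cur), 1e-300):
            return cur
        if n == arr.size:
            return cur  # exhausted the data; best available estimate
        if n > horizon:
            raise RuntimeError(f"Cesaro mean not stable within horizon {horizon}")
        prev = cur


def truncation_horizon(s_bar: float, tol: float) -> int:
    """Smallest K with geometric tail mass (1 - s_bar)**K below ``tol``."""
    if not (0.0 < s_bar < 1.0):
        raise ValueError("s_bar must lie in (0, 1)")
    if tol <= 0 or tol >= 1:
        raise ValueError("tol must lie in (0, 1)")
    return max(1, math.ceil(math.log(tol) / math.log1p(-s_bar)))


def geometric_weights(s_bar: float, K: int) -> tuple[np.ndarray, float]:
    """Weights w_k = s_bar (1 - s_bar)**k for k < K, plus the tail mass.

    The full series sums to one; the returned tail mass is (1 - s_bar)**K.
    """
    if not (0.0 < s_bar < 1.0):
        raise ValueError("s_bar must lie in (0, 1)")
    if K < 1:
        raise ValueError("K must be positive")
    k = np.arange(K)
    w = s_bar * np.power(1.0 - s_bar, k)
    return w, float((1.0 - s_bar) ** K)


def effective_advantage(
    trajectory: SelectionTrajectory,
    tol: float = 1e-10,
) -> float:
    """Weighted average s_e = sum_k w_k s_k, truncated at tail mass ``tol``.

    Generations beyond the stored trajectory contribute at the reference
    value s_bar, so s_e is bounded by [min s_k, max s_k] whenever the
    trajectory is (the weights are a probability distribution).
    """
    s_bar = trajectory.s_bar
    K = truncation_horizon(s_bar, tol)
    L = min(K, len(trajectory))
    w, _ = geometric_weights(s_bar, L)
    head = float(np.dot(w, trajectory.s[:L]))
    tail_mass = (1.0 - s_bar) ** L
    return head + tail_mass * s_bar


def fixation_approx(s_e: float, mechanism: str = "generation_time") -> float:
    """First-order fixation probability from the effective advantage.

    ``s_e / ln 2`` for generation-time mutants, ``2 s_e`` for fecundity
    mutants; their ratio is the classical 2 ln 2 overestimate incurred by
    treating a faster replicator as a more fecund one.
    """
    if s_e <= 0:
        raise ValueError("s_e must be positive")
    if mechanism in ("generation_time", "gentime"):
        p = s_e / LN2
    elif mechanism == "fecundity":
        p = 2.0 * s_e
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if p >= 1.0:
        raise ValueError(f"approximation invalid: s_e = {s_e} gives p = {p} >= 1")
    return p


def perturbation_series(
    trajectory: SelectionTrajectory,
    p_bar: float | None = None,
    tol: float = 1e-10,
) -> float:
    """First-order perturbation of the fixation probability around s_bar.

    Returns ``p_bar + p_bar * sum_k (s_k - s_bar) sigma**k`` with
    ``sigma = 1 - s_bar``; algebraically identical to
    ``p_bar * sum_k s_k (1 - s_bar)**k`` and hence — when ``p_bar`` is left
    at its default ``s_bar / ln 2`` — to
    ``fixation_approx(effective_advantage(trajectory), "generation_time")``.
    Supplying a numeric ``p_bar`` (e.g. the constant-environment fixed point)
    isolates the genuinely environment-dependent part of the error for
    sensitivity checks.
    """
    s_bar = trajectory.s_bar
    if p_bar is None:
        p_bar = s_bar / LN2
    if not (0.0 < p_bar < 1.0):
        raise ValueError("p_bar must lie in (0, 1)")
    sigma = 1.0 - s_bar
    K = truncation_horizon(s_bar, tol)
    L = min(K, len(trajectory))
    k = np.arange(L)
    correction = float(np.dot(trajectory.s[:L] - s_bar, np.power(sigma, k)))
    return p_bar + p_bar * correction
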