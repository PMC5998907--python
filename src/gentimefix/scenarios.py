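"""Four biological cases of a changing environment.

Each case supplies (i) a per-generation selective-advantage trajectory s_k for
a generation-time mutant, (ii) the analytic reference advantage s_bar, and
(iii) a closed-form effective advantage / fixation probability obtained by
summing the geometric weight series exactly:

* monotone     — s_k relaxes exponentially (rate 1/2 per generation) from s_0
                 to s_inf; models a stressor whose benefit builds up.
* cyclic       — s_k = s_mean + ds cos(k rho + theta); seasonal selection.
* demography   — constant mutant advantage s in a population whose census
                 follows Beverton-Holt growth to carrying capacity; the
                 mutant's net per-generation advantage is modulated by the
                 changing census.
* ar1          — s_k follows a positively autocorrelated AR(1) process around
                 s_mean with Gaussian innovations; random environments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .effective import LN2, SelectionTrajectory, truncation_horizon

__all__ = [
    "MonotoneParams",
    "CyclicParams",
    "DemographyParams",
    "AR1Params",
    "monotone_selection",
    "monotone_trajectory",
    "monotone_closed_form",
    "cyclic_selection",
    "cyclic_trajectory",
    "cyclic_closed_form",
    "beverton_holt",
    "demography_selection",
    "demography_trajectory",
    "demography_survival_fn",
    "ar1_path",
    "ar1_closed_form",
    "AR1_CLAMP_FLOOR",
]

#: decay rate (per generation) of the monotone relaxation; fixed by the model
MONOTONE_DECAY = 0.5

#: floor applied to AR(1) draws that would leave the beneficial regime
AR1_CLAMP_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# monotone increase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonotoneParams:
    """s_k = s0 exp(-k/2) + s_inf (1 - exp(-k/2))."""

    s0: float
    s_inf: float

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be nonnegative")
        if self.s_inf <= 0:
            raise ValueError("s_inf must be positive")


def monotone_selection(k, params: MonotoneParams):
    """Exponential relaxation from s0 to s_inf (vectorised over k)."""
    k = np.asarray(k, dtype=float)
    decay = np.exp(-MONOTONE_DECAY * k)
    out = params.s0 * decay + params.s_inf * (1.0 - decay)
    return float(out) if out.ndim == 0 else out


def monotone_trajectory(params: MonotoneParams, length: int | None = None) -> SelectionTrajectory:
    if length is None:
        length = truncation_horizon(params.s_inf, 1e-12)
    s = monotone_selection(np.arange(length), params)
    # k = 0 with s0 = 0 sits exactly on the boundary of the beneficial regime;
    # nudge it in so downstream positivity checks hold (s_1 > 0 always).
    s = np.maximum(s, AR1_CLAMP_FLOOR)
    return SelectionTrajectory(s=s, s_bar=params.s_inf, source="scenario")


def monotone_closed_form(params: MonotoneParams) -> tuple[float, float, float]:
    """(s_bar, s_e, p) with the geometric series summed analytically.

    s_bar = s_inf (the Cesaro mean); s_e = s_inf [1 + (s0 - s_inf) /
    (1 - exp(-1/2)(1 - s_inf))]; p = s_e / ln 2.
    """
    s_bar = params.s_inf
    bracket = 1.0 + (params.s0 - params.s_inf) / (
        1.0 - math.exp(-MONOTONE_DECAY) * (1.0 - s_bar)
    )
    s_e = s_bar * bracket
    p = s_e / LN2
    if not (0.0 < p < 1.0):
        raise ValueError(f"closed-form p out of (0, 1): {p}")
    return s_bar, s_e, p


# ---------------------------------------------------------------------------
# cyclic selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CyclicParams:
    """s_k = s_mean + delta_s cos(k rho + theta); rho, theta in radians."""

    s_mean: float
    delta_s: float
    rho: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.s_mean <= 0:
            raise ValueError("s_mean must be positive")
        if self.delta_s < 0:
            raise ValueError("delta_s must be nonnegative")
        if self.delta_s >= self.s_mean:
            raise ValueError("delta_s must be below s_mean to keep s_k positive")


def cyclic_selection(k, params: CyclicParams):
    k = np.asarray(k, dtype=float)
    out = params.s_mean + params.delta_s * np.cos(k * params.rho + params.theta)
    return float(out) if out.ndim == 0 else out


def cyclic_trajectory(params: CyclicParams, length: int | None = None) -> SelectionTrajectory:
    if length is None:
        length = truncation_horizon(params.s_mean, 1e-12)
    s = cyclic_selection(np.arange(length), params)
    return SelectionTrajectory(s=s, s_bar=params.s_mean, source="scenario")


def cyclic_closed_form(params: CyclicParams) -> tuple[float, float, float]:
    """(s_bar, s_e, p) for cyclic selection.

    Summing sum_k (1-s_bar)**k cos(k rho + theta) in closed form gives

        s_e = s_mean [1 + ds ((1-s_mean) cos(rho - theta) - cos theta)
                           / (2 (1-s_mean) cos rho - (1-s_mean)**2 - 1)].
    """
    s_bar = params.s_mean
    q = 1.0 - s_bar
    denom = 2.0 * q * math.cos(params.rho) - q * q - 1.0
    if denom == 0.0:
        raise ValueError("degenerate cyclic parameters: zero resonance denominator")
    bracket = 1.0 + params.delta_s * (
        q * math.cos(params.rho - params.theta) - math.cos(params.theta)
    ) / denom
    s_e = s_bar * bracket
    p = s_e / LN2
    if not (0.0 < p < 1.0):
        raise ValueError(f"closed-form p out of (0, 1): {p}")
    return s_bar, s_e, p


# ---------------------------------------------------------------------------
# Beverton-Holt demography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemographyParams:
    """Constant mutant advantage s; wild-type census follows Beverton-Holt.

    N_n = C N0 / (N0 + (C - N0) exp(-g n)): logistic-form approach to the
    carrying capacity C from the initial census N0 at rate g.
    """

    s: float
    N0: float
    C: float
    g: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.N0 <= 0 or self.C <= 0:
            raise ValueError("N0 and C must be positive")


def beverton_holt(n, params: DemographyParams):
    """Census size at generation n (vectorised)."""
    n = np.asarray(n, dtype=float)
    out = params.C * params.N0 / (params.N0 + (params.C - params.N0) * np.exp(-params.g * n))
    return float(out) if out.ndim == 0 else out


def demography_selection(n, params: DemographyParams):
    """Mutant net advantage s_n = M_n - 1 with M_n = (N_{n+1}/N_n)(1+s).

    M_n is the mutant's net mean surviving offspring in generation n; the
    reference advantage is s itself (the carrying-capacity regime, where
    N_{n+1}/N_n -> 1).
    """
    n = np.asarray(n)
    ratio = beverton_holt(np.asarray(n, dtype=float) + 1.0, params) / beverton_holt(n, params)
    out = ratio * (1.0 + params.s) - 1.0
    return float(out) if np.ndim(out) == 0 else out


def demography_trajectory(params: DemographyParams, length: int | None = None) -> SelectionTrajectory:
    if length is None:
        length = truncation_horizon(params.s, 1e-12)
    s = np.asarray(demography_selection(np.arange(length), params))
    if np.any(s <= 0):
        bad = int(np.argmax(s <= 0))
        raise ValueError(
            f"net advantage s_n <= 0 at generation {bad} (shrinking census overwhelms s); "
            "outside the validity of the beneficial-mutant approximation"
        )
    return SelectionTrajectory(s=s, s_bar=params.s, source="scenario")


def demography_survival_fn(params: DemographyParams, r: float = 2.0):
    """Per-generation wild-type bottleneck survival N_{n+1} / (r N_n).

    Makes the wild-type net mean exactly the census ratio N_{n+1}/N_n while
    the growth mean stays r; used as the per-cycle sampling survival of the
    exact branching-process computation under changing population size.
    """

    def survival(n: int) -> float:
        return float(
            beverton_holt(n + 1, params) / (r * beverton_holt(n, params))
        )

    return survival


# ---------------------------------------------------------------------------
# AR(1) stochastic selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AR1Params:
    """s_k = (1 - lam) s_mean + lam s_{k-1} + xi_k, xi_k ~ N(0, noise_sd**2)."""

    s_mean: float
    lam: float
    noise_sd: float
    s0: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_mean <= 0:
            raise ValueError("s_mean must be positive")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")


def ar1_path(
    params: AR1Params,
    length: int,
    rng: np.random.Generator | None = None,
) -> SelectionTrajectory:
    """One seeded sample path of the AR(1) selection process.

    Draws that would leave the beneficial regime (s_k <= 0) are clamped to
    ``AR1_CLAMP_FLOOR``; the clamp count is recorded in ``meta["n_clamped"]``
    and a warning is emitted when any occur.
    """
    if length < 1:
        raise ValueError("length must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    s = np.empty(length, dtype=float)
    s[0] = params.s0
    xi = rng.normal(0.0, params.noise_sd, size=length - 1) if length > 1 else np.empty(0)
    n_clamped = 0
    prev = params.s0
    for k in range(1, length):
        val = (1.0 - params.lam) * params.s_mean + params.lam * prev + xi[k - 1]
        if val <= 0.0:
            val = AR1_CLAMP_FLOOR
            n_clamped += 1
        s[k] = val
        prev = val
    if n_clamped:
        warnings.warn(
            f"AR(1) path clamped {n_clamped} draw(s) at {AR1_CLAMP_FLOOR}",
            RuntimeWarning,
            stacklevel=2,
        )
    return SelectionTrajectory(
        s=s,
        s_bar=params.s_mean,
        source="sampled",
        meta={"n_clamped": n_clamped, "seed": params.seed},
    )


def ar1_closed_form(params: AR1Params, k: int | None = None) -> tuple[float, float]:
    """Conditional mean E[s_k | s0] and expected fixation probability.

    E[s_k|s0] = (1 - lam**k) s_mean + lam**k s0, and averaging the
    effective-advantage series over the noise gives

        E[p | s0] = (s_mean / ln 2) [1 + (s0 - s_mean) / (1 - lam (1 - s_mean))].
    """
    lam_k = params.lam ** k if k is not None else 0.0
    cond_mean = (1.0 - lam_k) * params.s_mean + lam_k * params.s0
    expected_p = (params.s_mean / LN2) * (
        1.0 + (params.s0 - params.s_mean) / (1.0 - params.lam * (1.0 - params.s_mean))
    )
    return cond_mean, expected_p
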