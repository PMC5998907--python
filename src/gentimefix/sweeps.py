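"""Approximation-vs-exact comparison sweeps.

For each point of a parameter grid the sweep computes the fixation
probability three ways and records them side by side:

* ``p_exact``  — nested backward iteration of the time-dependent
  branching-process recursion over the explicit stage schedule;
* ``p_approx`` — the scenario's first-order effective-advantage closed form;
* ``mc_estimate`` (optional) — the Monte Carlo lineage simulator with a 99%
  confidence half-width.

Also houses the fecundity-mutant numeric route (per-generation growth mean
r(1+s_k), shared bottleneck sampling), the constant-environment counterpart
of the generation-time machinery.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .effective import LN2, SelectionTrajectory, effective_advantage, fixation_approx
from .gentime import GenTimeCycleFactory, GenTimeParams, gentime_fixation_numeric
from .montecarlo import MonteCarloSpec, monte_carlo_fixation
from .pgf import (
    CompositePGF,
    ConvergenceError,
    FixationResult,
    StagePGF,
    extinction_probability,
    time_dependent_extinction,
)
from . import scenarios as sc

__all__ = [
    "ComparisonRecord",
    "FecundityCycleFactory",
    "fecundity_fixation_numeric",
    "fecundity_perturbation_exact",
    "comparison_sweep",
    "records_to_dataframe",
    "SCENARIOS",
]

SCENARIOS = ("constant", "monotone", "cyclic", "demography", "ar1")


class FecundityCycleFactory:
    """Cycle pgfs of a fecundity mutant: growth mean r(1+s_k), sampling r**-tau."""

    def __init__(
        self,
        r: float = 2.0,
        tau: int = 1,
        s: float | None = None,
        s_per_generation: Callable[[int], float] | Sequence[float] | None = None,
        survival: float | Callable[[int], float] | None = None,
    ):
        if (s is None) == (s_per_generation is None):
            raise ValueError("provide exactly one of s or s_per_generation")
        self.r = float(r)
        self.tau = int(tau)
        if s_per_generation is None:
            self._s_fn = lambda k, _s=float(s): _s
        elif callable(s_per_generation):
            self._s_fn = s_per_generation
        else:
            arr = np.asarray(s_per_generation, dtype=float)
            self._s_fn = lambda k, _a=arr: float(_a[min(k, _a.size - 1)])
        if survival is None:
            survival = self.r ** (-self.tau)
        self._survival = survival
        self._cache: dict[int, CompositePGF] = {}

    def cycle_signature(self, k: int) -> tuple[tuple[float, ...], float]:
        means = tuple(
            self.r * (1.0 + self._s_fn(k * self.tau + j)) for j in range(self.tau)
        )
        c = self._survival(k) if callable(self._survival) else self._survival
        return means, c

    def __call__(self, k: int) -> CompositePGF:
        comp = self._cache.get(k)
        if comp is None:
            means, c = self.cycle_signature(k)
            comp = CompositePGF(
                [StagePGF.growth(m) for m in means] + [StagePGF.sampling(c)]
            )
            if len(self._cache) < 65536:
                self._cache[k] = comp
        return comp


def fecundity_fixation_numeric(
    s: float | None = None,
    r: float = 2.0,
    tau: int = 1,
    s_per_generation=None,
    survival=None,
    tol: float = 1e-12,
) -> FixationResult:
    """Numeric fixation probability of a fecundity mutant.

    Constant environments use the scalar fixed point of the per-cycle pgf;
    variable environments the nested backward iteration.
    """
    if s_per_generation is None and survival is None:
        return extinction_probability(
            CompositePGF.cycle(tau, r * (1.0 + s), r ** (-tau)), tol=tol
        )
    factory = FecundityCycleFactory(
        r=r, tau=tau, s=s, s_per_generation=s_per_generation, survival=survival
    )
    return time_dependent_extinction(factory, tol=max(tol, 1e-12))


def fecundity_perturbation_exact(
    trajectory: SelectionTrajectory,
    r: float = 2.0,
    tol: float = 1e-12,
) -> float:
    """First-order fixation probability with exact reference ingredients.

    Expands the nested extinction recursion of a fecundity mutant (per-cycle
    pgf ``exp((1+s_k)(x-1))`` after bottleneck thinning) around the constant
    reference environment, keeping the *exact* reference fixed point q_bar,
    the exact decay factor ``sigma = phi_bar'(q_bar)`` and the exact
    disturbance values ``phi_k(q_bar) - phi_bar(q_bar)``.  Its residual
    against the nested numeric value is second order in the fluctuation
    amplitude ``max_k |s_k - s_bar|`` — the sharpest form of the first-order
    theory, used to verify the quadratic remainder empirically.  (The fully
    simplified closed forms add O(s_bar * amplitude) terms on top, from
    ``sigma ~ 1 - s_bar`` and the linearised disturbance.)
    """
    from .effective import truncation_horizon

    s_bar = trajectory.s_bar
    ref = fecundity_fixation_numeric(s=s_bar, r=r, tau=1, tol=1e-14)
    q_bar, p_bar = ref.q, ref.p
    sigma = (1.0 + s_bar) * math.exp((1.0 + s_bar) * (q_bar - 1.0))
    L = min(truncation_horizon(s_bar, tol), len(trajectory))
    k = np.arange(L)
    eps_k = np.exp((1.0 + trajectory.s[:L]) * (q_bar - 1.0)) - math.exp(
        (1.0 + s_bar) * (q_bar - 1.0)
    )
    return p_bar - float(np.dot(eps_k, np.power(sigma, k)))


@dataclass(frozen=True)
class ComparisonRecord:
    """One grid point of an approximation-vs-exact comparison."""

    scenario: str
    mechanism: str
    parameters: dict
    p_exact: float
    p_approx: float
    rel_err: float
    mc_estimate: float | None = None
    mc_ci99: float | None = None
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"scenario": self.scenario, "mechanism": self.mechanism}
        row.update(self.parameters)
        row.update(
            p_exact=self.p_exact,
            p_approx=self.p_approx,
            rel_err=self.rel_err,
            mc_estimate=self.mc_estimate,
            mc_ci99=self.mc_ci99,
        )
        return row


def records_to_dataframe(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


def _expand_grid(grid: Mapping[str, object]) -> list[dict]:
    keys, columns = [], []
    for key, value in grid.items():
        keys.append(key)
        columns.append(list(value) if isinstance(value, (list, tuple, np.ndarray)) else [value])
    return [dict(zip(keys, combo)) for combo in itertools.product(*columns)]


def _positive_monotone_fn(params: sc.MonotoneParams) -> Callable[[int], float]:
    def s_at(k: int) -> float:
        return max(sc.monotone_selection(k, params), sc.AR1_CLAMP_FLOOR)
    return s_at


def _point_record(
    scenario: str,
    mechanism: str,
    point: dict,
    r: float,
    tau: int,
    tol: float,
    spec: MonteCarloSpec | None,
) -> ComparisonRecord:
    extra: dict = {"tol": tol, "r": r, "tau": tau}
    mech_kind = "fecundity" if mechanism == "fecundity" else "generation_time"
    survival = None

    if scenario == "constant":
        s = float(point["s"])
        s_fn = None
        traj = SelectionTrajectory(s=np.array([s]), s_bar=s, source="scenario")
        p_approx = fixation_approx(s, mech_kind)
    elif scenario == "monotone":
        mp = sc.MonotoneParams(s0=float(point["s0"]), s_inf=float(point["s_inf"]))
        s_fn = _positive_monotone_fn(mp)
        traj = sc.monotone_trajectory(mp)
        if mech_kind == "generation_time":
            _, s_e, p_approx = sc.monotone_closed_form(mp)
            extra["s_e"] = s_e
        else:
            p_approx = fixation_approx(effective_advantage(traj), "fecundity")
        s = mp.s_inf
    elif scenario == "cyclic":
        cp = sc.CyclicParams(
            s_mean=float(point["s_mean"]),
            delta_s=float(point["delta_s"]),
            rho=float(point["rho"]),
            theta=float(point.get("theta", 0.0)),
        )
        s_fn = lambda k: float(sc.cyclic_selection(k, cp))
        traj = sc.cyclic_trajectory(cp)
        if mech_kind == "generation_time":
            _, s_e, p_approx = sc.cyclic_closed_form(cp)
            extra["s_e"] = s_e
        else:
            p_approx = fixation_approx(effective_advantage(traj), "fecundity")
        s = cp.s_mean
    elif scenario == "demography":
        dp = sc.DemographyParams(
            s=float(point["s"]),
            N0=float(point["n0"]),
            C=float(point["capacity"]),
            g=float(point["growth_rate"]),
        )
        traj = sc.demography_trajectory(dp)
        survival = sc.demography_survival_fn(dp, r=r)
        s_fn = None  # constant mutant advantage; census enters via survival
        s = dp.s
        s_e = effective_advantage(traj)
        extra["s_e"] = s_e
        p_approx = fixation_approx(s_e, mech_kind)
    elif scenario == "ar1":
        ap = sc.AR1Params(
            s_mean=float(point["s_mean"]),
            lam=float(point["lam"]),
            noise_sd=float(point["noise_sd"]),
            s0=float(point["s0"]),
            seed=int(point.get("seed", 0)),
        )
        traj = sc.ar1_path(ap, length=2**14)
        s_fn = traj.value_at
        s = ap.s_mean
        s_e = effective_advantage(traj)
        extra["s_e"] = s_e
        extra["expected_p"] = sc.ar1_closed_form(ap)[1]
        extra["n_clamped"] = traj.meta["n_clamped"]
        p_approx = fixation_approx(s_e, mech_kind)
    else:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")

    try:
        if mech_kind == "fecundity":
            if scenario == "constant":
                res = fecundity_fixation_numeric(s=s, r=r, tau=tau, tol=min(tol, 1e-12))
            else:
                res = fecundity_fixation_numeric(
                    s=None if s_fn is not None else s,
                    r=r,
                    tau=tau,
                    s_per_generation=s_fn,
                    survival=survival,
                    tol=tol,
                )
        else:
            gp = GenTimeParams(s=s, r=r, tau=tau)
            res = gentime_fixation_numeric(
                gp, tol=tol, s_per_generation=s_fn, survival=survival
            )
        p_exact = res.p
        extra["exact_iterations"] = res.iterations_or_reps
    except ConvergenceError as exc:
        p_exact = math.nan
        extra["convergence_error"] = str(exc)

    rel_err = (
        abs(p_approx - p_exact) / p_exact if p_exact and not math.isnan(p_exact) else math.nan
    )

    mc_estimate = mc_ci99 = None
    if spec is not None:
        if mech_kind == "fecundity":
            mc_factory = FecundityCycleFactory(
                r=r,
                tau=tau,
                s=s if s_fn is None else None,
                s_per_generation=s_fn,
                survival=survival,
            )
        else:
            mc_factory = GenTimeCycleFactory(
                r=r,
                tau=tau,
                s=s if s_fn is None else None,
                s_per_generation=s_fn,
                survival=survival,
            )
        mc = monte_carlo_fixation(mc_factory, spec)
        mc_estimate, mc_ci99 = mc.p, mc.ci_halfwidth
        extra["mc_seed"] = spec.seed

    return ComparisonRecord(
        scenario=scenario,
        mechanism=mechanism,
        parameters=dict(point),
        p_exact=p_exact,
        p_approx=p_approx,
        rel_err=rel_err,
        mc_estimate=mc_estimate,
        mc_ci99=mc_ci99,
        extra=extra,
    )


def comparison_sweep(
    scenario: str,
    grid: Mapping[str, object],
    spec: MonteCarloSpec | None = None,
    mechanism: str = "gentime",
    r: float = 2.0,
    tau: int = 1,
    tol: float = 1e-10,
) -> list[ComparisonRecord]:
    """Run one scenario over a parameter grid.

    ``grid`` maps parameter names to scalars or lists; list-valued entries
    are expanded as a Cartesian product.  Grid points that fail to converge
    are flagged (``p_exact = nan``) and the sweep continues.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    points = _expand_grid(grid)
    records = [
        _point_record(scenario, mechanism, point, r=r, tau=tau, tol=tol, spec=spec)
        for point in points
    ]
    # stable sort by the swept (list-valued) parameters, in grid order
    swept = [k for k, v in grid.items() if isinstance(v, (list, tuple, np.ndarray))]
    if swept:
        records.sort(key=lambda rec: tuple(rec.parameters[k] for k in swept))
    return records
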