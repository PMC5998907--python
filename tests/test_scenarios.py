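"""Scenario trajectory generators and their closed forms.

Each closed form is checked against the independent truncated-weighted-sum
oracle: s_e = sum_k w_k s_k computed directly from the generated trajectory.
"""

import math

import numpy as np
import pytest

from gentimefix.effective import (
    LN2,
    SelectionTrajectory,
    effective_advantage,
    geometric_weights,
    truncation_horizon,
)
from gentimefix.scenarios import (
    AR1Params,
    CyclicParams,
    DemographyParams,
    MonotoneParams,
    ar1_closed_form,
    ar1_path,
    beverton_holt,
    cyclic_closed_form,
    cyclic_selection,
    cyclic_trajectory,
    demography_selection,
    demography_survival_fn,
    demography_trajectory,
    monotone_closed_form,
    monotone_selection,
    monotone_trajectory,
)


def direct_weighted_sum(s_k: np.ndarray, s_bar: float, tol: float = 1e-12) -> float:
    """Independent oracle: truncated sum w_k s_k with the tail at s_bar."""
    K = truncation_horizon(s_bar, tol)
    L = min(K, s_k.size)
    w, _ = geometric_weights(s_bar, L)
    return float(np.dot(w, s_k[:L])) + (1.0 - s_bar) ** L * s_bar


class TestMonotone:
    def test_endpoints(self):
        p = MonotoneParams(s0=0.002, s_inf=0.01)
        assert monotone_selection(0, p) == pytest.approx(0.002)
        assert monotone_selection(10_000, p) == pytest.approx(0.01)

    def test_constant_when_equal(self):
        p = MonotoneParams(s0=0.01, s_inf=0.01)
        assert np.allclose(monotone_selection(np.arange(50), p), 0.01)
        s_bar, s_e, prob = monotone_closed_form(p)
        assert (s_bar, s_e) == (0.01, pytest.approx(0.01, abs=1e-15))
        assert prob == pytest.approx(0.01 / LN2)

    @pytest.mark.parametrize("s0", [0.0, 0.001])
    def test_closed_form_equals_direct_sum(self, s0):
        p = MonotoneParams(s0=s0, s_inf=0.01)
        _, s_e, _ = monotone_closed_form(p)
        traj = monotone_selection(np.arange(4000), p)
        assert abs(s_e - direct_weighted_sum(traj, 0.01)) < 1e-10


class TestCyclic:
    def test_degenerate_amplitude(self):
        p = CyclicParams(s_mean=0.01, delta_s=0.0, rho=0.3)
        assert np.allclose(cyclic_selection(np.arange(20), p), 0.01)
        assert cyclic_closed_form(p)[2] == pytest.approx(0.01 / LN2)

    def test_phase(self):
        p = CyclicParams(s_mean=0.01, delta_s=0.005, rho=0.3, theta=math.pi)
        assert cyclic_selection(0, p) == pytest.approx(0.005)

    def test_periodicity(self):
        rho = 2 * math.pi / 50
        p = CyclicParams(s_mean=0.01, delta_s=0.004, rho=rho, theta=0.7)
        k = np.arange(100)
        s = cyclic_selection(k, p)
        assert np.allclose(s[:50], s[50:], atol=1e-15)

    def test_closed_form_equals_direct_sum(self):
        for rho in (0.1, 0.5, 1.0, 2.0):
            p = CyclicParams(s_mean=0.01, delta_s=0.005, rho=rho, theta=math.pi)
            _, s_e, _ = cyclic_closed_form(p)
            traj = cyclic_selection(np.arange(6000), p)
            assert abs(s_e - direct_weighted_sum(traj, 0.01)) < 1e-10

    def test_zero_frequency_limit_is_constant_trajectory(self):
        p = CyclicParams(s_mean=0.01, delta_s=0.004, rho=0.0, theta=0.0)
        _, s_e, _ = cyclic_closed_form(p)
        assert s_e == pytest.approx(0.014, rel=1e-12)
        traj = cyclic_trajectory(p, length=4000)
        assert s_e == pytest.approx(effective_advantage(traj), abs=1e-10)

    def test_amplitude_must_stay_beneficial(self):
        with pytest.raises(ValueError):
            CyclicParams(s_mean=0.01, delta_s=0.02, rho=0.5)


class TestBevertonHolt:
    def test_boundaries(self):
        p = DemographyParams(s=0.01, N0=500.0, C=1000.0, g=0.01)
        assert beverton_holt(0, p) == pytest.approx(500.0)
        assert beverton_holt(5000, p) == pytest.approx(1000.0, rel=1e-6)
        const = DemographyParams(s=0.01, N0=1000.0, C=1000.0, g=0.01)
        assert np.allclose(beverton_holt(np.arange(100), const), 1000.0)

    def test_selection_mapping(self):
        const = DemographyParams(s=0.01, N0=1000.0, C=1000.0, g=0.01)
        assert np.allclose(demography_selection(np.arange(50), const), 0.01)
        p = DemographyParams(s=0.01, N0=500.0, C=1000.0, g=0.01)
        s_n = demography_selection(np.arange(3000), p)
        assert s_n[0] > 0.01  # growing census boosts the net advantage
        assert s_n[-1] == pytest.approx(0.01, rel=1e-4)
        traj = demography_trajectory(p)
        assert traj.s_bar == 0.01

    def test_shrinking_census_flagged(self):
        bad = DemographyParams(s=0.001, N0=2000.0, C=1000.0, g=0.05)
        with pytest.raises(ValueError, match="s_n <= 0"):
            demography_trajectory(bad)

    def test_survival_fn_bounds(self):
        p = DemographyParams(s=0.01, N0=500.0, C=1000.0, g=0.01)
        surv = demography_survival_fn(p, r=2.0)
        vals = [surv(n) for n in range(200)]
        assert all(0.5 < c <= 0.51 for c in vals)  # N ratio in (1, 1.02)


def test_weak_early_selection_underestimates_fixation():
    """Known failure mode: with s_k << s_bar in early generations the
    first-order theory predicts a larger fixation loss than the exact
    iteration shows (it underestimates p relative to the reference)."""
    from gentimefix.gentime import GenTimeParams, gentime_fixation_numeric
    from gentimefix.scenarios import AR1_CLAMP_FLOOR

    s_bar = 0.01
    p_const = gentime_fixation_numeric(GenTimeParams(s=s_bar), tol=1e-11).p
    mp = MonotoneParams(s0=0.0, s_inf=s_bar)
    approx_shift = monotone_closed_form(mp)[2] - s_bar / LN2
    fn = lambda k: max(monotone_selection(k, mp), AR1_CLAMP_FLOOR)
    p_num = gentime_fixation_numeric(
        GenTimeParams(s=s_bar), tol=1e-11, s_per_generation=fn
    ).p
    exact_shift = p_num - p_const
    assert approx_shift < exact_shift < 0


class TestAR1:
    def test_degenerate_noise(self):
        p = AR1Params(s_mean=0.02, lam=1.0, noise_sd=0.0, s0=0.005)
        assert np.allclose(ar1_path(p, 20).s, 0.005)
        p0 = AR1Params(s_mean=0.02, lam=0.0, noise_sd=0.0, s0=0.005)
        path = ar1_path(p0, 20).s
        assert path[0] == 0.005 and np.allclose(path[1:], 0.02)

    def test_seeded_reproducibility(self):
        p = AR1Params(s_mean=0.02, lam=0.6, noise_sd=0.001, s0=0.001, seed=42)
        assert np.array_equal(ar1_path(p, 500).s, ar1_path(p, 500).s)

    def test_clamping_counted_and_warned(self):
        p = AR1Params(s_mean=0.0005, lam=0.2, noise_sd=0.01, s0=0.0005, seed=1)
        with pytest.warns(RuntimeWarning, match="clamped"):
            traj = ar1_path(p, 500)
        assert traj.meta["n_clamped"] > 0
        assert np.all(traj.s > 0)

    def test_stationary_mean(self):
        """Sample mean of s_k at large k approaches s_mean over many paths."""
        p = AR1Params(s_mean=0.02, lam=0.6, noise_sd=0.001, s0=0.001)
        rng = np.random.default_rng(2024)
        finals = [ar1_path(p, 200, rng=rng).s[-1] for _ in range(2000)]
        sd_stat = p.noise_sd / math.sqrt(1 - p.lam**2)
        assert abs(np.mean(finals) - p.s_mean) < 4 * sd_stat / math.sqrt(len(finals))

    def test_conditional_mean(self):
        p = AR1Params(s_mean=0.02, lam=0.6, noise_sd=0.001, s0=0.001)
        m0, _ = ar1_closed_form(p, 0)
        assert m0 == pytest.approx(0.001)
        m_inf, _ = ar1_closed_form(p, 10_000)
        assert m_inf == pytest.approx(0.02)
        _, ep = ar1_closed_form(AR1Params(s_mean=0.02, lam=0.6, noise_sd=0.001, s0=0.02))
        assert ep == pytest.approx(0.02 / LN2)

    def test_expected_p_equals_weighted_conditional_means(self):
        """E[p|s0] equals sum_k w_k E[s_k|s0] / ln 2 (geometric identity)."""
        p = AR1Params(s_mean=0.02, lam=0.6, noise_sd=0.001, s0=0.001)
        k = np.arange(4000)
        cond = (1 - p.lam**k) * p.s_mean + p.lam**k * p.s0
        oracle = direct_weighted_sum(cond, p.s_mean) / LN2
        _, ep = ar1_closed_form(p)
        assert abs(ep - oracle) < 1e-10
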