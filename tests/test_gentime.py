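"""Generation-time mutant machinery: schedule, stage sequences, fixation."""

import math

import numpy as np
import pytest

from gentimefix.effective import LN2
from gentimefix.gentime import (
    GenTimeParams,
    build_stage_sequence,
    extra_generation_schedule,
    generation_time_of,
    gentime_fixation_numeric,
    scaled_advantage,
)
from gentimefix.sweeps import fecundity_fixation_numeric


def brute_force_schedule(s_tilde: float, tau: int, n_max: int) -> list[int]:
    """Smallest n_i with (n_i tau + i) / (1 + s_tilde) <= n_i tau, by search."""
    out, i = [], 1
    for n in range(1, n_max + 1):
        while (n * tau + i) / (1.0 + s_tilde) <= n * tau + 1e-12:
            out.append(n)
            i += 1
    return out


class TestScaledAdvantage:
    def test_boundaries(self):
        assert scaled_advantage(0.0, 2.0) == 0.0
        assert scaled_advantage(1.0, 2.0) == pytest.approx(1.0, rel=1e-15)

    def test_small_s_form(self):
        s = 0.05
        st = scaled_advantage(s, 2.0)
        assert st == pytest.approx(math.log2(1.05), rel=1e-14)
        # s/ln r agrees to O(s^2)
        assert abs(st - s / LN2) < s ** 2

    def test_domain(self):
        with pytest.raises(ValueError):
            scaled_advantage(-1.5, 2.0)
        with pytest.raises(ValueError):
            scaled_advantage(0.1, 1.0)


@pytest.mark.parametrize(
    "s_tilde, expected", [(0.0, 1.0), (1.0, 0.5), (1 / 20, 20 / 21)]
)
def test_generation_time(s_tilde, expected):
    assert generation_time_of(s_tilde) == pytest.approx(expected, rel=1e-15)


def test_generation_time_rejects_deleterious():
    with pytest.raises(ValueError):
        generation_time_of(-0.1)


class TestExtraGenerationSchedule:
    def test_worked_example(self):
        """tau=5, s~=1/20: first extra generation fits at the 4th bottleneck."""
        sch = extra_generation_schedule(1 / 20, 5, 8)
        assert sch.extra_at == (4, 8)
        assert sch.t_g == pytest.approx(20 / 21)

    def test_every_cycle_when_advantage_is_one(self):
        sch = extra_generation_schedule(1.0, 1, 3)
        assert sch.extra_at == (1, 2, 3)

    def test_against_brute_force(self):
        for s_tilde, tau, n in [(0.01, 1, 250), (1 / 20, 5, 40), (0.037, 3, 60)]:
            sch = extra_generation_schedule(s_tilde, tau, n)
            assert list(sch.extra_at) == brute_force_schedule(s_tilde, tau, n)

    def test_spec_point(self):
        sch = extra_generation_schedule(0.01, 1, 250)
        assert sch.extra_at[:2] == (100, 200)

    @pytest.mark.parametrize("s_tilde, tau", [(0.03, 2), (1 / 20, 5), (0.2, 1)])
    def test_minimality(self, s_tilde, tau):
        """n_i is the smallest m with (m tau + i) t_g <= m tau."""
        t_g = generation_time_of(s_tilde)
        sch = extra_generation_schedule(s_tilde, tau, 200)
        for i, n_i in enumerate(sch.extra_at, start=1):
            assert (n_i * tau + i) * t_g <= n_i * tau + 1e-9
            for m in range(1, n_i):
                assert (m * tau + i) * t_g > m * tau - 1e-9


class TestStageSequence:
    def test_eight_cycle_pattern(self):
        """tau=5, s~=1/20: cycles read phi,phi,phi,phi+,phi,phi,phi,phi+."""
        s = 2.0 ** (1 / 20) - 1.0  # s~ = 1/20 exactly for r = 2
        seq = build_stage_sequence(GenTimeParams(s=s, tau=5), 8)
        n_growth = [len(c.stages) - 1 for c in seq]
        assert n_growth == [5, 5, 5, 6, 5, 5, 5, 6]
        # growth stages keep the wild-type mean r; bottleneck survival r^-tau
        for comp in seq:
            assert all(st.mean_offspring == 2.0 for st in comp.stages[:-1])
            assert comp.stages[-1].survival_prob == pytest.approx(2.0 ** -5)

    def test_vanishing_advantage_never_earns_extra_stage(self):
        seq = build_stage_sequence(GenTimeParams(s=1e-9, tau=1), 50)
        assert all(len(c.stages) == 2 for c in seq)

    def test_variable_constant_consistency(self):
        """A constant per-generation trajectory reproduces the constant schedule."""
        params = GenTimeParams(s=0.07, tau=3)
        n = 40
        const = build_stage_sequence(params, n)
        variable = build_stage_sequence(params, n, s_per_generation=[0.07] * (n * 3))
        assert const == variable

    def test_wildtype_composite_is_conservative(self):
        """Cycles without an extra stage have composite mean exactly 1."""
        seq = build_stage_sequence(GenTimeParams(s=0.05, tau=4), 6)
        for comp in seq:
            extras = len(comp.stages) - 1 - 4
            assert comp.mean == pytest.approx(2.0 ** extras, rel=1e-12)


class TestGenTimeFixation:
    def test_neutral_mutant_is_lost(self):
        assert gentime_fixation_numeric(GenTimeParams(s=0.0)).p == 0.0

    @pytest.mark.parametrize("s", [2e-3, 5e-3, 1e-2])
    def test_wahl_dehaan_recovery(self, s):
        """p approaches s/ln 2 for r=2, tau=1 constant environments."""
        p = gentime_fixation_numeric(GenTimeParams(s=s), tol=1e-11).p
        assert abs(p * LN2 / s - 1.0) <= 0.05

    def test_mechanism_ordering(self):
        """Equal s: fecundity fixes more easily than generation time."""
        s = 0.01
        p_gt = gentime_fixation_numeric(GenTimeParams(s=s), tol=1e-11).p
        p_fec = fecundity_fixation_numeric(s=s).p
        assert p_fec > p_gt
        assert p_fec / p_gt == pytest.approx(2 * LN2, rel=0.02)

    def test_serial_passage_interval(self):
        """tau=5 at s~=1/20: nested value is finite, positive, stable."""
        s = 2.0 ** (1 / 20) - 1.0
        res = gentime_fixation_numeric(GenTimeParams(s=s, tau=5), tol=1e-11)
        assert 0.0 < res.p < 1.0
        # halving the tolerance does not move the answer
        res2 = gentime_fixation_numeric(GenTimeParams(s=s, tau=5), tol=5e-12)
        assert res.p == pytest.approx(res2.p, abs=1e-9)
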