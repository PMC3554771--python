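"""Output, responsiveness, Gradient, bistability index, temporal classes."""

import numpy as np
import pytest

from mapkscreen.config import Thresholds
from mapkscreen.indicators import (bistability_index, classify_temporal,
                                   gradient, is_responsive, output)
from mapkscreen.network import SPECIES_INDEX
from mapkscreen.simulate import Trajectory
from mapkscreen.synth import synth_curves

PP = SPECIES_INDEX["pp-MAPK"]
CPLX = SPECIES_INDEX["MKP:pp-MAPK"]


class TestOutput:
    def test_zero_and_full_activation(self):
        state = np.zeros(20)
        assert output(state, 1.0) == 0.0
        state[PP] = 1.0
        assert output(state, 1.0) == 1.0

    def test_complexed_pp_mapk_not_counted(self):
        """Half the pp-MAPK sequestered on MKP contributes nothing to O."""
        free = np.zeros(20)
        free[PP] = 0.5
        bound = free.copy()
        bound[CPLX] = 0.5  # same total pp-MAPK, half in complex
        assert output(free, 1.0) == 0.5
        assert output(bound, 1.0) == 0.5  # only the free form counts

    def test_requires_positive_total(self):
        with pytest.raises(ValueError):
            output(np.zeros(20), 0.0)


def _traj_from_series(t, o):
    states = np.zeros((len(t), 20))
    states[:, PP] = o
    return Trajectory(np.asarray(t, float), states, mapk_total=1.0)


class TestResponsiveness:
    def test_flat_zero_not_responsive(self):
        flag, o_max = is_responsive(_traj_from_series([0, 1, 2], [0, 0, 0]))
        assert not flag and o_max == 0.0

    def test_threshold_is_strict(self):
        """O_max exactly 0.1 is NOT responsive (strict inequality)."""
        flag, o_max = is_responsive(
            _traj_from_series([0, 1, 2], [0.0, 0.05, 0.1]))
        assert o_max == 0.1 and not flag
        flag, _ = is_responsive(
            _traj_from_series([0, 1, 2], [0.0, 0.05, 0.100001]))
        assert flag

    def test_monotone_saturating_peak_is_final_value(self):
        t = np.linspace(0, 50, 200)
        o = 0.8 * (1 - np.exp(-t / 5))
        flag, o_max = is_responsive(_traj_from_series(t, o))
        assert flag and o_max == pytest.approx(o[-1])


class TestGradient:
    def test_linear_branch_closed_form(self):
        """O(S) = S / S_max gives Gradient = 0.8 / (0.8 S_max) = 1/S_max."""
        dr = synth_curves("linear", o_max=1.0, s_max=10.0)
        g = gradient(dr, refine=lambda s: s / 10.0)
        assert g.value == pytest.approx(1.0 / 10.0, rel=1e-4)
        assert not g.saturated
        # grid interpolation alone is within a percent
        assert gradient(dr).value == pytest.approx(0.1, rel=0.01)

    @pytest.mark.parametrize("n,K", [(1.0, 1.0), (2.0, 0.5), (4.0, 2.0)])
    def test_hill_branch_matches_analytic_inverse(self, n, K):
        """The saturated maximum is the largest output on the stimulus
        range, so the analytic anchors sit at 10%/90% of that value."""
        from mapkscreen.synth import hill_inverse
        dr = synth_curves("hill", K=K, n=n)
        hill = lambda s: s ** n / (K ** n + s ** n)  # noqa: E731
        o_max = hill(10.0)
        expected = 0.8 * o_max / (hill_inverse(0.9 * o_max, 1.0, K, n)
                                  - hill_inverse(0.1 * o_max, 1.0, K, n))
        g = gradient(dr, refine=hill)
        assert g.value == pytest.approx(expected, rel=0.01)

    def test_classification_threshold_strict(self):
        th = Thresholds()
        assert not (1.0 > th.ultrasensitive_gradient)
        assert 1.0 + 1e-9 > th.ultrasensitive_gradient

    def test_step_like_branch_reports_saturation(self):
        """A discontinuous switch: both anchors bisect to the same stimulus,
        so the secant is capped at the resolution floor and flagged."""
        dr = synth_curves("hill", K=1.0, n=2.0)
        o = np.where(dr.s_grid >= 1.0, 1.0, 0.0).astype(float)
        dr.up_output = o
        dr.down_output = o.copy()
        step = lambda s: 1.0 if s >= 1.0 else 0.0  # noqa: E731
        g = gradient(dr, refine=step)
        assert g.saturated and np.isfinite(g.value)
        assert g.value == pytest.approx(0.8 / (1e-4 * 10.0), rel=0.5)


class TestBistabilityIndex:
    def test_coinciding_branches_give_exactly_one(self):
        dr = synth_curves("hysteresis-pair", K_up=2.0, K_down=2.0)
        b = bistability_index(dr)
        assert b.value == 1.0
        assert b.raw_ratio == pytest.approx(1.0, abs=1e-9)

    def test_separated_branches_detected(self):
        dr = synth_curves("hysteresis-pair", K_up=2.0, K_down=0.1, n=6.0)
        b = bistability_index(dr)
        assert b.value > 1.5

    def test_index_bounded_by_ten(self):
        """Down branch saturated everywhere cannot push the index past 10."""
        for k_down in (0.01, 0.05, 0.2):
            dr = synth_curves("hysteresis-pair", K_up=5.0, K_down=k_down,
                              n=8.0)
            b = bistability_index(dr)
            assert 1.0 <= b.value <= 10.0

    def test_check_point_sits_at_ten_percent_level(self):
        dr = synth_curves("hill", K=1.0, n=2.0)
        b = bistability_index(dr)
        o_max = dr.o_ss_max
        # S_cp is where the up branch crosses 0.1 * O_ss_max
        from mapkscreen.synth import hill_inverse
        assert b.s_cp == pytest.approx(hill_inverse(0.1 * o_max, 1.0, 1.0, 2.0),
                                       rel=0.05)


class TestTemporalClassification:
    def test_monotone_saturating_is_none(self):
        t = np.linspace(0, 400, 400)
        o = 0.8 * (1 - np.exp(-t / 30))
        assert classify_temporal(_traj_from_series(t, o)) == "none"

    def test_peak_decay_is_transient(self):
        traj = synth_curves("peak-decay", peak=0.5, t_peak=20.0)
        assert classify_temporal(traj) == "transient"

    def test_sustained_sinusoid_is_oscillation(self):
        traj = synth_curves("sinusoid", mid=0.5, amp=0.2, period=50.0)
        assert classify_temporal(traj) == "oscillation"

    def test_decaying_ring_is_not_oscillation(self):
        """A damped ring fails the persistence requirement."""
        t = np.linspace(0, 400, 800)
        o = 0.4 + 0.3 * np.exp(-t / 40) * np.sin(2 * np.pi * t / 30)
        assert classify_temporal(_traj_from_series(t, np.clip(o, 0, None))) \
            != "oscillation"

    def test_small_amplitude_wiggle_is_none(self):
        traj = synth_curves("sinusoid", mid=0.5, amp=0.01, period=50.0)
        assert classify_temporal(traj) == "none"
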