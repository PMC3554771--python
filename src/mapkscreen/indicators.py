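"""Per-model dynamics indicators.

Output O: fraction of total MAPK present as *free* dual-phosphorylated
pp-MAPK.  Complexed pp-MAPK (sequestered on MKP) is catalytically
unavailable and is not counted.

Responsiveness: O_max > 0.1 over the time course at saturating stimulus.

Gradient (ultrasensitivity): secant slope of the up-branch steady-state
dose-response between the stimuli producing 10% and 90% of the saturated
maximum output O_ss_max,

    Gradient = (0.9 - 0.1) * O_ss_max / (S(0.9 O_ss_max) - S(0.1 O_ss_max)),

with Gradient > 1.0 classed as significantly ultrasensitive.

Bistability: ratio of down-sweep to up-sweep steady-state output at the
check-point stimulus S_cp = S(0.1 O_ss_max) on the up branch.  Since
O_up(S_cp) = 0.1 O_ss_max by construction and O_down <= O_ss_max, the index
lies in [1, 10]; > 1.5 is bistable, > 9.5 absolutely bistable.

Temporal classes: sustained oscillation and transient activation
(adaptation), detected on the saturating-stimulus time course.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.signal import find_peaks

from .config import Thresholds
from .network import SPECIES_INDEX
from .simulate import (DoseResponse, Trajectory, UnreachableOutputError,
                       invert_response)

__all__ = [
    "output", "is_responsive", "gradient", "bistability_index",
    "classify_temporal", "GradientResult", "BistabilityResult",
    "DynamicsReport", "IndeterminateBistabilityError",
]

_PP_MAPK = SPECIES_INDEX["pp-MAPK"]


class IndeterminateBistabilityError(ValueError):
    """The up branch never reaches the check-point output level."""


def output(state, mapk_total: float) -> float:
    """Activation strength O = free [pp-MAPK] / [MAPK]_total, in [0, 1]."""
    if mapk_total <= 0:
        raise ValueError("mapk_total must be > 0")
    return float(np.asarray(state, dtype=float)[_PP_MAPK]) / mapk_total


def is_responsive(traj: Trajectory, thresholds: Thresholds | None = None
                  ) -> tuple[bool, float]:
    """(flag, O_max): maximal output over the time course, strict > 0.1."""
    thresholds = thresholds or Thresholds()
    o_max = float(np.max(traj.output)) if traj.output.size else 0.0
    return o_max > thresholds.responsive_o_max, o_max


@dataclass(frozen=True)
class GradientResult:
    value: float
    o_ss_max: float
    s_low: float
    s_high: float
    saturated: bool = False  # denominator hit the stimulus-resolution floor

    def __float__(self):
        return self.value


def gradient(dr: DoseResponse, thresholds: Thresholds | None = None,
             refine: bool | Callable[[float], float] = False,
             tol_frac: float = 1e-4) -> GradientResult:
    """Ultrasensitivity secant of the up branch between the anchor outputs."""
    thresholds = thresholds or Thresholds()
    lo_f, hi_f = thresholds.gradient_anchor_low, thresholds.gradient_anchor_high
    o_max = dr.o_ss_max
    if o_max <= 0:
        raise ValueError("up branch has zero maximal output")
    s_lo = invert_response(dr, "up", lo_f * o_max, refine=refine,
                           tol_frac=tol_frac)
    s_hi = invert_response(dr, "up", hi_f * o_max, refine=refine,
                           tol_frac=tol_frac)
    s_max = float(dr.s_grid[-1])
    floor = tol_frac * s_max
    denom = s_hi - s_lo
    if denom < floor:
        # response switches within the stimulus resolution; report the
        # resolution-capped value rather than a spurious huge slope
        return GradientResult((hi_f - lo_f) * o_max / floor, o_max,
                              s_lo, s_hi, saturated=True)
    return GradientResult((hi_f - lo_f) * o_max / denom, o_max, s_lo, s_hi)


@dataclass(frozen=True)
class BistabilityResult:
    value: float        # index clamped to its theoretical range [1, 10]
    raw_ratio: float    # unclamped down/up output ratio
    s_cp: float         # check-point stimulus S(0.1 * O_ss_max), up branch
    o_ss_max: float

    def __float__(self):
        return self.value


def bistability_index(dr: DoseResponse, thresholds: Thresholds | None = None,
                      down_solver: Callable[[float], float] | None = None,
                      refine: bool | str = False,
                      tol_frac: float = 1e-4) -> BistabilityResult:
    """Down/up steady-state output ratio at the check-point stimulus.

    The check point S_cp is where the up branch reaches 10% of its saturated
    maximum, so the up output there is 0.1 * O_ss_max by construction and the
    index is bounded by 10.  ``down_solver`` (S -> output), when given,
    evaluates the down branch by a fresh steady-state solve from SCV_max;
    otherwise the down branch grid is interpolated.
    """
    thresholds = thresholds or Thresholds()
    lo_f = thresholds.gradient_anchor_low
    o_max = dr.o_ss_max
    if o_max <= 0:
        raise ValueError("up branch has zero maximal output")
    target = lo_f * o_max
    try:
        s_cp = invert_response(dr, "up", target, refine=refine,
                               tol_frac=tol_frac)
    except UnreachableOutputError as exc:
        raise IndeterminateBistabilityError(
            f"up branch never reaches the check-point level {target}"
        ) from exc

    if down_solver is not None:
        o_down = down_solver(s_cp)
    else:
        # interpolate the down branch on the same grid and scale as the up
        # branch: for coincident branches the two interpolations cancel
        # exactly, so steep mono-stable responses cannot fake hysteresis
        o_down = _interp_branch(dr, "down", s_cp)
    raw = o_down / target
    value = min(float(raw), 10.0)
    if value < 1.0 + 1e-9:   # mono-stable up to round-off reports exactly 1
        value = 1.0
    return BistabilityResult(value, raw, s_cp, o_max)


def _interp_branch(dr: DoseResponse, which: str, S: float) -> float:
    s, o, m = dr.branch(which)
    s, o = s[m], o[m]
    if s.size == 0:
        raise IndeterminateBistabilityError(f"{which} branch has no valid points")
    if S <= s[0]:
        return float(o[0])
    if S >= s[-1]:
        return float(o[-1])
    i = int(np.searchsorted(s, S)) - 1
    s_lo, s_hi, o_lo, o_hi = s[i], s[i + 1], o[i], o[i + 1]
    if s_lo > 0:
        w = (np.log(S) - np.log(s_lo)) / (np.log(s_hi) - np.log(s_lo))
    else:
        w = (S - s_lo) / (s_hi - s_lo)
    return float(o_lo + w * (o_hi - o_lo))


def classify_temporal(traj: Trajectory, thresholds: Thresholds | None = None
                      ) -> str:
    """'oscillation', 'transient', or 'none' for a fixed-stimulus time course.

    Oscillation: at least ``oscillation_min_peaks`` maxima after the first
    quarter of the horizon, peak-to-trough amplitude above
    ``oscillation_min_amplitude``, and last/first peak amplitude ratio above
    ``oscillation_persistence`` (sustained, not a decaying ring).
    Transient: O_max > 0.1 reached in the first half of the horizon with the
    final output below ``transient_decay_fraction`` * O_max.
    """
    th = thresholds or Thresholds()
    t, o = traj.t, traj.output
    if o.size < 8:
        return "none"
    horizon = t[-1] - t[0]
    o_max = float(np.max(o))

    late = t >= t[0] + 0.25 * horizon
    o_late, t_late = o[late], t[late]
    peaks, _ = find_peaks(o_late)
    troughs, _ = find_peaks(-o_late)
    if len(peaks) >= th.oscillation_min_peaks and len(troughs) >= 1:
        amp = float(np.max(o_late[peaks]) - np.min(o_late[troughs]))
        base = float(np.min(o_late[troughs]))
        first_amp = o_late[peaks[0]] - base
        last_amp = o_late[peaks[-1]] - base
        if (amp > th.oscillation_min_amplitude and first_amp > 0
                and last_amp / first_amp > th.oscillation_persistence):
            return "oscillation"

    t_peak = float(t[int(np.argmax(o))])
    if (o_max > th.responsive_o_max
            and t_peak <= t[0] + 0.5 * horizon
            and float(o[-1]) < th.transient_decay_fraction * o_max):
        return "transient"
    return "none"


@dataclass
class DynamicsReport:
    """Indicator bundle for one (concentration vector, rate vector, topology)."""

    cv_id: int | None
    krv_id: int | None
    topology: str
    o_max: float
    responsive: bool
    o_ss_max: float | None = None
    gradient: float | None = None
    ultrasensitive: bool | None = None
    bistability: float | None = None
    bistable: bool | None = None
    absolutely_bistable: bool | None = None
    s_cp: float | None = None
    temporal_class: str = "none"
    status: str = "ok"  # ok | failed | non-stationary | indeterminate

    def to_row(self) -> dict:
        return dict(self.__dict__)
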