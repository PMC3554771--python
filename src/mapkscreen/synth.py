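"""Closed-form dose-response curves and trajectories for indicator testing.

These bypass the ODE solver entirely: they build :class:`DoseResponse` /
:class:`Trajectory` containers from analytic expressions with known
indicator values, so the Gradient, bistability-index and temporal
classifiers can be checked against closed forms.
"""

from __future__ import annotations

import numpy as np

from .config import default_s_grid
from .network import SPECIES_INDEX
from .simulate import DoseResponse, Trajectory

__all__ = ["synth_curves", "hill_inverse", "hill_gradient"]

_PP_MAPK = SPECIES_INDEX["pp-MAPK"]


def hill_inverse(x: float, o_max: float, K: float, n: float) -> float:
    """Closed-form S(x) for the Hill curve O(S) = o_max S^n / (K^n + S^n)."""
    if not 0 < x < o_max:
        raise ValueError("x must lie strictly inside (0, o_max)")
    y = x / o_max
    return K * (y / (1 - y)) ** (1 / n)


def hill_gradient(o_max: float, K: float, n: float,
                  lo: float = 0.1, hi: float = 0.9) -> float:
    """Analytic 10%-90% secant Gradient of a Hill dose-response curve."""
    return (hi - lo) * o_max / (hill_inverse(hi * o_max, o_max, K, n)
                                - hill_inverse(lo * o_max, o_max, K, n))


def _curve_to_dr(s_grid: np.ndarray, up_o: np.ndarray, down_o: np.ndarray
                 ) -> DoseResponse:
    n = len(s_grid)
    up_states = np.zeros((n, len(SPECIES_INDEX)))
    down_states = np.zeros_like(up_states)
    up_states[:, _PP_MAPK] = up_o      # mapk_total = 1, so output == column
    down_states[:, _PP_MAPK] = down_o
    mask = np.ones(n, dtype=bool)
    return DoseResponse(
        s_grid=s_grid, up_states=up_states, down_states=down_states,
        up_output=up_o.astype(float), down_output=down_o.astype(float),
        up_mask=mask, down_mask=mask.copy(),
        scv_max=up_states[int(np.argmax(up_o))].copy(), mapk_total=1.0)


def synth_curves(kind: str, **params):
    """Analytic curve factory.

    kinds and their parameters (all optional, shown with defaults):

    - ``linear``: O(S) = o_max * S / s_max; ``o_max=1, s_max=10``
    - ``hill``: O(S) = o_max S^n / (K^n + S^n); ``o_max=1, K=1, n=2``
    - ``hysteresis-pair``: up and down branches are Hill curves with
      thresholds ``K_up=2`` and ``K_down=0.2`` (down >= up everywhere)
    - ``peak-decay``: O(t) = peak * (t/t_peak) exp(1 - t/t_peak);
      ``peak=0.5, t_peak=20, horizon=400``
    - ``sinusoid``: O(t) = mid + amp sin(2 pi t / period);
      ``mid=0.5, amp=0.2, period=50, horizon=400``

    Dose-response kinds return :class:`DoseResponse`; time-course kinds
    return :class:`Trajectory` (with [MAPK]_total = 1 so O equals the
    pp-MAPK coordinate).
    """
    if kind == "linear":
        o_max = params.pop("o_max", 1.0)
        s_max = params.pop("s_max", 10.0)
        _check_empty(kind, params)
        s = default_s_grid(s_max)
        o = o_max * s / s_max
        return _curve_to_dr(s, o, o.copy())
    if kind == "hill":
        o_max = params.pop("o_max", 1.0)
        K = params.pop("K", 1.0)
        n = params.pop("n", 2.0)
        s_max = params.pop("s_max", 10.0)
        _check_empty(kind, params)
        if K <= 0 or n <= 0:
            raise ValueError("hill curve needs K > 0 and n > 0")
        s = default_s_grid(s_max)
        o = o_max * s ** n / (K ** n + s ** n)
        return _curve_to_dr(s, o, o.copy())
    if kind == "hysteresis-pair":
        o_max = params.pop("o_max", 1.0)
        K_up = params.pop("K_up", 2.0)
        K_down = params.pop("K_down", 0.2)
        n = params.pop("n", 4.0)
        s_max = params.pop("s_max", 10.0)
        _check_empty(kind, params)
        if not 0 < K_down <= K_up:
            raise ValueError("need 0 < K_down <= K_up")
        s = default_s_grid(s_max)
        up = o_max * s ** n / (K_up ** n + s ** n)
        down = o_max * s ** n / (K_down ** n + s ** n)
        return _curve_to_dr(s, up, down)
    if kind == "peak-decay":
        peak = params.pop("peak", 0.5)
        t_peak = params.pop("t_peak", 20.0)
        horizon = params.pop("horizon", 400.0)
        _check_empty(kind, params)
        t = np.linspace(0, horizon, 400)
        o = peak * (t / t_peak) * np.exp(1 - t / t_peak)
        return _traj(t, o)
    if kind == "sinusoid":
        mid = params.pop("mid", 0.5)
        amp = params.pop("amp", 0.2)
        period = params.pop("period", 50.0)
        horizon = params.pop("horizon", 400.0)
        _check_empty(kind, params)
        if amp < 0 or mid - amp < 0:
            raise ValueError("sinusoid must stay nonnegative")
        t = np.linspace(0, horizon, 800)
        o = mid + amp * np.sin(2 * np.pi * t / period)
        return _traj(t, o)
    raise ValueError(f"unknown synthetic curve kind {kind!r}")


def _traj(t: np.ndarray, o: np.ndarray) -> Trajectory:
    states = np.zeros((len(t), len(SPECIES_INDEX)))
    states[:, _PP_MAPK] = o
    return Trajectory(t, states, mapk_total=1.0)


def _check_empty(kind: str, params: dict) -> None:
    if params:
        raise ValueError(f"unknown parameters for {kind!r}: {sorted(params)}")
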