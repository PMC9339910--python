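"""Projector LED luminance calibration.

Because of intrinsic polarisation of the optical path, LED luminance
varies sinusoidally (period 180 deg) with the polariser angle.  Each LED
is modelled as ``L(theta, c) = c * gain * (offset + amplitude *
cos(2*(theta - phase)))`` and equalised against a common target — the
lowest uncalibrated luminance over all LEDs and conditions — by
iteratively adjusting its drive current, producing a polariser-angle-
indexed lookup table per LED.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LedLuminanceModel",
    "CalibrationLUT",
    "CalibrationError",
    "fit_polariser_sinusoid",
    "select_calibration_target",
    "equalise_led",
    "build_lut",
]


class CalibrationError(RuntimeError):
    """Raised when LED equalisation fails to converge.

    Carries the iteration trace in ``trace`` (list of (current,
    luminance) pairs) for diagnosis.
    """

    def __init__(self, message: str, trace: list[tuple[float, float]] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class LedLuminanceModel:
    """Sinusoidal polariser-angle dependence of one LED's luminance.

    ``L(theta, current) = current * current_gain *
    (offset + amplitude * cos(2 * (theta - phase)))``
    with phase in degrees; the angular period is 180 deg.
    """

    offset: float
    amplitude: float
    phase: float  # deg, reported in [0, 180)
    current_gain: float = 1.0
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            # fold negative amplitude into a 90 deg phase shift
            self.amplitude = -self.amplitude
            self.phase += 90.0
        self.phase %= 180.0
        if self.offset < self.amplitude:
            raise ValueError(
                "offset must be >= amplitude (luminance non-negative)"
            )

    def luminance(self, theta_deg, current: float = 1.0):
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        ph = np.deg2rad(self.phase)
        return (
            current
            * self.current_gain
            * (self.offset + self.amplitude * np.cos(2.0 * (th - ph)))
        )

    def min_luminance(self, current: float = 1.0) -> float:
        return current * self.current_gain * (self.offset - self.amplitude)


@dataclass
class CalibrationLUT:
    """Polariser-angle-indexed drive currents for one LED."""

    led_id: str
    angles: np.ndarray  # deg
    currents: np.ndarray
    achieved_luminance: np.ndarray
    target: float
    tolerance: float

    def max_relative_error(self) -> float:
        return float(
            np.max(np.abs(self.achieved_luminance - self.target) / self.target)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "led_id": self.led_id,
                "angle_deg": self.angles,
                "current": self.currents,
                "luminance": self.achieved_luminance,
            }
        )


def fit_polariser_sinusoid(
    samples: Sequence[tuple[float, float]]
) -> LedLuminanceModel:
    """Least-squares fit of ``offset + amplitude*cos(2*(theta - phase))``.

    Linear in the basis ``[1, cos(2*theta), sin(2*theta)]``; requires at
    least three angles distinct modulo 180 deg.  The fitted phase is
    reported in [0, 180) and the residual norm is stored on the model.
    """
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to fit the sinusoid")
    theta = np.deg2rad(np.array([s[0] for s in samples], dtype=float))
    lum = np.array([s[1] for s in samples], dtype=float)

    design = np.column_stack(
        [np.ones_like(theta), np.cos(2 * theta), np.sin(2 * theta)]
    )
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError(
            "rank-deficient sampling: need >= 3 polariser angles distinct "
            "modulo 180 deg to separate offset, amplitude and phase"
        )
    coef, *_ = np.linalg.lstsq(design, lum, rcond=None)
    offset, a, b = coef
    amplitude = float(np.hypot(a, b))
    phase = float(np.rad2deg(0.5 * np.arctan2(b, a))) % 180.0
    if amplitude < 1e-12:
        phase = 0.0  # phase undefined for a flat response
    residual = float(np.linalg.norm(design @ coef - lum))
    return LedLuminanceModel(
        offset=float(offset),
        amplitude=amplitude,
        phase=phase,
        residual_norm=residual,
    )


def select_calibration_target(models: Sequence[LedLuminanceModel]) -> float:
    """Lowest uncalibrated luminance over all LEDs/conditions.

    The minimum over polariser angle of each model is closed-form
    (``gain * (offset - amplitude)`` at unit current); the target is the
    global minimum so every LED can be dimmed down to it.
    """
    models = list(models)
    if not models:
        raise ValueError("empty model set")
    return min(m.min_luminance() for m in models)


def equalise_led(
    luminance_oracle: Callable[[float, float], float],
    target: float,
    theta_deg: float,
    tolerance: float = 0.005,
    max_iter: int = 100,
    initial_current: float = 1.0,
) -> float:
    """Find the drive current at which the LED emits ``target`` luminance.

    ``luminance_oracle(current, theta_deg)`` must be monotone
    non-decreasing in current at fixed angle.  The solve is a bracketing
    bisection on that monotone map (the stable stand-in for the fixed-
    step descent the hardware procedure uses); convergence is judged on
    relative luminance error.

    Raises :class:`CalibrationError` with the iteration trace if the
    target is unreachable or the budget is exhausted.
    """
    if target <= 0:
        raise ValueError("target luminance must be positive")
    trace: list[tuple[float, float]] = []

    def f(c: float) -> float:
        lum = float(luminance_oracle(c, theta_deg))
        trace.append((c, lum))
        return lum

    lo, hi = 0.0, max(initial_current, 1e-9)
    lum_hi = f(hi)
    n_expand = 0
    while lum_hi < target:
        hi *= 2.0
        lum_hi = f(hi)
        n_expand += 1
        if n_expand > 60:
            raise CalibrationError(
                f"target {target} unreachable: luminance plateaued at "
                f"{lum_hi} by current {hi}",
                trace,
            )

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        lum = f(mid)
        if abs(lum - target) / target <= tolerance:
            return mid
        if lum < target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"no convergence within {max_iter} iterations "
        f"(last luminance {trace[-1][1]}, target {target})",
        trace,
    )


def build_lut(
    luminance_oracle: Callable[[float, float], float],
    target: float,
    angle_grid: Sequence[float],
    tolerance: float = 0.005,
    led_id: str = "led",
    max_iter: int = 100,
) -> CalibrationLUT:
    """Equalise one LED at every angle of ``angle_grid`` into a LUT."""
    angles = np.asarray(angle_grid, dtype=float)
    currents = np.empty_like(angles)
    achieved = np.empty_like(angles)
    for i, th in enumerate(angles):
        c = equalise_led(
            luminance_oracle, target, th, tolerance=tolerance, max_iter=max_iter
        )
        currents[i] = c
        achieved[i] = float(luminance_oracle(c, th))
    return CalibrationLUT(
        led_id=led_id,
        angles=angles,
        currents=currents,
        achieved_luminance=achieved,
        target=target,
        tolerance=tolerance,
    )
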