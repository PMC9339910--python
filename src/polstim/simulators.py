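"""Ground-truth simulators for end-to-end validation.

Three generators stand in for the hardware and the animals:

* a photodiode reading a simulated dual-projector light path whose
  luminance varies sinusoidally with polariser angle (calibration
  test-bed);
* a polarisation-sensitive photoreceptor with a photon-capture model,
  a Gaussian spatial receptive field, a Naka-Rushton voltage
  nonlinearity and additive Gaussian noise (receptive-field mapping
  test-bed);
* a direction-tuned spiking neuron with contrast-squared gain, response
  latency and inhomogeneous Poisson spiking via thinning (LPD/LMS
  test-bed).  The neuron is polarisation-blind by default; an optional
  polarisation-sensitive variant scales its gain by relative photon
  capture.

All stochastic outputs are reproducible from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from polstim.calibration import LedLuminanceModel
from polstim.frame_codec import (
    DotTrajectory,
    GridSchedule,
    PolPixelCommand,
    grid_cell_centres,
)
from polstim.lms_lpd import SpikeTrain
from polstim.rf_photoreceptor import IntracellularTrace

__all__ = [
    "PhotoreceptorModel",
    "H1Model",
    "SimulatedDevice",
    "photon_capture",
    "simulate_photoreceptor_trace",
    "simulate_h1_spikes",
    "simulated_photodiode",
]


@dataclass
class PhotoreceptorModel:
    """Polarisation-sensitive photoreceptor with a Gaussian spatial RF.

    ``phi_max`` is the preferred e-vector angle (90 deg for the
    blue-class dorsoventral preference, 0 deg for the green-class
    equatorial preference) and ``ps`` the polarisation sensitivity
    ratio.  ``half_capture`` sets the Naka-Rushton half-saturation; keep
    it well above typical captures to operate in the near-linear regime
    where response ratios approximate capture ratios.
    """

    phi_max: float = 90.0  # deg
    ps: float = 2.0
    rf_centre: tuple[float, float] = (0.0, 0.0)  # (az, el) deg
    rf_sd: float = 1.0  # deg
    v_max: float = 40.0  # mV
    half_capture: float = 10.0
    noise_sd: float = 0.1  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ps < 1:
            raise ValueError("ps must be >= 1")
        if self.rf_sd <= 0:
            raise ValueError("rf_sd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class H1Model:
    """Direction-tuned spiking neuron (cosine tuning, contrast^2 gain).

    Firing rate before rectification is
    ``baseline + gain * contrast**2 * cos(theta(t - latency) - theta_pref)``
    scaled by a Gaussian spatial envelope; the contrast exponent is
    fixed at 2 (correlator-model prediction).  Spikes are drawn from an
    inhomogeneous Poisson process by thinning.
    """

    theta_pref: float = 0.0  # deg; horizontal back-to-front by convention
    baseline_rate: float = 20.0  # spikes/s
    gain: float = 80.0  # spikes/s per unit drive
    latency: float = 0.0  # s
    envelope_centre: tuple[float, float] = (0.0, 0.0)  # (az, el) deg
    envelope_sd: float = 40.0  # deg
    polarisation_sensitive: bool = False
    phi_max: float = 0.0  # deg, only used if polarisation_sensitive
    ps: float = 2.0
    seed: int = 0

    contrast_exponent: int = field(default=2, init=False)

    def envelope(self, location: tuple[float, float]) -> float:
        az, el = location
        d2 = (az - self.envelope_centre[0]) ** 2 + (el - self.envelope_centre[1]) ** 2
        return float(np.exp(-d2 / (2.0 * self.envelope_sd**2)))


@dataclass
class SimulatedDevice:
    """Bank of LEDs with intrinsic polarisation, read by a photodiode."""

    leds: Mapping[str, LedLuminanceModel]

    def __post_init__(self) -> None:
        self.leds = dict(self.leds)


def photon_capture(
    intensity: float, dolp: float, aop_deg: float, model: PhotoreceptorModel
):
    """Photon capture of a polarisation-sensitive rhabdom.

    ``C = I * [(1 - d) * (1 + 1/ps) / 2
              + d * (cos^2(a - phi_max) + sin^2(a - phi_max) / ps)]``

    Fully aligned polarised light captures I, orthogonal light I/ps, and
    non-polarised light the average of the two extremes — intermediate
    for ps > 1.
    """
    dolp = np.asarray(dolp, dtype=float)
    if np.any(dolp < 0) or np.any(dolp > 1):
        raise ValueError("dolp outside [0, 1]")
    delta = np.deg2rad(np.asarray(aop_deg, dtype=float) - model.phi_max)
    pol_term = np.cos(delta) ** 2 + np.sin(delta) ** 2 / model.ps
    unpol_term = (1.0 + 1.0 / model.ps) / 2.0
    return np.asarray(intensity, dtype=float) * (
        (1.0 - dolp) * unpol_term + dolp * pol_term
    )


def _effective_capture(
    obj: PolPixelCommand,
    bg: PolPixelCommand,
    aop_obj: float | None,
    aop_bg: float | None,
    model: PhotoreceptorModel,
) -> float:
    """Object-minus-background capture, rectified at zero.

    A polarised object on a luminance-matched non-polarised background
    yields zero for ps = 1 (the "masked" control) but a positive capture
    contrast for ps > 1.
    """
    c_obj = float(photon_capture(obj.intensity, obj.dolp, aop_obj or 0.0, model))
    c_bg = float(photon_capture(bg.intensity, bg.dolp, aop_bg or 0.0, model))
    return max(0.0, c_obj - c_bg)


def simulate_photoreceptor_trace(
    schedule: GridSchedule,
    object_cmd: PolPixelCommand,
    background_cmd: PolPixelCommand,
    model: PhotoreceptorModel,
    aop_deg: float | None = None,
    sample_rate: float = 30_000.0,
    rng: np.random.Generator | None = None,
) -> IntracellularTrace:
    """Synthesise the intracellular voltage trace for a grid protocol.

    During each presentation the membrane depolarises by
    ``v_max * C_eff / (C_eff + half_capture)`` scaled by the Gaussian
    spatial receptive field at the square's location; Gaussian noise of
    ``model.noise_sd`` mV is added throughout.  The trace starts one gap
    before the first onset so every presentation has a baseline window.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    t0 = schedule.entries[0][2] - schedule.gap_duration
    n = int(round((schedule.span + schedule.gap_duration) * sample_rate))
    v = np.zeros(n)
    az, el = grid_cell_centres(schedule)
    c_eff = _effective_capture(
        object_cmd, background_cmd, aop_deg, aop_deg, model
    )
    amplitude = model.v_max * c_eff / (c_eff + model.half_capture)
    two_sd2 = 2.0 * model.rf_sd**2
    for row, col, onset, offset in schedule.entries:
        d2 = (az[row, col] - model.rf_centre[0]) ** 2 + (
            el[row, col] - model.rf_centre[1]
        ) ** 2
        level = amplitude * np.exp(-d2 / two_sd2)
        i0 = int(round((onset - t0) * sample_rate))
        i1 = int(round((offset - t0) * sample_rate))
        v[i0:i1] = level
    if model.noise_sd > 0:
        v = v + rng.normal(0.0, model.noise_sd, size=n)
    return IntracellularTrace(samples=v, sample_rate=sample_rate, t0=t0)


def _h1_rate(
    t: np.ndarray,
    traj: DotTrajectory,
    location: tuple[float, float],
    contrast: float,
    model: H1Model,
    dolp: float,
    aop_deg: float | None,
) -> np.ndarray:
    theta = traj.theta_at(np.asarray(t, dtype=float) - model.latency)
    drive = np.cos(np.deg2rad(theta - model.theta_pref))
    gain = model.gain * abs(contrast) ** model.contrast_exponent
    if model.polarisation_sensitive:
        probe = PhotoreceptorModel(phi_max=model.phi_max, ps=model.ps, noise_sd=0.0)
        gain = gain * float(photon_capture(1.0, dolp, aop_deg or 0.0, probe))
    rate = model.baseline_rate + gain * drive
    return np.maximum(0.0, rate) * model.envelope(location)


def simulate_h1_spikes(
    traj: DotTrajectory,
    location: tuple[float, float],
    contrast: float,
    model: H1Model,
    dolp: float = 0.0,
    aop_deg: float | None = None,
    rng: np.random.Generator | None = None,
) -> SpikeTrain:
    """Draw spikes for one circular-dot trial by Poisson thinning.

    Candidate events come from a homogeneous Poisson process at the
    rate-function ceiling; each is kept with probability
    ``rate(t) / ceiling``, yielding an exact inhomogeneous Poisson
    sample of the direction-tuned rate.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    duration = traj.duration
    env = model.envelope(location)
    ceiling = (
        model.baseline_rate
        + model.gain * abs(contrast) ** model.contrast_exponent * (2.0 if model.polarisation_sensitive else 1.0)
    ) * max(env, 1e-12)
    n_cand = rng.poisson(ceiling * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    accept_p = _h1_rate(t_cand, traj, location, contrast, model, dolp, aop_deg) / ceiling
    keep = rng.uniform(size=n_cand) < accept_p
    times = t_cand[keep]
    # enforce strict monotonicity against duplicate uniform draws
    times = np.unique(times)
    return SpikeTrain(
        spike_times=times,
        unit_id="sim_h1",
        direction=traj.direction,
        condition=f"contrast={contrast}",
        location=location,
    )


def simulated_photodiode(
    device: SimulatedDevice, led_id: str, current: float, polariser_angle_deg: float
) -> float:
    """Deterministic photodiode reading of one LED through the polariser."""
    if current < 0:
        raise ValueError("current must be non-negative")
    model = device.leds[led_id]
    return float(model.luminance(polariser_angle_deg, current=current))
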