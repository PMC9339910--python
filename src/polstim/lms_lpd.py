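"""Local preferred direction (LPD) and local motion sensitivity (LMS).

A small dot revolving on a circular path sweeps through every motion
direction once per cycle; the circular mean of the motion directions at
spike times estimates the local preferred direction.  Because the
neuronal response lags the stimulus, clockwise and counter-clockwise
single-direction estimates are phase-shifted in opposite directions, so
the latency-corrected LPD is the resultant of the two unit vectors.
LMS is the mean, over the two rotation directions, of the spike-rate
difference between the +/-45 deg sector around the LPD and the sector
around the anti-LPD:

    LMS = ((a_CW - b_CW) + (a_CCW - b_CCW)) / 2

Vector-field receptive fields collect (LPD, LMS) over a grid of visual-
field locations and are interpolated componentwise with bicubic splines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from polstim.frame_codec import DotTrajectory

__all__ = [
    "SpikeTrain",
    "LocalMotionEstimate",
    "VectorField",
    "spike_motion_directions",
    "circular_mean",
    "latency_corrected_lpd",
    "sector_rate",
    "lms",
    "estimate_local_motion",
    "contrast_tuning",
    "polarisation_tuning",
    "interpolate_vector_field",
    "normalise_field",
]


@dataclass
class SpikeTrain:
    """Sorted spike times with trial metadata."""

    spike_times: np.ndarray  # s, strictly increasing
    unit_id: str = ""
    direction: str = ""  # "CW" | "CCW"
    condition: str = ""
    location: tuple[float, float] = (0.0, 0.0)  # (azimuth, elevation) deg

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if len(self.spike_times) > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass
class LocalMotionEstimate:
    """LPD/LMS summary for one visual-field location."""

    lpd: float  # deg, latency-corrected
    lpd_cw: float  # deg
    lpd_ccw: float  # deg
    lms: float  # spikes/s
    resultant_length: float
    a_cw: float
    a_ccw: float
    b_cw: float
    b_ccw: float
    location: tuple[float, float] = (0.0, 0.0)


@dataclass
class VectorField:
    """(LPD, LMS) sampled on an azimuth x elevation grid.

    Azimuth positive = right visual field; elevation positive = dorsal.
    ``lpd`` and ``lms`` are (n_elevation, n_azimuth) arrays.
    """

    azimuths: np.ndarray  # deg, ascending
    elevations: np.ndarray  # deg, ascending
    lpd: np.ndarray  # deg
    lms: np.ndarray  # spikes/s (or normalised)
    condition: str = ""

    def __post_init__(self) -> None:
        self.azimuths = np.asarray(self.azimuths, dtype=float)
        self.elevations = np.asarray(self.elevations, dtype=float)
        self.lpd = np.asarray(self.lpd, dtype=float)
        self.lms = np.asarray(self.lms, dtype=float)
        expected = (len(self.elevations), len(self.azimuths))
        if self.lpd.shape != expected or self.lms.shape != expected:
            raise ValueError(
                f"lpd/lms shape must be {expected} (elevation x azimuth)"
            )

    def to_frame(self) -> pd.DataFrame:
        az, el = np.meshgrid(self.azimuths, self.elevations)
        return pd.DataFrame(
            {
                "azimuth_deg": az.ravel(),
                "elevation_deg": el.ravel(),
                "lpd_deg": self.lpd.ravel(),
                "lms": self.lms.ravel(),
            }
        )


def spike_motion_directions(
    train: SpikeTrain, traj: DotTrajectory
) -> tuple[np.ndarray, int]:
    """Instantaneous motion direction (deg) at each spike time.

    Spikes outside the trajectory span are dropped; the count of
    dropped spikes is returned alongside.
    """
    t = train.spike_times
    inside = (t >= 0.0) & (t <= traj.duration)
    dropped = int(np.sum(~inside))
    return traj.theta_at(t[inside]), dropped


def circular_mean(angles_deg) -> tuple[float, float]:
    """Circular mean direction and resultant length of angles in degrees.

    Returns ``(mean_deg in [0, 360), R in [0, 1])``.  The mean is the
    direction of the summed unit vectors; for a perfectly balanced
    (antipodal) set R = 0 and the mean is undefined (NaN).
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle set")
    rad = np.deg2rad(angles)
    z = np.mean(np.cos(rad)) + 1j * np.mean(np.sin(rad))
    r = float(np.abs(z))
    if r < 1e-12:
        return float("nan"), 0.0
    return float(np.rad2deg(np.angle(z)) % 360.0), r


def latency_corrected_lpd(lpd_cw: float, lpd_ccw: float) -> float:
    """Direction of the resultant of the CW and CCW unit vectors.

    The response latency rotates the CW and CCW single-direction
    estimates by equal and opposite phase angles, so their resultant
    cancels the lag.  Antipodal inputs leave the resultant undefined.
    """
    v = np.exp(1j * np.deg2rad(lpd_cw)) + np.exp(1j * np.deg2rad(lpd_ccw))
    if np.abs(v) < 1e-9:
        raise ValueError(
            f"antipodal estimates ({lpd_cw}, {lpd_ccw}): corrected LPD undefined"
        )
    return float(np.rad2deg(np.angle(v)) % 360.0)


def _ang_dist(a, b):
    """Absolute angular distance in degrees, in [0, 180]."""
    d = np.mod(np.asarray(a) - b, 360.0)
    return np.minimum(d, 360.0 - d)


def sector_rate(
    train: SpikeTrain,
    traj: DotTrajectory,
    centre_deg: float,
    halfwidth_deg: float = 45.0,
) -> float:
    """Spike rate while the motion direction is within a sector.

    Rate = spikes whose motion direction falls within ``halfwidth_deg``
    of ``centre_deg``, divided by the total time the trajectory's motion
    direction spends in that sector (dwell-time normalisation, robust to
    partial cycles).
    """
    theta_spk, _ = spike_motion_directions(train, traj)
    in_sector_spk = _ang_dist(theta_spk, centre_deg) <= halfwidth_deg

    dt = np.diff(traj.times, prepend=traj.times[0] - (traj.times[1] - traj.times[0]))
    theta_t = traj.theta_at(traj.times)
    dwell = float(np.sum(dt[_ang_dist(theta_t, centre_deg) <= halfwidth_deg]))
    if dwell <= 0:
        raise ValueError(
            f"trajectory never enters the sector around {centre_deg} deg"
        )
    return float(np.sum(in_sector_spk)) / dwell


def lms(a_cw: float, a_ccw: float, b_cw: float, b_ccw: float) -> float:
    """Mean over rotation directions of (preferred - anti-preferred) rate."""
    for r in (a_cw, a_ccw, b_cw, b_ccw):
        if r < 0:
            raise ValueError("sector rates must be non-negative")
    return ((a_cw - b_cw) + (a_ccw - b_ccw)) / 2.0


def estimate_local_motion(
    train_cw: SpikeTrain,
    train_ccw: SpikeTrain,
    traj_cw: DotTrajectory,
    traj_ccw: DotTrajectory,
    halfwidth_deg: float = 45.0,
    location: tuple[float, float] | None = None,
) -> LocalMotionEstimate:
    """Full local-motion estimate from a CW + CCW trial pair.

    Single-direction LPDs are circular means of spike-triggered motion
    directions; the corrected LPD is their resultant; the a/b sectors
    (+/-45 deg around LPD and anti-LPD) feed the LMS rate difference.
    """
    th_cw, _ = spike_motion_directions(train_cw, traj_cw)
    th_ccw, _ = spike_motion_directions(train_ccw, traj_ccw)
    lpd_cw, r_cw = circular_mean(th_cw)
    lpd_ccw, r_ccw = circular_mean(th_ccw)
    lpd = latency_corrected_lpd(lpd_cw, lpd_ccw)

    anti = (lpd + 180.0) % 360.0
    a_cw = sector_rate(train_cw, traj_cw, lpd, halfwidth_deg)
    a_ccw = sector_rate(train_ccw, traj_ccw, lpd, halfwidth_deg)
    b_cw = sector_rate(train_cw, traj_cw, anti, halfwidth_deg)
    b_ccw = sector_rate(train_ccw, traj_ccw, anti, halfwidth_deg)

    return LocalMotionEstimate(
        lpd=lpd,
        lpd_cw=lpd_cw,
        lpd_ccw=lpd_ccw,
        lms=lms(a_cw, a_ccw, b_cw, b_ccw),
        resultant_length=float((r_cw + r_ccw) / 2.0),
        a_cw=a_cw,
        a_ccw=a_ccw,
        b_cw=b_cw,
        b_ccw=b_ccw,
        location=location or train_cw.location,
    )


def _grouped_curve(records, level_key: str) -> pd.DataFrame:
    df = pd.DataFrame(records)
    # trials within each animal first, then across animals
    per_animal = df.groupby([level_key, "animal"], sort=True)["lms"].mean()
    out = per_animal.groupby(level=0).agg(["mean", "std", "count"])
    out = out.rename(columns={"mean": "lms_mean", "std": "lms_sd", "count": "n_animals"})
    return out.reset_index()


def contrast_tuning(records: Sequence[Mapping]) -> pd.DataFrame:
    """LMS vs contrast, averaged within animals before across animals.

    ``records`` are dicts with keys ``animal``, ``contrast``, ``lms``
    (one per trial).  Returns columns contrast, lms_mean, lms_sd,
    n_animals, ordered by contrast.
    """
    if not records:
        raise ValueError("no records")
    if len({r["contrast"] for r in records}) < 2:
        raise ValueError("need at least 2 contrast levels")
    return _grouped_curve(records, "contrast")


def polarisation_tuning(records: Sequence[Mapping]) -> pd.DataFrame:
    """LMS vs AoP for each contrast level, same aggregation rule.

    ``records`` carry ``animal``, ``contrast``, ``aop`` (deg, or None
    for the non-polarised condition) and ``lms``.  Rotations of the
    polariser are pooled: trials sharing an AoP label are averaged
    together within each animal.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(records)
    df["aop"] = df["aop"].map(lambda a: "NP" if a is None else float(a) % 360.0)
    per_animal = df.groupby(["contrast", "aop", "animal"], sort=True)["lms"].mean()
    out = per_animal.groupby(level=[0, 1]).agg(["mean", "std", "count"])
    out = out.rename(
        columns={"mean": "lms_mean", "std": "lms_sd", "count": "n_animals"}
    )
    return out.reset_index()


def interpolate_vector_field(
    fld: VectorField, step_deg: float = 15.0
) -> VectorField:
    """Refine a vector field to ``step_deg`` spacing, componentwise.

    The polar (LPD, LMS) pairs are converted to Cartesian components
    ``lms * (cos lpd, sin lpd)``, each component is interpolated with a
    bicubic spline over the sample grid, and the result is re-expressed
    in polar form.  Sampled nodes are reproduced exactly (interpolating
    spline); needs at least a 4x4 grid.
    """
    if len(fld.azimuths) < 4 or len(fld.elevations) < 4:
        raise ValueError("need at least a 4x4 sample grid for bicubic splines")
    rad = np.deg2rad(fld.lpd)
    u = fld.lms * np.cos(rad)
    v = fld.lms * np.sin(rad)
    su = RectBivariateSpline(fld.elevations, fld.azimuths, u, kx=3, ky=3)
    sv = RectBivariateSpline(fld.elevations, fld.azimuths, v, kx=3, ky=3)

    az_f = _refined_axis(fld.azimuths, step_deg)
    el_f = _refined_axis(fld.elevations, step_deg)
    uf = su(el_f, az_f)
    vf = sv(el_f, az_f)
    return VectorField(
        azimuths=az_f,
        elevations=el_f,
        lpd=np.rad2deg(np.arctan2(vf, uf)) % 360.0,
        lms=np.hypot(uf, vf),
        condition=fld.condition,
    )


def _refined_axis(axis: np.ndarray, step: float) -> np.ndarray:
    lo, hi = float(axis[0]), float(axis[-1])
    n = int(round((hi - lo) / step))
    fine = lo + step * np.arange(n + 1)
    # keep the original nodes so spline interpolation is verifiable
    return np.unique(np.concatenate([fine, axis]))


def normalise_field(
    fields: Mapping[str, VectorField], reference: str
) -> dict[str, VectorField]:
    """Scale all fields by the reference condition's maximum LMS."""
    if reference not in fields:
        raise ValueError(f"reference condition {reference!r} missing")
    ref_max = float(np.max(fields[reference].lms))
    if ref_max <= 0:
        raise ValueError("reference maximum LMS must be positive")
    return {
        k: VectorField(
            azimuths=f.azimuths,
            elevations=f.elevations,
            lpd=f.lpd,
            lms=f.lms / ref_max,
            condition=f.condition,
        )
        for k, f in fields.items()
    }
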