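"""Photoreceptor receptive-field mapping from intracellular recordings.

An intracellular voltage trace recorded during a grid-square protocol is
reduced to one depolarisation per grid location (mean voltage during the
presentation minus the baseline immediately before it), giving a 2-D
receptive-field map per stimulus condition.  Maps are spline-interpolated
and Gaussian-smoothed for display, normalised to the per-cell maximum
across trials, aligned on the non-polarised-condition centroid, and
summarised as polarisation tuning curves whose max/min ratio is the
polarisation sensitivity (PS) ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

from polstim.frame_codec import GridSchedule

__all__ = [
    "IntracellularTrace",
    "RFMap",
    "PolTuningCurve",
    "location_response",
    "build_rf_map",
    "gaussian_smooth",
    "interpolate_smooth",
    "normalise_maps",
    "rf_centroid",
    "align_and_average",
    "polarisation_tuning",
    "ps_ratio",
]


@dataclass
class IntracellularTrace:
    """Uniformly sampled membrane-voltage series (mV)."""

    samples: np.ndarray
    sample_rate: float = 30_000.0  # Hz
    t0: float = 0.0  # s, time of the first sample

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def t_end(self) -> float:
        return self.t0 + len(self.samples) / self.sample_rate

    def window_mean(self, start: float, stop: float) -> float:
        """Mean voltage over [start, stop) seconds."""
        if stop <= start:
            raise ValueError(f"empty window ({start}, {stop})")
        if start < self.t0 - 1e-12 or stop > self.t_end + 1e-12:
            raise ValueError(
                f"window ({start}, {stop}) outside trace span "
                f"({self.t0}, {self.t_end})"
            )
        i0 = int(round((start - self.t0) * self.sample_rate))
        i1 = int(round((stop - self.t0) * self.sample_rate))
        i1 = min(i1, len(self.samples))
        if i1 <= i0:
            raise ValueError("window contains no samples")
        return float(self.samples[i0:i1].mean())


@dataclass
class RFMap:
    """Per-grid-location response map for one condition of one cell."""

    responses: np.ndarray  # (rows, cols), mV or normalised
    square_size: float = 0.5  # deg
    condition: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be 2-D")


@dataclass
class PolTuningCurve:
    """Per-AoP peak responses plus the non-polarised reference."""

    aop_deg: np.ndarray = field(default_factory=lambda: np.array([]))
    peak_responses: np.ndarray = field(default_factory=lambda: np.array([]))
    nonpolarised_response: float | None = None


def location_response(
    trace: IntracellularTrace,
    window: tuple[float, float],
    baseline_window: tuple[float, float],
) -> float:
    """Mean depolarisation during the presentation relative to baseline."""
    return trace.window_mean(*window) - trace.window_mean(*baseline_window)


def build_rf_map(
    trace: IntracellularTrace,
    schedule: GridSchedule,
    condition: str = "",
    cell_id: str = "",
) -> RFMap:
    """One response per grid cell, in (row, col) position.

    Baseline for each presentation is the inter-stimulus gap immediately
    preceding its onset, so the trace must start at least one gap before
    the first onset (the simulators emit traces with ``t0 = -gap``).
    """
    first_onset = schedule.entries[0][2]
    if trace.t0 > first_onset - schedule.gap_duration + 1e-12:
        raise ValueError(
            "trace must begin >= one gap_duration before the first onset "
            "to provide a baseline window"
        )
    last_offset = schedule.entries[-1][3]
    if trace.t_end < last_offset - 1e-12:
        raise ValueError("trace ends before the schedule does")

    responses = np.full(schedule.grid_shape, np.nan)
    for row, col, onset, offset in schedule.entries:
        responses[row, col] = location_response(
            trace,
            (onset, offset),
            (onset - schedule.gap_duration, onset),
        )
    return RFMap(
        responses=responses,
        square_size=schedule.square_size,
        condition=condition,
        cell_id=cell_id,
    )


def gaussian_smooth(responses: np.ndarray, sd: float) -> np.ndarray:
    """2-D Gaussian smoothing with reflective boundaries."""
    return ndimage.gaussian_filter(
        np.asarray(responses, dtype=float), sigma=sd, mode="nearest"
    )


def interpolate_smooth(
    rf: RFMap, upsample: int = 10, kernel_sd: float = 1.0
) -> RFMap:
    """Bicubic-spline upsampling followed by Gaussian smoothing.

    ``kernel_sd`` is expressed in pre-interpolation grid cells and
    rescaled to the upsampled grid.  Display refinement only: centroids
    and tuning curves are computed on the raw grid.
    """
    z = np.asarray(rf.responses, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("map contains non-finite responses")
    rows, cols = z.shape
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    spline = RectBivariateSpline(
        np.arange(rows), np.arange(cols), z,
        kx=min(3, rows - 1), ky=min(3, cols - 1),
    )
    fine_r = np.linspace(0, rows - 1, (rows - 1) * upsample + 1)
    fine_c = np.linspace(0, cols - 1, (cols - 1) * upsample + 1)
    fine = spline(fine_r, fine_c)
    fine = gaussian_smooth(fine, kernel_sd * upsample)
    return RFMap(
        responses=fine,
        square_size=rf.square_size / upsample,
        condition=rf.condition,
        cell_id=rf.cell_id,
    )


def normalise_maps(maps: Sequence[RFMap]) -> list[RFMap]:
    """Divide every map of a cell by the single maximum across trials.

    All maps share one denominator so the relative ordering of
    conditions is preserved and the largest peak becomes exactly 1.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to normalise")
    peak = max(float(np.nanmax(m.responses)) for m in maps)
    if peak <= 0:
        raise ValueError(
            f"cannot normalise: maximum response {peak} is not positive"
        )
    return [
        RFMap(
            responses=m.responses / peak,
            square_size=m.square_size,
            condition=m.condition,
            cell_id=m.cell_id,
        )
        for m in maps
    ]


def rf_centroid(
    rf: RFMap, threshold: float = 0.30, weighted: bool = False
) -> tuple[float, float]:
    """Centre of mass of the thresholded receptive field, in degrees.

    The map is binarised at ``threshold`` x its maximum and the
    unweighted centroid of the super-threshold support is returned as
    (azimuth, elevation) relative to the grid centre (column -> azimuth
    rightward, row -> elevation with the top row dorsal-most).  Set
    ``weighted=True`` for a response-weighted centre of mass instead.
    """
    z = np.asarray(rf.responses, dtype=float)
    if not np.any(np.isfinite(z)):
        raise ValueError("no pixels above threshold (map is all-NaN)")
    peak = np.nanmax(z)
    mask = z >= threshold * peak
    if not mask.any():
        raise ValueError("no pixels above threshold")
    rows, cols = np.nonzero(mask)
    if weighted:
        w = z[rows, cols]
        r_c = np.average(rows, weights=w)
        c_c = np.average(cols, weights=w)
    else:
        r_c = rows.mean()
        c_c = cols.mean()
    n_rows, n_cols = z.shape
    az = (c_c - (n_cols - 1) / 2.0) * rf.square_size
    el = ((n_rows - 1) / 2.0 - r_c) * rf.square_size
    return float(az), float(el)


def align_and_average(
    maps_by_cell: Mapping[str, Sequence[RFMap]],
    centroids_by_cell: Mapping[str, tuple[float, float]],
) -> np.ndarray:
    """Offset every cell's maps by its reference centroid, then average.

    ``centroids_by_cell`` holds each cell's non-polarised-condition
    centroid in degrees; each map is translated by minus that offset
    (linear interpolation, zero fill) before the cross-cell mean.
    """
    shifted = []
    for cell_id, maps in maps_by_cell.items():
        if cell_id not in centroids_by_cell:
            raise ValueError(
                f"cell {cell_id!r} has no non-polarised reference centroid"
            )
        az, el = centroids_by_cell[cell_id]
        for m in maps:
            # degrees -> (row, col) pixel shift; +el moves content up
            dr = el / m.square_size
            dc = -az / m.square_size
            shifted.append(
                ndimage.shift(m.responses, (dr, dc), order=1, mode="constant", cval=0.0)
            )
    if not shifted:
        raise ValueError("nothing to average")
    return np.mean(shifted, axis=0)


def polarisation_tuning(maps: Sequence[RFMap]) -> PolTuningCurve:
    """Per-condition map maxima as a function of AoP.

    Polarised conditions must be labelled ``"pol<angle>"`` (e.g.
    ``pol45``); the condition labelled ``"NP"`` (case-insensitive)
    becomes the non-polarised reference.
    """
    aops, peaks, np_ref = [], [], None
    for m in maps:
        peak = float(np.nanmax(m.responses))
        label = m.condition.strip()
        if label.upper() in ("NP", "NONPOL", "NON-POLARISED"):
            np_ref = peak
        elif label.lower().startswith("pol"):
            aops.append(float(label[3:]) % 180.0)
            peaks.append(peak)
        else:
            raise ValueError(f"unrecognised condition label {label!r}")
    order = np.argsort(aops)
    return PolTuningCurve(
        aop_deg=np.asarray(aops)[order],
        peak_responses=np.asarray(peaks)[order],
        nonpolarised_response=np_ref,
    )


def ps_ratio(curve: PolTuningCurve) -> float:
    """Polarisation sensitivity: max over min of the tuning curve."""
    if len(curve.peak_responses) < 2:
        raise ValueError("need at least 2 AoP conditions")
    lo = float(np.min(curve.peak_responses))
    if lo <= 0:
        raise ValueError("tuning-curve minimum must be positive")
    return float(np.max(curve.peak_responses)) / lo
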