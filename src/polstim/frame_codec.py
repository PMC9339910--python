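"""Stimulus frame encoding for a dual-DLP polarisation display.

The display shows two superimposed projector images: a polarised channel
(DLP1, behind a linear polariser) and a non-polarised channel (DLP2).
Each projector parses its 24-bit video frames as six consecutive 4-bit
greyscale subframes per pixel, raising the pattern update rate from the
60 Hz video rate to 360 Hz.  Per-pixel intensity and degree of linear
polarisation (DoLP) are controlled jointly by splitting a total greyscale
budget between the two channels such that the two values always sum to
the commanded total (15 at full luminance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DisplaySpec",
    "PolPixelCommand",
    "FramePair",
    "DotTrajectory",
    "GridSchedule",
    "encode_pixel",
    "encode_frame",
    "pack_video_frames",
    "unpack_video_frames",
    "pattern_rate",
    "stimulus_contrast",
    "make_dot_trajectory",
    "make_grid_schedule",
    "grid_cell_centres",
    "render_frames",
]


@dataclass(frozen=True)
class DisplaySpec:
    """Geometry and timing of the dual-projector video pipeline."""

    video_rate: float = 60.0  # Hz
    bits_per_video_frame: int = 24
    channel_order: str = "BRG"
    bit_depth: int = 4
    width: int = 608
    height: int = 684
    degrees_per_pixel: float = 0.1

    def __post_init__(self) -> None:
        if self.bits_per_video_frame % self.bit_depth != 0:
            raise ValueError(
                f"bits_per_video_frame ({self.bits_per_video_frame}) must be "
                f"divisible by bit_depth ({self.bit_depth})"
            )
        if self.video_rate <= 0:
            raise ValueError("video_rate must be positive")

    @property
    def subframes_per_frame(self) -> int:
        return self.bits_per_video_frame // self.bit_depth

    @property
    def max_grey(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class PolPixelCommand:
    """Desired luminance fraction and degree of linear polarisation."""

    intensity: float
    dolp: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.intensity <= 1.0):
            raise ValueError(f"intensity {self.intensity} outside [0, 1]")
        if not (0.0 <= self.dolp <= 1.0):
            raise ValueError(f"dolp {self.dolp} outside [0, 1]")


@dataclass
class FramePair:
    """Greyscale images for the polarised (DLP1) and non-polarised (DLP2)
    channels; per pixel, ``g_pol + g_nonpol <= max_grey``."""

    g_pol: np.ndarray
    g_nonpol: np.ndarray

    def __post_init__(self) -> None:
        self.g_pol = np.asarray(self.g_pol)
        self.g_nonpol = np.asarray(self.g_nonpol)
        if self.g_pol.shape != self.g_nonpol.shape:
            raise ValueError("channel shapes differ")


def _round_half_away(x):
    """Round half away from zero (NumPy's ``round`` rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def encode_pixel(cmd: PolPixelCommand, spec: DisplaySpec = DisplaySpec()) -> tuple[int, int]:
    """Split one pixel command into (g_pol, g_nonpol) greyscale values.

    The total greyscale is rounded first, then the polarised share, and
    the non-polarised channel takes the remainder, so the sum constraint
    is exact: at intensity 1 the two values always sum to ``max_grey``.
    The achieved DoLP is ``g_pol / (g_pol + g_nonpol)``.
    """
    total = int(_round_half_away(cmd.intensity * spec.max_grey))
    g_pol = int(_round_half_away(cmd.dolp * total))
    return g_pol, total - g_pol


def encode_frame(
    intensity: np.ndarray, dolp: np.ndarray, spec: DisplaySpec = DisplaySpec()
) -> FramePair:
    """Vectorised :func:`encode_pixel` over intensity and DoLP images."""
    intensity = np.asarray(intensity, dtype=float)
    dolp = np.asarray(dolp, dtype=float)
    if intensity.shape != dolp.shape:
        raise ValueError(
            f"intensity shape {intensity.shape} != dolp shape {dolp.shape}"
        )
    if intensity.size and (intensity.min() < 0 or intensity.max() > 1):
        raise ValueError("intensity values outside [0, 1]")
    if dolp.size and (dolp.min() < 0 or dolp.max() > 1):
        raise ValueError("dolp values outside [0, 1]")
    total = _round_half_away(intensity * spec.max_grey)
    g_pol = _round_half_away(dolp * total)
    return FramePair(
        g_pol.astype(np.uint8), (total - g_pol).astype(np.uint8)
    )


def pack_video_frames(
    subframes: np.ndarray | list, spec: DisplaySpec = DisplaySpec()
) -> np.ndarray:
    """Pack greyscale subframes into 24-bit video frames.

    Parameters
    ----------
    subframes
        Sequence of ``(H, W)`` images with values in ``0..max_grey``;
        length must be a multiple of ``spec.subframes_per_frame``.

    Returns
    -------
    ndarray, shape (n_frames, H, W, 3), dtype uint8
        Video frames in display R, G, B channel order.  Subframe ``i``
        of each group occupies bits ``[bit_depth*i, bit_depth*(i+1))``
        of the 24-bit word read in B, R, G byte order, least-significant
        bit first (so subframe 0 lands in the low nibble of blue).
    """
    sub = np.asarray(subframes)
    if sub.ndim != 3:
        raise ValueError("expected a (n, H, W) stack of subframes")
    n = sub.shape[0]
    k = spec.subframes_per_frame
    if n % k != 0:
        raise ValueError(f"number of subframes ({n}) not a multiple of {k}")
    if sub.size and (sub.min() < 0 or sub.max() > spec.max_grey):
        raise ValueError(f"greyscale values outside 0..{spec.max_grey}")

    words = np.zeros((n // k,) + sub.shape[1:], dtype=np.uint32)
    grouped = sub.reshape(n // k, k, *sub.shape[1:]).astype(np.uint32)
    for i in range(k):
        words |= grouped[:, i] << (spec.bit_depth * i)

    # byte order on the wire is B, R, G: blue = bits 0-7, red = 8-15,
    # green = 16-23; returned in conventional R, G, B channel layout
    b = (words & 0xFF).astype(np.uint8)
    r = ((words >> 8) & 0xFF).astype(np.uint8)
    g = ((words >> 16) & 0xFF).astype(np.uint8)
    return np.stack([r, g, b], axis=-1)


def unpack_video_frames(
    frames: np.ndarray, spec: DisplaySpec = DisplaySpec()
) -> np.ndarray:
    """Inverse of :func:`pack_video_frames`; returns the subframe stack."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("expected (n_frames, H, W, 3) packed frames")
    r = frames[..., 0].astype(np.uint32)
    g = frames[..., 1].astype(np.uint32)
    b = frames[..., 2].astype(np.uint32)
    words = b | (r << 8) | (g << 16)

    k = spec.subframes_per_frame
    mask = np.uint32(spec.max_grey)
    subs = [
        ((words >> (spec.bit_depth * i)) & mask).astype(np.uint8)
        for i in range(k)
    ]
    stacked = np.stack(subs, axis=1)
    return stacked.reshape((-1,) + frames.shape[1:3])


def pattern_rate(spec: DisplaySpec = DisplaySpec()) -> float:
    """Pattern update rate in Hz: video_rate x subframes per video frame."""
    return spec.video_rate * spec.bits_per_video_frame / spec.bit_depth


def stimulus_contrast(object_intensity: float, background_intensity: float) -> float:
    """Signed object-minus-background contrast on the [-1, +1] scale.

    Defined as the difference of normalised intensities, the only
    definition consistent with the printed endpoint conditions: dark
    object on bright background -> -1, matched intensities -> 0, bright
    object on dark background -> +1.  (Referred to as "Weber contrast"
    in the source protocol although the classical Weber formula cannot
    reach +1 on a dark background.)
    """
    for v in (object_intensity, background_intensity):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"intensity {v} outside [0, 1]")
    return object_intensity - background_intensity


@dataclass
class DotTrajectory:
    """Circular-dot stimulus: a dot revolving on a circular path.

    Position angle ``psi(t)`` locates the dot centre on the path
    (0 deg = rightmost point, counter-clockwise positive); the
    instantaneous motion direction is the tangent, ``psi + 90`` deg for
    CCW and ``psi - 90`` deg for CW rotation.
    """

    times: np.ndarray
    position_angle: np.ndarray  # deg, psi(t)
    motion_direction: np.ndarray  # deg, theta(t)
    direction: str  # "CW" | "CCW"
    dot_diameter: float = 7.6  # deg
    path_diameter: float = 10.4  # deg
    frequency: float = 2.0  # Hz
    n_cycles: int = 10
    psi0: float = 0.0  # deg
    path_centre: tuple[float, float] = (0.0, 0.0)  # (az, el) deg

    @property
    def duration(self) -> float:
        return self.n_cycles / self.frequency

    @property
    def sign(self) -> int:
        return 1 if self.direction == "CCW" else -1

    def psi_at(self, t):
        """Position angle (deg, mod 360) at arbitrary times."""
        t = np.asarray(t, dtype=float)
        return np.mod(self.psi0 + self.sign * 360.0 * self.frequency * t, 360.0)

    def theta_at(self, t):
        """Instantaneous motion direction (deg, mod 360) at arbitrary times."""
        return np.mod(self.psi_at(t) + self.sign * 90.0, 360.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "position_angle_deg": self.position_angle,
                "motion_direction_deg": self.motion_direction,
            }
        )


def make_dot_trajectory(
    direction: str = "CW",
    sample_rate: float = 360.0,
    frequency: float = 2.0,
    n_cycles: int = 10,
    dot_diameter: float = 7.6,
    path_diameter: float = 10.4,
    psi0: float = 0.0,
    path_centre: tuple[float, float] = (0.0, 0.0),
) -> DotTrajectory:
    """Sample a circular-dot trajectory at ``sample_rate``."""
    if direction not in ("CW", "CCW"):
        raise ValueError("direction must be 'CW' or 'CCW'")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    duration = n_cycles / frequency
    times = np.arange(0.0, duration, 1.0 / sample_rate)
    traj = DotTrajectory(
        times=times,
        position_angle=np.empty_like(times),
        motion_direction=np.empty_like(times),
        direction=direction,
        dot_diameter=dot_diameter,
        path_diameter=path_diameter,
        frequency=frequency,
        n_cycles=n_cycles,
        psi0=psi0,
        path_centre=path_centre,
    )
    traj.position_angle = traj.psi_at(times)
    traj.motion_direction = traj.theta_at(times)
    return traj


@dataclass
class GridSchedule:
    """Timetable of square presentations over a rectangular grid.

    Entries are ``(row, col, onset_s, offset_s)`` in row-major scan
    order from the top-left; entry ``k`` starts at
    ``k * (on_duration + gap_duration)``.
    """

    entries: list[tuple[int, int, float, float]]
    grid_shape: tuple[int, int] = (20, 20)
    square_size: float = 0.5  # deg
    on_duration: float = 0.100  # s
    gap_duration: float = 0.050  # s

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def span(self) -> float:
        """Total schedule duration (end of last gap)."""
        return len(self.entries) * (self.on_duration + self.gap_duration)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["row", "col", "onset_s", "offset_s"]
        )


def make_grid_schedule(
    grid_shape: tuple[int, int] = (20, 20),
    square_size: float = 0.5,
    on_duration: float = 0.100,
    gap_duration: float = 0.050,
) -> GridSchedule:
    """Build the receptive-field mapping schedule: one square per cell."""
    if on_duration <= 0 or gap_duration < 0:
        raise ValueError("durations must be positive")
    rows, cols = grid_shape
    period = on_duration + gap_duration
    entries = []
    for k in range(rows * cols):
        r, c = divmod(k, cols)
        onset = k * period
        entries.append((r, c, onset, onset + on_duration))
    return GridSchedule(
        entries=entries,
        grid_shape=grid_shape,
        square_size=square_size,
        on_duration=on_duration,
        gap_duration=gap_duration,
    )


def grid_cell_centres(schedule: GridSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Angular (azimuth, elevation) centres of every grid cell, deg.

    The grid is centred on (0, 0); azimuth increases with column
    (rightward), elevation decreases with row (top row is dorsal-most).
    Returns two ``grid_shape`` arrays (azimuth, elevation).
    """
    rows, cols = schedule.grid_shape
    s = schedule.square_size
    az = (np.arange(cols) - (cols - 1) / 2.0) * s
    el = ((rows - 1) / 2.0 - np.arange(rows)) * s
    az_grid, el_grid = np.meshgrid(az, el)
    return az_grid, el_grid


def _deg_to_px(x_deg: float, y_deg: float, spec: DisplaySpec) -> tuple[float, float]:
    """Angular (az, el) coordinates -> pixel (col, row), screen centre at 0."""
    col = spec.width / 2.0 + x_deg / spec.degrees_per_pixel
    row = spec.height / 2.0 - y_deg / spec.degrees_per_pixel
    return col, row


def render_frames(
    protocol: DotTrajectory | GridSchedule,
    object_cmd: PolPixelCommand,
    background_cmd: PolPixelCommand,
    spec: DisplaySpec = DisplaySpec(),
    sync_patch_px: int = 50,
) -> tuple[list[FramePair], np.ndarray]:
    """Render a stimulus protocol to per-pattern-frame FramePairs.

    The object (dot or square) is drawn with ``object_cmd``, everything
    else with ``background_cmd``.  A ``sync_patch_px`` square patch in
    the bottom-left corner of the non-polarised channel alternates
    between 0 and ``max_grey`` on every pattern frame; the returned sync
    trace is its 0/1 state per frame.

    Raises ``ValueError`` if the object path leaves the display.
    """
    rate = pattern_rate(spec)
    if isinstance(protocol, DotTrajectory):
        duration = protocol.duration
    else:
        duration = protocol.span
    n_frames = int(round(duration * rate))
    times = np.arange(n_frames) / rate

    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    bg_pol, bg_nonpol = encode_pixel(background_cmd, spec)
    obj_pol, obj_nonpol = encode_pixel(object_cmd, spec)

    frames: list[FramePair] = []
    sync = np.zeros(n_frames, dtype=np.uint8)
    for i, t in enumerate(times):
        mask = _object_mask(protocol, t, xx, yy, spec)
        g_pol = np.full((spec.height, spec.width), bg_pol, dtype=np.uint8)
        g_nonpol = np.full((spec.height, spec.width), bg_nonpol, dtype=np.uint8)
        g_pol[mask] = obj_pol
        g_nonpol[mask] = obj_nonpol
        sync[i] = i % 2
        g_nonpol[-sync_patch_px:, :sync_patch_px] = sync[i] * spec.max_grey
        frames.append(FramePair(g_pol, g_nonpol))
    return frames, sync


def _object_mask(protocol, t, xx, yy, spec) -> np.ndarray:
    if isinstance(protocol, DotTrajectory):
        radius_path = protocol.path_diameter / 2.0
        psi = np.deg2rad(protocol.psi_at(t))
        cx = protocol.path_centre[0] + radius_path * np.cos(psi)
        cy = protocol.path_centre[1] + radius_path * np.sin(psi)
        r_px = protocol.dot_diameter / 2.0 / spec.degrees_per_pixel
        col, row = _deg_to_px(cx, cy, spec)
        if (
            col - r_px < 0
            or col + r_px > spec.width
            or row - r_px < 0
            or row + r_px > spec.height
        ):
            raise ValueError("dot leaves the display area")
        return (xx - col) ** 2 + (yy - row) ** 2 <= r_px**2
    # grid schedule: find the entry active at time t (if any)
    sched: GridSchedule = protocol
    period = sched.on_duration + sched.gap_duration
    k = int(t // period)
    if k >= len(sched.entries):
        return np.zeros_like(xx, dtype=bool)
    r, c, onset, offset = sched.entries[k]
    if not (onset <= t < offset):
        return np.zeros_like(xx, dtype=bool)
    az, el = grid_cell_centres(sched)
    col, row = _deg_to_px(az[r, c], el[r, c], spec)
    half = sched.square_size / 2.0 / spec.degrees_per_pixel
    if col - half < 0 or col + half > spec.width or row - half < 0 or row + half > spec.height:
        raise ValueError("grid square leaves the display area")
    return (np.abs(xx - col) <= half) & (np.abs(yy - row) <= half)
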