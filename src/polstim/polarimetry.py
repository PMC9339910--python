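"""Stokes-parameter imaging polarimetry.

Linear-polarisation state is recovered from four linear-intensity images
taken through an analyser at 0, 45, 90 and 135 deg:

    S0 = (I0 + I45 + I90 + I135) / 2
    S1 = I0 - I90
    S2 = I45 - I135
    AoP  = 0.5 * atan2(S2, S1)         (deg, in (-90, 90])
    DoLP = sqrt(S1^2 + S2^2) / S0

Inputs are assumed camera-linear (un-brightened, un-gamma-corrected);
raw conversion and demosaicing are out of scope, but single Bayer
channels can be extracted from an RGGB mosaic by strided subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolarimetricStack",
    "StokesMaps",
    "PolarisationMaps",
    "compute_stokes",
    "compute_aop",
    "compute_dolp",
    "compute_polarisation_maps",
    "synthesize_stack",
    "extract_bayer_channel",
    "dolp_weighted_aop_image",
]

ANALYSER_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0)

# RGGB layout: (row offset, col offset) of each colour in the 2x2 tile
_BAYER_OFFSETS = {"R": (0, 0), "G1": (0, 1), "G2": (1, 0), "B": (1, 1)}


@dataclass
class PolarimetricStack:
    """Four analyser-angle intensity images of identical shape."""

    I0: np.ndarray
    I45: np.ndarray
    I90: np.ndarray
    I135: np.ndarray

    def __post_init__(self) -> None:
        imgs = [np.asarray(im, dtype=float) for im in (self.I0, self.I45, self.I90, self.I135)]
        shapes = {im.shape for im in imgs}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for im in imgs:
            if im.size and im.min() < 0:
                raise ValueError("intensities must be non-negative")
        self.I0, self.I45, self.I90, self.I135 = imgs

    @property
    def shape(self):
        return self.I0.shape


@dataclass
class StokesMaps:
    """Total intensity S0 and the linear difference components S1, S2."""

    S0: np.ndarray
    S1: np.ndarray
    S2: np.ndarray

    def physicality_violations(self) -> np.ndarray:
        """Pixels where S1^2 + S2^2 > S0^2 (possible under noise;
        flagged rather than clipped)."""
        return self.S1**2 + self.S2**2 > self.S0**2


@dataclass
class PolarisationMaps:
    """AoP (deg, (-90, 90]) and DoLP maps with a validity mask."""

    aop: np.ndarray
    dolp: np.ndarray
    valid: np.ndarray  # S0 above floor and polarisation defined
    n_dolp_above_one: int = 0  # noise-driven unphysical pixels, not clipped


def compute_stokes(stack: PolarimetricStack) -> StokesMaps:
    """Four-angle Stokes estimators (sum-over-2 normalisation for S0)."""
    S0 = (stack.I0 + stack.I45 + stack.I90 + stack.I135) / 2.0
    S1 = stack.I0 - stack.I90
    S2 = stack.I45 - stack.I135
    return StokesMaps(S0=S0, S1=S1, S2=S2)


def compute_aop(S: StokesMaps) -> np.ndarray:
    """Angle of polarisation in degrees, range (-90, 90].

    Undefined (NaN) where S1 = S2 = 0.
    """
    aop = 0.5 * np.degrees(np.arctan2(S.S2, S.S1))
    undefined = (S.S1 == 0) & (S.S2 == 0)
    aop = np.where(undefined, np.nan, aop)
    return aop


def compute_dolp(
    S: StokesMaps, s0_floor: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Degree of linear polarisation with an S0 validity mask.

    Pixels with S0 at or below the floor (default ``1e-6 * max(S0)``)
    are masked NaN instead of emitting divide-by-zero noise.  Values
    above 1 (physically impossible, noise-driven) are preserved.
    """
    if s0_floor is None:
        s0_floor = 1e-6 * float(np.max(S.S0)) if S.S0.size else 0.0
    valid = S.S0 > s0_floor
    dolp = np.full(S.S0.shape, np.nan)
    np.divide(
        np.hypot(S.S1, S.S2), S.S0, out=dolp, where=valid
    )
    return dolp, valid


def compute_polarisation_maps(
    stack: PolarimetricStack, s0_floor: float | None = None
) -> PolarisationMaps:
    """Full pipeline: stack -> Stokes -> AoP/DoLP maps."""
    S = compute_stokes(stack)
    dolp, valid = compute_dolp(S, s0_floor=s0_floor)
    aop = compute_aop(S)
    aop = np.where(valid, aop, np.nan)
    n_above = int(np.sum(dolp[valid] > 1.0)) if valid.any() else 0
    return PolarisationMaps(
        aop=aop, dolp=dolp, valid=valid, n_dolp_above_one=n_above
    )


def synthesize_stack(
    S0_img: np.ndarray, dolp_img: np.ndarray, aop_img: np.ndarray
) -> PolarimetricStack:
    """Inverse of the analysis: build the four analyser-angle images.

    Uses the analyser response ``I(phi) = (S0 + S1 cos 2phi +
    S2 sin 2phi) / 2`` with ``S1 = S0 d cos 2a``, ``S2 = S0 d sin 2a``;
    ``compute_stokes(synthesize_stack(...))`` recovers the inputs
    exactly (to float rounding) wherever dolp > 0.
    """
    S0 = np.asarray(S0_img, dtype=float)
    d = np.asarray(dolp_img, dtype=float)
    a = np.deg2rad(np.asarray(aop_img, dtype=float))
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("dolp values outside [0, 1]")
    S1 = S0 * d * np.cos(2 * a)
    S2 = S0 * d * np.sin(2 * a)
    imgs = []
    for phi_deg in ANALYSER_ANGLES_DEG:
        phi = np.deg2rad(phi_deg)
        imgs.append((S0 + S1 * np.cos(2 * phi) + S2 * np.sin(2 * phi)) / 2.0)
    return PolarimetricStack(*imgs)


def extract_bayer_channel(mosaic: np.ndarray, channel: str) -> np.ndarray:
    """Pull one colour channel out of an RGGB mosaic by 2x2 subsampling.

    No interpolation: output is exactly half resolution in each
    dimension.  ``channel`` is one of R, G1, G2, B.
    """
    mosaic = np.asarray(mosaic)
    if mosaic.ndim != 2:
        raise ValueError("mosaic must be a 2-D image")
    if mosaic.shape[0] % 2 or mosaic.shape[1] % 2:
        raise ValueError(f"mosaic dimensions {mosaic.shape} must be even")
    try:
        dr, dc = _BAYER_OFFSETS[channel.upper()]
    except KeyError:
        raise ValueError(f"unknown Bayer channel {channel!r}; use R, G1, G2 or B")
    return mosaic[dr::2, dc::2]


def dolp_weighted_aop_image(maps: PolarisationMaps) -> np.ndarray:
    """Render AoP as hue with brightness weighted by DoLP.

    Hue wraps over the 180-deg AoP period so -90 and +90 deg share a
    colour; pixel value (brightness) equals DoLP clipped to [0, 1], so
    weakly polarised pixels appear dark and invalid pixels black.
    Returns an (H, W, 3) float RGB image in [0, 1].
    """
    from matplotlib.colors import hsv_to_rgb

    aop = np.where(np.isfinite(maps.aop), maps.aop, 0.0)
    hue = np.mod(aop, 180.0) / 180.0
    value = np.clip(np.where(np.isfinite(maps.dolp), maps.dolp, 0.0), 0.0, 1.0)
    value = np.where(maps.valid, value, 0.0)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)
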