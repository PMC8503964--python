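"""Grating stimulus synthesis.

Renders the vertical sinusoidal luminance gratings used in the contrast
matching task: a sine carrier windowed by a Gaussian envelope on a mid-gray
background, specified in degrees of visual angle (DVA) and rasterized at a
given pixel density.  Luminance is normalized to [0, 1]; no monitor gamma
model is applied.

Coordinate convention: patch-centered, x increases rightward, y downward,
both in DVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DisplayGeometry",
    "GratingSpec",
    "render_grating",
    "michelson_contrast",
    "compose_frame",
    "save_png",
]


@dataclass(frozen=True)
class DisplayGeometry:
    """Mapping between visual angle and pixels plus screen constants.

    Parameters
    ----------
    pixels_per_degree:
        Raster density in pixels per DVA; must be positive.
    background_luminance:
        Normalized mean luminance of the screen (0.5 = mid-gray).
    fixation_size:
        Side length of the central fixation cross, DVA.
    grating_offset:
        Vertical distance of each patch center from fixation, DVA.
    """

    pixels_per_degree: float
    background_luminance: float = 0.5
    fixation_size: float = 0.5
    grating_offset: float = 3.0

    def __post_init__(self) -> None:
        if not self.pixels_per_degree > 0:
            raise ValueError("pixels_per_degree must be > 0")
        if not 0.0 <= self.background_luminance <= 1.0:
            raise ValueError("background_luminance must be in [0, 1]")
        if not (self.fixation_size > 0 and self.grating_offset > 0):
            raise ValueError("sizes must be > 0")


@dataclass(frozen=True)
class GratingSpec:
    """Parameters of one Gabor-like grating patch.

    ``envelope_sigma`` defaults to ``size / 6`` so that the Gaussian mask
    fades to near-background at the patch edge (+/-3 sigma).  Pass
    ``math.inf`` to disable the envelope (a hard-edged sinusoid), which is
    useful when verifying nominal Michelson contrast.
    """

    contrast: float
    spatial_frequency: float = 3.0
    size: float = 3.0
    phase: float = 0.0
    envelope_sigma: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must be in [0, 1], got {self.contrast}")
        if not self.spatial_frequency > 0:
            raise ValueError("spatial_frequency must be > 0")
        if not self.size > 0:
            raise ValueError("size must be > 0")
        if self.envelope_sigma is not None and not self.envelope_sigma > 0:
            raise ValueError("envelope_sigma must be > 0 (or None for size/6)")

    @property
    def sigma(self) -> float:
        return self.size / 6.0 if self.envelope_sigma is None else self.envelope_sigma


def _patch_coords(size_dva: float, ppd: float) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(size_dva * ppd))
    if n < 1:
        raise ValueError("patch resolves to zero pixels; increase pixels_per_degree")
    # pixel centers in DVA, symmetric about the patch center
    c = (np.arange(n) - (n - 1) / 2.0) / ppd
    return np.meshgrid(c, c)


def render_grating(spec: GratingSpec, geometry: DisplayGeometry) -> np.ndarray:
    """Render one grating patch to a square luminance image in [0, 1].

    L(x, y) = Lb * (1 + c * exp(-(x^2+y^2)/(2 sigma^2)) * sin(2 pi f x + phi))

    with Lb the background luminance and (x, y) patch-centered DVA
    coordinates.  The carrier is vertical: luminance varies along x only.
    """
    x, y = _patch_coords(spec.size, geometry.pixels_per_degree)
    sigma = spec.sigma
    if math.isinf(sigma):
        envelope = np.ones_like(x)
    else:
        envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    carrier = np.sin(2.0 * math.pi * spec.spatial_frequency * x + spec.phase)
    lb = geometry.background_luminance
    image = lb * (1.0 + spec.contrast * envelope * carrier)
    return np.clip(image, 0.0, 1.0)


def michelson_contrast(image: np.ndarray) -> float:
    """(Lmax - Lmin) / (Lmax + Lmin) of a luminance image.

    Raises ``ValueError`` for an empty image or an all-black one (the ratio
    is undefined when Lmax + Lmin = 0).
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    lmax = float(arr.max())
    lmin = float(arr.min())
    if lmax + lmin == 0.0:
        raise ValueError("Michelson contrast undefined: Lmax + Lmin = 0")
    return (lmax - lmin) / (lmax + lmin)


def compose_frame(
    upper: GratingSpec | None,
    lower: GratingSpec | None,
    geometry: DisplayGeometry,
    frame_width: float = 8.0,
    frame_height: float = 14.0,
) -> np.ndarray:
    """Lay out a full display frame: fixation cross plus 0-2 grating patches.

    Patches are centered ``grating_offset`` DVA above (upper) and below
    (lower) the fixation cross, which is drawn in white at the frame center.
    Frame dimensions are in DVA.  Overlapping patches are rejected.
    """
    ppd = geometry.pixels_per_degree
    h = int(round(frame_height * ppd))
    w = int(round(frame_width * ppd))
    frame = np.full((h, w), geometry.background_luminance)

    if upper is not None and lower is not None:
        if geometry.grating_offset * 2.0 < (upper.size + lower.size) / 2.0:
            raise ValueError("grating patches overlap at this offset")

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    def _blit(spec: GratingSpec, sign: int) -> None:
        patch = render_grating(spec, geometry)
        n = patch.shape[0]
        top = int(round(cy + sign * geometry.grating_offset * ppd - (n - 1) / 2.0))
        left = int(round(cx - (n - 1) / 2.0))
        if top < 0 or left < 0 or top + n > h or left + n > w:
            raise ValueError("patch does not fit in frame; enlarge the frame")
        frame[top : top + n, left : left + n] = patch

    if upper is not None:
        _blit(upper, -1)  # y grows downward, so "above" is negative
    if lower is not None:
        _blit(lower, +1)

    # fixation cross: two one-pixel-wide white bars of fixation_size DVA
    half = max(1, int(round(geometry.fixation_size * ppd / 2.0)))
    iy, ix = int(round(cy)), int(round(cx))
    frame[iy, max(0, ix - half) : ix + half + 1] = 1.0
    frame[max(0, iy - half) : iy + half + 1, ix] = 1.0
    return frame


def save_png(image: np.ndarray, path) -> None:
    """Export a luminance image as an 8-bit grayscale PNG (for demos/docs)."""
    from PIL import Image

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="L").save(path)
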