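"""Phases 4-5: iris-colour subtraction and sclera-referenced white balance.

The colours inside the ROI mix the interference signal with the iris
colour underneath, and the whole image carries the tint of the room
light, LED temperature and camera exposure.  Two corrections are applied
in the flowchart's order:

Phase 4 — the mean iris colour, sampled inside the inner (0.8-radius)
circle but outside the ROI and pupil, is subtracted channel-wise from
every ROI pixel (clamped at 0).

Phase 5 — the sclera is treated as an in-scene white reference: the
per-channel gains that would map its mean colour to reference white are
applied multiplicatively (von-Kries-style white balancing; an additive
offset mode is available for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frames import Frame, pixel_brightness
from .geometry import EyeGeometry, ROIMask

__all__ = [
    "ColorBias",
    "estimate_iris_color",
    "subtract_iris",
    "sample_sclera",
    "estimate_illumination_gains",
    "apply_gains",
    "apply_offsets",
]

REFERENCE_WHITE = np.array([255.0, 255.0, 255.0])


@dataclass(frozen=True)
class ColorBias:
    """Per-frame colour-correction parameters."""

    iris_color: np.ndarray
    sclera_white: np.ndarray
    channel_gains: np.ndarray

    def __post_init__(self) -> None:
        for name in ("iris_color", "sclera_white", "channel_gains"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.channel_gains <= 0):
            raise ValueError("channel gains must be positive")
        for name in ("iris_color", "sclera_white"):
            v = getattr(self, name)
            if v.shape != (3,) or v.min() < 0 or v.max() > 255:
                raise ValueError(f"{name} must be an RGB triple in [0, 255]")


def estimate_iris_color(
    frame: Frame | np.ndarray,
    geometry: EyeGeometry,
    roi: ROIMask,
    roi_fraction: float = 0.8,
    pupil_margin: int = 20,
    band_margin: float = 5.0,
) -> np.ndarray:
    """Mean RGB of iris pixels inside the inner circle but outside ROI and pupil.

    "Outside the ROI" means outside the whole geometric inferior-iris
    region the ROI was cut from, not merely outside the pixels that
    survived its brightness filter: below-average interference pixels are
    still interference, not iris, and would bias the estimate.  The pupil
    mask is dilated by ``pupil_margin`` pixels before exclusion because
    the refined mask hugs the pupil interior and would otherwise let dark
    pupil-boundary pixels darken the iris estimate.  The inferior region
    is carved out with a ``band_margin``-row safety strip above the
    centre row, since a centre estimate a couple of pixels low would
    otherwise leak the brightest band rows into the sample.

    Raises ``ValueError`` when the sampling region is empty (the caller
    may fall back to the previous frame's estimate).
    """
    pixels = np.asarray(frame.pixels if isinstance(frame, Frame) else frame, dtype=float)
    h, w = pixels.shape[:2]
    rr, cc = np.ogrid[:h, :w]
    r0, c0 = geometry.eye_center
    inner_radius = roi_fraction * geometry.iris_radius
    inner = (rr - r0) ** 2 + (cc - c0) ** 2 <= inner_radius**2
    band = (
        inner
        & (rr > r0 - band_margin)
        & (np.abs(cc - c0) <= roi_fraction * inner_radius + band_margin)
    )
    pupil = geometry.pupil_mask
    if pupil_margin > 0:
        pupil = ndimage.maximum_filter(pupil, size=2 * pupil_margin + 1)
    sample = inner & ~band & ~roi.mask & ~pupil
    if not sample.any():
        raise ValueError("iris colour sampling region is empty")
    return pixels[sample].mean(axis=0)


def subtract_iris(pixels: np.ndarray, iris_color: np.ndarray) -> np.ndarray:
    """Channel-wise subtraction of the iris colour, clamped to [0, 255]."""
    out = np.asarray(pixels, dtype=float) - np.asarray(iris_color, dtype=float)
    return np.clip(out, 0.0, 255.0)


def sample_sclera(
    frame: Frame | np.ndarray,
    geometry: EyeGeometry,
    fraction: float = 0.01,
    box: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Mean RGB of the sclera sample used as the white reference.

    By default: the brightest ``fraction`` of pixels outside the iris
    circle, excluding saturated pixels (any channel at 255).  Brightness
    for the selection is measured on a lightly denoised image so that a
    homogeneous sclera does not contribute only its sensor-noise upper
    tail (which would bias the white reference bright); the returned mean
    is over the raw pixels.  A manual ``box`` override ``(row0, row1,
    col0, col1)`` samples that rectangle instead (still excluding
    saturated pixels).
    """
    pixels = np.asarray(frame.pixels if isinstance(frame, Frame) else frame, dtype=float)
    h, w = pixels.shape[:2]
    if box is not None:
        r0, r1, c0, c1 = box
        candidates = np.zeros((h, w), dtype=bool)
        candidates[r0:r1, c0:c1] = True
    else:
        rr, cc = np.ogrid[:h, :w]
        er, ec = geometry.eye_center
        candidates = (rr - er) ** 2 + (cc - ec) ** 2 > geometry.iris_radius**2
    candidates &= ~(pixels == 255.0).any(axis=-1)
    if not candidates.any():
        raise ValueError("no unsaturated sclera candidates")
    if box is None:
        smoothed = ndimage.gaussian_filter(pixel_brightness(pixels), sigma=8.0)
        cutoff = np.quantile(smoothed[candidates], 1.0 - fraction)
        candidates &= smoothed >= cutoff
    return pixels[candidates].mean(axis=0)


def estimate_illumination_gains(
    sclera_sample: np.ndarray, reference_white: np.ndarray = REFERENCE_WHITE
) -> np.ndarray:
    """Per-channel gains mapping the sclera sample onto the reference white."""
    sample = np.asarray(sclera_sample, dtype=float)
    if np.any(sample <= 0):
        raise ValueError("sclera sample has a zero channel; cannot form gains")
    return np.asarray(reference_white, dtype=float) / sample


def apply_gains(pixels: np.ndarray, channel_gains: np.ndarray) -> np.ndarray:
    """Multiplicative white balance, clamped to [0, 255]."""
    gains = np.asarray(channel_gains, dtype=float)
    if np.any(gains <= 0):
        raise ValueError("channel gains must be positive")
    return np.clip(np.asarray(pixels, dtype=float) * gains, 0.0, 255.0)


def apply_offsets(pixels: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Additive illumination correction (sensitivity-analysis alternative)."""
    out = np.asarray(pixels, dtype=float) + np.asarray(offsets, dtype=float)
    return np.clip(out, 0.0, 255.0)
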