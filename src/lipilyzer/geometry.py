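"""Phases 2-3: pupil/eye-centre localization, iris radius, ROI extraction.

The pupil is the darkest structure in the image, so the darkest 21x21
window seeds an 8-connected flood fill (brightness tolerance 5/256) that
grows the pupil region.  The region is refined by painting it white,
blurring, and re-flooding with a lower tolerance (3/256), which smooths
a boundary that would otherwise leak into the iris.  The eye centre is
the refined pupil centroid unless it drifted far from the darkest seed,
in which case the seed wins.

The iris radius comes from a second flood fill seeded inside the iris:
Canny edges of that region are kept only where the edge orientation is
nearly vertical (eyelids occlude the top/bottom arcs, so only the left
and right arcs are trustworthy) and where the distance from the eye
centre is plausible; the radius is the mean distance of the surviving
edge pixels.

The region of interest is the inferior part of the iris: inside 80% of
the iris radius, strictly below the eye-centre row, within 80% of that
inner circle laterally, at or above the region's mean brightness, and
outside the pupil.

Coordinates are 0-based ``(row, col)``, origin at the top-left, row
increasing downward; "above the centre" means a smaller row index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import canny

from .frames import Frame, pixel_brightness

__all__ = [
    "GeometryConfig",
    "EyeGeometry",
    "ROIMask",
    "GeometryError",
    "IrisNotFoundError",
    "EmptyROIError",
    "find_darkest_seed",
    "flood_fill",
    "refine_pupil",
    "choose_eye_center",
    "estimate_iris_radius",
    "extract_roi",
    "compute_geometry",
]


class GeometryError(ValueError):
    """A frame on which the eye geometry cannot be established."""


class IrisNotFoundError(GeometryError):
    """No iris boundary pixels survive the orientation/distance filters."""


class EmptyROIError(GeometryError):
    """The inferior-iris region of interest came out empty."""


@dataclass(frozen=True)
class GeometryConfig:
    """Tunables of the geometry phases (pixel units unless noted)."""

    window: int = 21                    # darkest-region window size
    pupil_threshold: float = 5.0        # flood-fill tolerance, /256 scale
    refine_threshold: float = 3.0       # second flood fill after blurring
    blur_sigma: float = 5.0             # Gaussian blur for the refine step
    expected_radius: float = 240.0      # prior iris radius at the acquisition zoom
    iris_threshold: float = 20.0        # flood-fill tolerance for the iris region
    angular_tol_deg: float = 15.0       # edge orientation window around vertical
    band: tuple[float, float] = (0.8, 1.2)  # plausible radius range x expected
    roi_fraction: float = 0.8           # ROI circle as a fraction of iris radius

    @property
    def max_center_distance(self) -> float:
        """Farthest the pupil centroid may sit from the darkest seed.

        The darkest window can land anywhere inside the pupil, so the
        bound must exceed a plausible pupil radius; 0.4 x expected iris
        radius covers pupils up to that relative size.
        """
        return 0.4 * self.expected_radius


@dataclass(frozen=True)
class EyeGeometry:
    """Pupil and iris geometry of one frame."""

    darkest_seed: tuple[int, int]
    pupil_mask: np.ndarray
    pupil_centroid: tuple[float, float]
    eye_center: tuple[float, float]
    iris_radius: float

    def __post_init__(self) -> None:
        if not self.pupil_mask.any():
            raise ValueError("pupil mask is empty")
        h, w = self.pupil_mask.shape
        r, c = self.eye_center
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("eye centre outside image bounds")
        if self.iris_radius <= 0:
            raise ValueError("iris radius must be positive")


@dataclass(frozen=True)
class ROIMask:
    """Analyzable inferior-iris pixels of one frame."""

    mask: np.ndarray
    frame_index: int = -1
    pixel_count: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixel_count", int(self.mask.sum()))


def _as_brightness(frame: Frame | np.ndarray) -> np.ndarray:
    if isinstance(frame, Frame):
        return pixel_brightness(frame.pixels)
    arr = np.asarray(frame, dtype=float)
    if arr.ndim == 3:
        return pixel_brightness(arr)
    return arr


def find_darkest_seed(frame: Frame | np.ndarray, window: int = 21) -> tuple[int, int]:
    """Centre of the ``window x window`` patch with the lowest mean brightness.

    Ties are broken toward the smallest row, then the smallest column.
    Window sums are taken over the integer channel sum so tie comparisons
    are exact.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if pixels.ndim == 3:
        values = pixels.astype(np.int64).sum(axis=-1)
    else:
        values = np.rint(np.asarray(pixels, dtype=float) * 3).astype(np.int64)
    h, w = values.shape
    if h < window or w < window:
        raise ValueError(f"frame {h}x{w} smaller than the {window}x{window} window")
    # exact sliding-window sums from the 2-D prefix-sum table
    pad = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(values, axis=0), axis=1, out=pad[1:, 1:])
    sums = (
        pad[window:, window:]
        - pad[:-window, window:]
        - pad[window:, :-window]
        + pad[:-window, :-window]
    )
    top, left = np.unravel_index(int(np.argmin(sums)), sums.shape)
    return int(top) + window // 2, int(left) + window // 2


def flood_fill(
    frame: Frame | np.ndarray,
    seed: tuple[int, int],
    threshold: float,
    connectivity: int = 8,
) -> np.ndarray:
    """8-connected region of pixels within ``threshold`` brightness of the seed.

    A pixel joins the region when it is reachable from the seed through
    neighbours whose brightness differs from the *seed pixel's* brightness
    by strictly less than ``threshold``.
    """
    brightness = _as_brightness(frame)
    h, w = brightness.shape
    r, c = seed
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"seed {seed} outside image of shape {(h, w)}")
    within = np.abs(brightness - brightness[r, c]) < threshold
    structure = np.ones((3, 3), bool) if connectivity == 8 else None
    labels, _ = ndimage.label(within, structure=structure)
    return labels == labels[r, c]


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """First-moment centroid (row, col) of a boolean mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("cannot take the centroid of an empty mask")
    return float(rows.mean()), float(cols.mean())


def refine_pupil(
    frame: Frame | np.ndarray,
    coarse_mask: np.ndarray,
    seed: tuple[int, int] | None = None,
    blur_sigma: float = 5.0,
    refine_threshold: float = 3.0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Smooth the pupil boundary: paint the coarse region white, blur, re-flood.

    The coarse flood fill can leak into the iris and leave a ragged
    boundary; painting it to maximum brightness and blurring turns the
    pupil into a smooth bright blob whose core is recovered by a stricter
    flood fill.  With ``seed=None`` the re-flood starts from the coarse
    mask's deepest interior point (its incenter): the original darkest
    seed can sit near the pupil boundary, where blurring lowers the
    painted value and a flood from it would trace a thin level-set ring
    instead of the core.  Falls back to the coarse mask if the refined
    region is empty.
    """
    if not coarse_mask.any():
        raise ValueError("coarse pupil mask is empty")
    if seed is None:
        depth = ndimage.distance_transform_edt(coarse_mask)
        seed = tuple(int(v) for v in np.unravel_index(int(np.argmax(depth)), depth.shape))
    brightness = _as_brightness(frame).copy()
    brightness[coarse_mask] = 255.0
    blurred = ndimage.gaussian_filter(brightness, sigma=blur_sigma)
    refined = flood_fill(blurred, seed, refine_threshold)
    if not refined.any():  # pragma: no cover - flood fill always contains its seed
        refined = coarse_mask
    return refined, mask_centroid(refined)


def choose_eye_center(
    pupil_centroid: tuple[float, float],
    darkest_seed: tuple[int, int],
    max_distance: float,
) -> tuple[float, float]:
    """Pupil centroid unless it sits farther than ``max_distance`` (inclusive)
    from the darkest seed, in which case the seed is the safer centre."""
    dist = math.hypot(
        pupil_centroid[0] - darkest_seed[0], pupil_centroid[1] - darkest_seed[1]
    )
    if dist <= max_distance:
        return pupil_centroid
    return float(darkest_seed[0]), float(darkest_seed[1])


def estimate_iris_radius(
    frame: Frame | np.ndarray,
    eye_center: tuple[float, float],
    config: GeometryConfig = GeometryConfig(),
) -> float:
    """Iris radius from the near-vertical Canny edges of the iris region.

    Seeds a flood fill half an expected radius to the left of the eye
    centre and a quarter radius above it (adjacent to the pupil on the
    side least likely to land on eyelid, sclera or the interference band,
    which sits below the centre), finds the region's Canny edges, keeps
    edge pixels whose gradient is within ``angular_tol_deg`` of horizontal
    (edge tangent near vertical) and whose distance from the centre lies
    in ``band x expected_radius``, and returns their mean distance.
    """
    brightness = _as_brightness(frame)
    h, w = brightness.shape
    if config.expected_radius <= 0:
        raise ValueError("expected_radius must be positive")
    seed = (
        int(round(min(max(eye_center[0] - 0.25 * config.expected_radius, 0), h - 1))),
        int(round(min(max(eye_center[1] - 0.5 * config.expected_radius, 0), w - 1))),
    )
    region = flood_fill(brightness, seed, config.iris_threshold)
    region_f = region.astype(float)
    edges = canny(region_f, sigma=2.0)
    if not edges.any():
        raise IrisNotFoundError("iris region has no edges")
    smoothed = ndimage.gaussian_filter(region_f, sigma=2.0)
    gy, gx = np.gradient(smoothed)
    rows, cols = np.nonzero(edges)
    angle_to_horizontal = np.degrees(
        np.arctan2(np.abs(gy[rows, cols]), np.abs(gx[rows, cols]))
    )
    dist = np.hypot(rows - eye_center[0], cols - eye_center[1])
    lo, hi = config.band
    keep = (
        (angle_to_horizontal <= config.angular_tol_deg)
        & (dist >= lo * config.expected_radius)
        & (dist <= hi * config.expected_radius)
    )
    if not keep.any():
        raise IrisNotFoundError(
            "no near-vertical iris boundary pixels within the expected radius band"
        )
    return float(dist[keep].mean())


def extract_roi(
    frame: Frame | np.ndarray,
    eye_center: tuple[float, float],
    iris_radius: float,
    pupil_mask: np.ndarray | None = None,
    roi_fraction: float = 0.8,
    frame_index: int = -1,
) -> ROIMask:
    """Inferior-iris region of interest.

    Keeps pixels that are (a) within ``roi_fraction * iris_radius`` of the
    eye centre, (b) strictly below the eye-centre row, (c) laterally
    within ``roi_fraction`` of that inner circle's radius, and (d) at or
    above the mean brightness of the region satisfying (a)-(c); pupil
    pixels are excluded throughout.  Raises :class:`EmptyROIError` when
    nothing survives.
    """
    brightness = _as_brightness(frame)
    h, w = brightness.shape
    rr, cc = np.ogrid[:h, :w]
    inner_radius = roi_fraction * iris_radius
    region = (
        ((rr - eye_center[0]) ** 2 + (cc - eye_center[1]) ** 2 <= inner_radius**2)
        & (rr > eye_center[0])
        & (np.abs(cc - eye_center[1]) <= roi_fraction * inner_radius)
    )
    if pupil_mask is not None:
        region &= ~pupil_mask
    if not region.any():
        raise EmptyROIError("inferior-iris region is empty")
    mean_brightness = brightness[region].mean()
    mask = region & (brightness >= mean_brightness)
    if not mask.any():
        raise EmptyROIError("region of interest empty after the brightness filter")
    return ROIMask(mask=mask, frame_index=frame_index)


def _representative_seed(
    brightness: np.ndarray, seed: tuple[int, int], window: int
) -> tuple[int, int]:
    """A median-brightness pixel of the darkest window, nearest the centre.

    Flood filling measures every pixel against the starting pixel, so a
    start whose own value is a sensor-noise outlier strands the fill on a
    fragment of the pupil; the window's median pixel is a representative
    start with the same tolerance semantics.
    """
    half = window // 2
    r0, c0 = seed
    patch = brightness[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1]
    target = np.median(patch)
    rows, cols = np.nonzero(np.abs(patch - target) == np.abs(patch - target).min())
    best = np.argmin((rows - half) ** 2 + (cols - half) ** 2)
    return r0 - half + int(rows[best]), c0 - half + int(cols[best])


def compute_geometry(
    frame: Frame | np.ndarray, config: GeometryConfig = GeometryConfig()
) -> EyeGeometry:
    """Run Phase 2 end to end on one frame."""
    seed = find_darkest_seed(frame, config.window)
    start = _representative_seed(_as_brightness(frame), seed, config.window)
    coarse = flood_fill(frame, start, config.pupil_threshold)
    refined, centroid = refine_pupil(
        frame, coarse, None, config.blur_sigma, config.refine_threshold
    )
    center = choose_eye_center(centroid, seed, config.max_center_distance)
    radius = estimate_iris_radius(frame, center, config)
    return EyeGeometry(
        darkest_seed=seed,
        pupil_mask=refined,
        pupil_centroid=centroid,
        eye_center=center,
        iris_radius=radius,
    )
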