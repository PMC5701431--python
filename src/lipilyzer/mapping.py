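"""Phase 6 and the statistical outputs: colour -> thickness and summaries.

Every corrected ROI pixel is assigned the lookup-table thickness whose
colour is nearest in Euclidean RGB distance (ties to the thinner film).
Pixels darkened by eyelash shadows carry no interference information;
anything below a small brightness floor is excluded before statistics.

Per frame we report mean, population SD, pixel count and a
relative-frequency histogram of thickness; per video, the pooled mean
and SD over all assigned pixels of all retained frames.  For
visualization the ROI is resampled onto a 50x50 grid (surface plots) and
pooled (RGB, thickness) pairs from three consecutive frames are
downsampled to one third (RGB-space scatter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import pixel_brightness
from .geometry import ROIMask
from .lut import ColorLUT

__all__ = [
    "LLTMap",
    "FrameStats",
    "SurfaceGrid",
    "RGBScatter",
    "assign_thickness",
    "map_frame",
    "frame_statistics",
    "sequence_statistics",
    "surface_grid",
    "rgb_scatter",
    "SHADOW_FLOOR_DEFAULT",
    "SENTINEL_NM",
]

#: corrected-brightness floor below which a pixel counts as eyelash shadow
SHADOW_FLOOR_DEFAULT = 10.0
#: sentinel value for non-ROI / excluded positions in exported rasters
SENTINEL_NM = 65535


@dataclass(frozen=True)
class LLTMap:
    """Per-pixel lipid layer thickness raster for one frame.

    ``thickness`` is a float raster in nm with NaN at positions outside
    the ROI or excluded as shadow; ``colors`` keeps the corrected RGB
    raster the assignment was made from.
    """

    frame_index: int
    thickness: np.ndarray
    roi: ROIMask
    colors: np.ndarray

    @property
    def assigned(self) -> np.ndarray:
        """1-D array of assigned thickness values."""
        return self.thickness[np.isfinite(self.thickness)]

    @property
    def assigned_mask(self) -> np.ndarray:
        return np.isfinite(self.thickness)


@dataclass(frozen=True)
class FrameStats:
    """Summary of one frame's thickness map."""

    frame_index: int
    time: float
    mean_llt: float
    sd_llt: float
    n_pixels: int
    histogram: np.ndarray
    bin_edges: np.ndarray


@dataclass(frozen=True)
class SurfaceGrid:
    """50x50 nearest-pixel resampling of the ROI thickness field."""

    frame_index: int
    grid: np.ndarray

    def __post_init__(self) -> None:
        if self.grid.shape != (50, 50):
            raise ValueError("surface grid must be 50x50")


@dataclass(frozen=True)
class RGBScatter:
    """Pooled (RGB, thickness) pairs from up to three consecutive frames."""

    rgb: np.ndarray
    thickness: np.ndarray
    frame_indices: tuple = ()


def assign_thickness(pixel_rgb: np.ndarray, lut: ColorLUT) -> np.ndarray:
    """Nearest-colour thickness for one RGB triple or an array of them."""
    return lut.nearest(pixel_rgb)


def map_frame(
    corrected: np.ndarray,
    roi: ROIMask,
    lut: ColorLUT,
    frame_index: int = -1,
    shadow_floor: float = SHADOW_FLOOR_DEFAULT,
) -> LLTMap:
    """Assign a thickness to every analyzable ROI pixel of one frame.

    ``corrected`` is the fully colour-corrected HxWx3 raster.  ROI pixels
    whose corrected brightness is below ``shadow_floor`` are treated as
    eyelash shadow and excluded.  Raises when nothing remains.
    """
    corrected = np.asarray(corrected, dtype=float)
    if roi.pixel_count == 0:
        raise ValueError("empty ROI")
    usable = roi.mask & (pixel_brightness(corrected) >= shadow_floor)
    if not usable.any():
        raise ValueError("ROI empty after eyelash-shadow exclusion")
    thickness = np.full(roi.mask.shape, np.nan)
    thickness[usable] = lut.nearest(corrected[usable])
    return LLTMap(frame_index=frame_index, thickness=thickness, roi=roi, colors=corrected)


def frame_statistics(
    llt_map: LLTMap,
    time: float = 0.0,
    bin_width: float = 10.0,
    thickness_range: tuple[float, float] = (0.0, 240.0),
) -> FrameStats:
    """Mean, population SD and relative-frequency histogram of one frame."""
    values = llt_map.assigned
    if values.size == 0:
        raise ValueError("empty thickness map")
    lo, hi = thickness_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return FrameStats(
        frame_index=llt_map.frame_index,
        time=time,
        mean_llt=float(values.mean()),
        sd_llt=float(values.std()),
        n_pixels=int(values.size),
        histogram=counts / values.size,
        bin_edges=edges,
    )


@dataclass(frozen=True)
class SequenceSummary:
    """Video-level pooled statistics plus the per-frame series."""

    mean_llt: float
    sd_llt: float
    n_pixels: int
    frames: list = field(default_factory=list)


def sequence_statistics(stats: list[FrameStats]) -> SequenceSummary:
    """Pool all assigned pixels of all frames into one mean +/- SD.

    The pooled SD is the population SD of the flattened pixel set,
    reconstructed exactly from the per-frame moments.
    """
    if not stats:
        raise ValueError("no frame statistics to pool")
    n = np.array([s.n_pixels for s in stats], dtype=float)
    m = np.array([s.mean_llt for s in stats])
    sd = np.array([s.sd_llt for s in stats])
    total = n.sum()
    mean = float((n * m).sum() / total)
    second_moment = float((n * (sd**2 + m**2)).sum() / total)
    return SequenceSummary(
        mean_llt=mean,
        sd_llt=float(np.sqrt(max(second_moment - mean**2, 0.0))),
        n_pixels=int(total),
        frames=list(stats),
    )


def surface_grid(llt_map: LLTMap, size: int = 50) -> SurfaceGrid:
    """Resample the ROI's bounding box onto a ``size x size`` grid.

    Nearest-pixel sampling; grid cells whose source pixel is not an
    assigned ROI pixel carry NaN.
    """
    mask = llt_map.assigned_mask
    rows, cols = np.nonzero(llt_map.roi.mask)
    if rows.size == 0:
        raise ValueError("empty thickness map")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub = llt_map.thickness[r0:r1, c0:c1]
    h, w = sub.shape
    ri = np.clip(((np.arange(size) + 0.5) * h / size).astype(int), 0, h - 1)
    ci = np.clip(((np.arange(size) + 0.5) * w / size).astype(int), 0, w - 1)
    grid = sub[np.ix_(ri, ci)]
    return SurfaceGrid(frame_index=llt_map.frame_index, grid=grid)


def rgb_scatter(maps: list[LLTMap], downsample: int = 3) -> RGBScatter:
    """Pool (corrected RGB, thickness) pairs from consecutive frames.

    The paper pools three consecutive retained frames and keeps every
    third pixel in scan order; fewer than three maps are used as-is with
    a warning.
    """
    import warnings

    if not maps:
        raise ValueError("no thickness maps")
    if len(maps) < 3:
        warnings.warn(f"rgb_scatter: only {len(maps)} frame(s) available; using all")
    rgb_parts, thick_parts = [], []
    for m in maps[:3]:
        sel = m.assigned_mask
        rgb_parts.append(m.colors[sel])
        thick_parts.append(m.thickness[sel])
    rgb = np.concatenate(rgb_parts)[::downsample]
    thickness = np.concatenate(thick_parts)[::downsample]
    return RGBScatter(
        rgb=rgb, thickness=thickness, frame_indices=tuple(m.frame_index for m in maps[:3])
    )
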