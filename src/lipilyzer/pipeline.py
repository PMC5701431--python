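"""End-to-end analysis: video in, per-frame LLT statistics and exports out.

Runs the six phases in order on an analysis window of frames: blink
rejection by global brightness, pupil/eye-centre localization, iris
radius and ROI extraction, iris-colour subtraction, sclera-referenced
white balance, and nearest-colour thickness assignment.  Frames whose
geometry cannot be established (pupil partially occluded, iris boundary
not found, empty ROI) are dropped with a recorded reason, implementing
the occlusion half of the frame-rejection rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import correction as corr
from .frames import (
    BLINK_COEF_DEFAULT,
    MIN_BLINK_GAP_DEFAULT,
    FrameSequence,
    select_frames,
)
from .geometry import (
    EyeGeometry,
    GeometryConfig,
    GeometryError,
    ROIMask,
    compute_geometry,
    extract_roi,
)
from .lut import ColorLUT, build_lut
from .mapping import (
    SHADOW_FLOOR_DEFAULT,
    FrameStats,
    LLTMap,
    RGBScatter,
    SequenceSummary,
    SurfaceGrid,
    frame_statistics,
    map_frame,
    rgb_scatter,
    sequence_statistics,
    surface_grid,
)

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_sequence", "write_outputs"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of one analysis run."""

    fps: float = 30.0
    window_s: float = 2.5              # analysis window; 75 frames at 30 fps
    blink_coef: float = BLINK_COEF_DEFAULT
    min_blink_gap: float = MIN_BLINK_GAP_DEFAULT
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    shadow_floor: float = SHADOW_FLOOR_DEFAULT
    bin_width: float = 10.0
    gains_per_frame: bool = False      # re-estimate white balance every frame
    per_pixel_iris: bool = False       # row-resolved iris subtraction (variant)
    keep_maps: int = 3                 # full thickness maps kept for Figs 5-6 style output

    def flat_dict(self) -> dict:
        out = {}
        for key, value in asdict(self).items():
            if isinstance(value, dict):
                out.update({f"geometry.{k}": v for k, v in value.items()})
            else:
                out[key] = value
        return out


@dataclass
class AnalysisResult:
    """Everything one analysis run produced."""

    summary: SequenceSummary
    frame_stats: list[FrameStats]
    selection_report: pd.DataFrame
    correction_report: pd.DataFrame
    dropped: list[tuple[int, str]]
    maps: list[LLTMap]
    surface: SurfaceGrid | None
    scatter: RGBScatter | None
    config: AnalysisConfig
    lut: ColorLUT


def _subtract_iris_rowwise(
    pixels: np.ndarray,
    frame_pixels: np.ndarray,
    roi: ROIMask,
    geometry: EyeGeometry,
    roi_fraction: float,
) -> np.ndarray:
    """Row-resolved iris subtraction: each ROI row uses the mean colour of
    iris pixels on the same image row, outside the geometric inferior band
    (plus margin) and away from the pupil, falling back to the global iris
    mean where a row has no clean sample."""
    from scipy import ndimage

    h, w = frame_pixels.shape[:2]
    rr, cc = np.ogrid[:h, :w]
    r0, c0 = geometry.eye_center
    inner_radius = roi_fraction * geometry.iris_radius
    inner = (rr - r0) ** 2 + (cc - c0) ** 2 <= inner_radius**2
    band = (rr > r0 - 5.0) & (np.abs(cc - c0) <= roi_fraction * inner_radius + 5.0)
    pupil = ndimage.maximum_filter(geometry.pupil_mask, size=21)
    sample = inner & ~band & ~roi.mask & ~pupil
    out = np.asarray(pixels, dtype=float).copy()
    frame_float = np.asarray(frame_pixels, dtype=float)
    fallback = frame_float[sample].mean(axis=0)
    for row in np.unique(np.nonzero(roi.mask)[0]):
        row_sample = sample[row]
        iris_row = frame_float[row][row_sample].mean(axis=0) if row_sample.any() else fallback
        out[row][roi.mask[row]] -= iris_row
    return np.clip(out, 0.0, 255.0)


def analyze_sequence(
    frames: FrameSequence,
    lut: ColorLUT | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisResult:
    """Run the full six-phase analysis on a frame sequence."""
    lut = lut or build_lut()

    window_n = int(round(config.window_s * config.fps))
    window = FrameSequence(frames[:window_n] if window_n > 0 else frames, fps=frames.fps)

    retained, selection_report = select_frames(
        window, config.blink_coef, config.min_blink_gap
    )

    gains: np.ndarray | None = None
    stats: list[FrameStats] = []
    maps: list[LLTMap] = []
    dropped: list[tuple[int, str]] = []
    corr_rows = []
    retained_count = len(retained)
    # keep full maps only for a few central frames (surface/scatter exports)
    keep = set()
    if config.keep_maps > 0:
        mid = retained_count // 2
        half = config.keep_maps // 2
        keep = {i for i in range(mid - half, mid - half + config.keep_maps)}

    for pos, frame in enumerate(retained):
        try:
            geometry = compute_geometry(frame, config.geometry)
            roi = extract_roi(
                frame,
                geometry.eye_center,
                geometry.iris_radius,
                geometry.pupil_mask,
                config.geometry.roi_fraction,
                frame_index=frame.index,
            )
        except GeometryError as exc:
            dropped.append((frame.index, str(exc)))
            selection_report.loc[
                selection_report["frame_index"] == frame.index, ["kept", "reason"]
            ] = [False, f"geometry: {exc}"]
            continue

        pixels = frame.pixels.astype(float)
        iris_color = corr.estimate_iris_color(
            frame, geometry, roi, config.geometry.roi_fraction
        )
        if config.per_pixel_iris:
            subtracted = _subtract_iris_rowwise(
                pixels, frame.pixels, roi, geometry, config.geometry.roi_fraction
            )
        else:
            subtracted = corr.subtract_iris(pixels, iris_color)

        if gains is None or config.gains_per_frame:
            sclera = corr.sample_sclera(frame, geometry)
            gains = corr.estimate_illumination_gains(sclera)
        else:
            sclera = np.full(3, np.nan)
        corrected = corr.apply_gains(subtracted, gains)
        corr_rows.append(
            {
                "frame_index": frame.index,
                "iris_r": iris_color[0],
                "iris_g": iris_color[1],
                "iris_b": iris_color[2],
                "sclera_r": sclera[0],
                "sclera_g": sclera[1],
                "sclera_b": sclera[2],
                "gain_r": gains[0],
                "gain_g": gains[1],
                "gain_b": gains[2],
            }
        )

        try:
            llt_map = map_frame(
                corrected, roi, lut, frame_index=frame.index, shadow_floor=config.shadow_floor
            )
        except ValueError as exc:
            dropped.append((frame.index, str(exc)))
            continue
        stats.append(
            frame_statistics(llt_map, time=frame.time, bin_width=config.bin_width)
        )
        if pos in keep:
            maps.append(llt_map)

    if not stats:
        raise GeometryError("no frame yielded an analyzable region of interest")

    summary = sequence_statistics(stats)
    surface = surface_grid(maps[len(maps) // 2]) if maps else None
    scatter = rgb_scatter(maps) if maps else None
    return AnalysisResult(
        summary=summary,
        frame_stats=stats,
        selection_report=selection_report,
        correction_report=pd.DataFrame(corr_rows),
        dropped=dropped,
        maps=maps,
        surface=surface,
        scatter=scatter,
        config=config,
        lut=lut,
    )


def write_outputs(result: AnalysisResult, out_dir: str | Path) -> Path:
    """Write the run's data products as plain-text CSV/JSON plus 16-bit maps."""
    import imageio.v3 as iio

    from .mapping import SENTINEL_NM

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stats = pd.DataFrame(
        {
            "frame_index": [s.frame_index for s in result.frame_stats],
            "time_s": [s.time for s in result.frame_stats],
            "mean_nm": [s.mean_llt for s in result.frame_stats],
            "sd_nm": [s.sd_llt for s in result.frame_stats],
            "n_pixels": [s.n_pixels for s in result.frame_stats],
        }
    )
    stats.to_csv(out_dir / "stats.csv", index=False)

    hist = {
        "bin_edges_nm": result.frame_stats[0].bin_edges.tolist(),
        "sd_definition": "population (all pooled pixels)",
        "frames": [
            {"frame_index": s.frame_index, "time_s": s.time, "relative_frequency": s.histogram.tolist()}
            for s in result.frame_stats
        ],
        "pooled": {
            "mean_nm": result.summary.mean_llt,
            "sd_nm": result.summary.sd_llt,
            "n_pixels": result.summary.n_pixels,
        },
    }
    (out_dir / "histogram.json").write_text(json.dumps(hist, indent=1))

    for llt_map in result.maps:
        raster = np.where(
            np.isfinite(llt_map.thickness), llt_map.thickness, SENTINEL_NM
        ).astype(np.uint16)
        iio.imwrite(out_dir / f"llt_map_{llt_map.frame_index:04d}.tif", raster)

    if result.surface is not None:
        np.savetxt(
            out_dir / f"surface_{result.surface.frame_index:04d}.csv",
            np.where(np.isfinite(result.surface.grid), result.surface.grid, SENTINEL_NM),
            fmt="%g",
            delimiter=",",
        )
    if result.scatter is not None:
        scatter_df = pd.DataFrame(
            {
                "R": result.scatter.rgb[:, 0],
                "G": result.scatter.rgb[:, 1],
                "B": result.scatter.rgb[:, 2],
                "thickness_nm": result.scatter.thickness,
            }
        )
        scatter_df.to_csv(out_dir / "scatter.csv", index=False)

    result.selection_report.to_csv(out_dir / "frame_selection.csv", index=False)
    result.correction_report.to_csv(out_dir / "color_correction.csv", index=False)
    with (out_dir / "config.txt").open("w") as fh:
        for key, value in result.config.flat_dict().items():
            fh.write(f"{key}={value}\n")
    return out_dir
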