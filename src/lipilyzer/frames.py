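"""Phase 1: frame loading and blink rejection by global brightness.

During a blink the LED light reflects off the eyelid and the whole frame
brightens, so blink (and eye-closing) frames are separated from open-eye
frames with a single global-brightness threshold

    B_opened + c * (B_closed - B_opened),      c = 0.33 by default,

where ``B_opened`` is the mode of the per-frame mean-brightness series
over the analysis window and ``B_closed`` its maximum.  Frames above the
threshold are dropped.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Frame",
    "FrameSequence",
    "frame_brightness",
    "brightness_profile",
    "blink_threshold",
    "select_frames",
    "load_frames",
    "BrightnessProfile",
]

BLINK_COEF_DEFAULT = 0.33
#: sentinel threshold meaning "no blink evidence; keep every frame"
KEEP_ALL = float("inf")
#: smallest mode-to-maximum brightness gap counted as blink evidence; below
#: this the series is treated as blink-free (open-eye flicker, not eyelid
#: reflection) and every frame is kept
MIN_BLINK_GAP_DEFAULT = 5.0


def pixel_brightness(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel brightness (R+G+B)/3 of an ``(..., 3)`` 8-bit raster."""
    return np.asarray(pixels, dtype=float).sum(axis=-1) / 3.0


def pixel_luma(pixels: np.ndarray) -> np.ndarray:
    """Rec. 601 luma, an alternative per-pixel brightness weighting."""
    return np.asarray(pixels, dtype=float) @ np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Frame:
    """One 8-bit RGB video frame with its index and timestamp."""

    index: int
    time: float
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[-1] != 3 or px.shape[0] == 0 or px.shape[1] == 0:
            raise ValueError("pixels must be a nonempty HxWx3 raster")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


class FrameSequence(list):
    """A list of :class:`Frame` in temporal order."""

    def __init__(self, frames=(), fps: float = 30.0):
        super().__init__(frames)
        self.fps = float(fps)


def frame_brightness(frame: Frame | np.ndarray, method: str = "mean") -> float:
    """Mean brightness of a frame: average of (R+G+B)/3 over all pixels.

    ``method='luma'`` uses the Rec. 601 weighting instead of the channel
    mean.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if pixels.size == 0:
        raise ValueError("empty frame")
    weight = {"mean": pixel_brightness, "luma": pixel_luma}[method]
    return float(weight(pixels).mean())


@dataclass(frozen=True)
class BrightnessProfile:
    """Per-frame brightness series with the open/closed landmarks."""

    brightness: np.ndarray
    b_opened: float
    b_closed: float
    threshold: float = field(default=np.nan)


def _mode_integer(values: np.ndarray) -> float:
    """Mode of a near-continuous series on 256 unit-width integer bins.

    Brightness values are rounded to the nearest integer (bin centres
    0, 1, ..., 255) and the most frequent centre is returned; ties go to
    the smaller centre.
    """
    rounded = np.rint(np.asarray(values, dtype=float)).astype(int)
    counts = Counter(rounded.tolist())
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return float(best[0])


def brightness_profile(
    sequence: FrameSequence,
    c: float = BLINK_COEF_DEFAULT,
    min_gap: float = MIN_BLINK_GAP_DEFAULT,
) -> BrightnessProfile:
    """Brightness series, its mode/maximum landmarks and the blink threshold."""
    series = np.array([frame_brightness(f) for f in sequence], dtype=float)
    if series.size == 0:
        raise ValueError("empty frame sequence")
    b_opened = _mode_integer(series)
    b_closed = float(series.max())
    profile = BrightnessProfile(series, b_opened, b_closed)
    return BrightnessProfile(
        series, b_opened, b_closed, blink_threshold(profile, c, min_gap)
    )


def blink_threshold(
    profile: BrightnessProfile,
    c: float = BLINK_COEF_DEFAULT,
    min_gap: float = MIN_BLINK_GAP_DEFAULT,
) -> float:
    """Blink-rejection threshold ``B_opened + c * (B_closed - B_opened)``.

    Returns the keep-all sentinel (+inf) when the series carries no blink
    evidence: a constant series, or a mode-to-maximum gap no larger than
    ``min_gap`` (ordinary open-eye brightness flicker).
    """
    if profile.b_closed - profile.b_opened <= min_gap:
        return KEEP_ALL
    return profile.b_opened + c * (profile.b_closed - profile.b_opened)


def select_frames(
    sequence: FrameSequence,
    c: float = BLINK_COEF_DEFAULT,
    min_gap: float = MIN_BLINK_GAP_DEFAULT,
) -> tuple[FrameSequence, "pd.DataFrame"]:
    """Drop blink frames; return the retained sequence and a per-frame report.

    Frames with mean brightness <= threshold are retained in order with
    their original indices and timestamps.  Raises if every frame is
    rejected.
    """
    import pandas as pd

    if len(sequence) == 0:
        raise ValueError("empty frame sequence")
    profile = brightness_profile(sequence, c, min_gap)
    kept = profile.brightness <= profile.threshold
    report = pd.DataFrame(
        {
            "frame_index": [f.index for f in sequence],
            "time_s": [f.time for f in sequence],
            "brightness": profile.brightness,
            "kept": kept,
            "reason": np.where(kept, "", "blink"),
        }
    )
    retained = FrameSequence(
        (f for f, keep in zip(sequence, kept) if keep), fps=sequence.fps
    )
    if len(retained) == 0:
        raise ValueError("no usable frames: every frame exceeds the blink threshold")
    return retained, report


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(path: Path) -> tuple:
    return tuple(int(tok) if tok.isdigit() else tok for tok in _NUM_RE.split(path.stem))


def load_frames(source: str | Path, fps: float = 30.0) -> FrameSequence:
    """Load a frame sequence from a directory of numbered images or a video file.

    A directory is read as sequentially numbered PNG/TIFF frames (natural
    sort on the digits in the file names).  Anything else is handed to
    imageio; reading a video container requires an ffmpeg-capable imageio
    plugin to be installed.
    """
    source = Path(source)
    frames = FrameSequence(fps=fps)
    if source.is_dir():
        paths = sorted(
            (p for p in source.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}),
            key=_numeric_key,
        )
        if not paths:
            raise FileNotFoundError(f"no PNG/TIFF frames found in {source}")
        for i, path in enumerate(paths):
            pixels = np.asarray(iio.imread(path))[..., :3]
            frames.append(Frame(index=i, time=i / fps, pixels=pixels))
        return frames
    try:
        stack = iio.imread(source, index=None)
    except Exception as exc:  # pragma: no cover - depends on installed plugins
        raise RuntimeError(
            f"could not read {source} as a video container; install an "
            "ffmpeg-capable imageio plugin or supply a directory of frames"
        ) from exc
    for i, pixels in enumerate(np.asarray(stack)):
        frames.append(Frame(index=i, time=i / fps, pixels=np.asarray(pixels)[..., :3]))
    return frames
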