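"""Ground-truth-labelled synthetic eye videos for exercising the pipeline.

Frames are composited directly from the scene description — bright
sclera, textured iris disk, dark pupil, an inferior-iris band coloured
through a thickness->RGB table, optional eyelid occluders, eyelash
streaks and blink frames — then tinted by per-channel illumination
gains, perturbed with sensor noise and quantized to 8 bits.  The
compositing shares no code with the analysis pipeline, so pipeline tests
against the labels are not self-confirming.

The stored colour of a band pixel is ``gains * (iris_color + lut(d))``;
the sclera is pure white before the tint.  Running the analysis pipeline
(iris subtraction, then sclera-referenced white balance) on such a frame
therefore recovers the table colours up to quantization, which is the
round-trip property the correction stage is tested on.

Geometry is scaled to the acquisition described for the instrument: an
iris diameter of ~480 px on 640x800 frames at 30 frames/s, 75-frame
(2.5 s) analysis windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .frames import Frame, FrameSequence
from .lut import ColorLUT

__all__ = [
    "SceneSpec",
    "constant_field",
    "vertical_gradient_field",
    "patchy_field",
    "render_frame",
    "render_video",
    "write_video",
    "preset",
    "PRESETS",
]

ThicknessField = Callable[[np.ndarray, np.ndarray], np.ndarray]


def constant_field(mu: float) -> ThicknessField:
    """Uniform lipid layer of ``mu`` nm."""

    def f(drow: np.ndarray, dcol: np.ndarray) -> np.ndarray:
        return np.full(np.broadcast(drow, dcol).shape, float(mu))

    f.description = f"constant:{mu:g}"
    return f


def vertical_gradient_field(lo: float, hi: float, extent: float) -> ThicknessField:
    """Thickness rising linearly from ``lo`` at the eye centre row to ``hi``
    at ``extent`` pixels below it (thicker toward the lower eyelid)."""

    def f(drow: np.ndarray, dcol: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(drow, dtype=float) / extent, 0.0, 1.0)
        return lo + (hi - lo) * t

    f.description = f"vertical_gradient:{lo:g}-{hi:g}"
    return f


def patchy_field(
    mu: float, amplitude: float, scale: float, seed: int = 0
) -> ThicknessField:
    """Smooth pseudo-random patches of thickness around ``mu`` nm."""
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=(4, 3))

    def f(drow: np.ndarray, dcol: np.ndarray) -> np.ndarray:
        drow = np.asarray(drow, dtype=float)
        dcol = np.asarray(dcol, dtype=float)
        out = np.full(np.broadcast(drow, dcol).shape, float(mu))
        for k, (p1, p2, p3) in enumerate(phases, start=1):
            out = out + (amplitude / k) * np.sin(
                k * drow / scale + p1
            ) * np.cos(k * dcol / scale + p2 + p3)
        return np.clip(out, 0.0, 240.0)

    f.description = f"patchy:{mu:g}"
    return f


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic eye video."""

    shape: tuple[int, int] = (640, 800)
    eye_path: Sequence[tuple[int, int]] = ((320, 400),)
    pupil_radius: float = 80.0
    iris_radius: float = 240.0
    iris_color: tuple[float, float, float] = (60.0, 40.0, 30.0)
    iris_texture_sigma: float = 4.0
    sclera_color: tuple[float, float, float] = (255.0, 255.0, 255.0)
    pupil_color: tuple[float, float, float] = (8.0, 8.0, 8.0)
    thickness_field: ThicknessField = field(default_factory=lambda: constant_field(70.0))
    illumination_gains: tuple[float, float, float] = (0.75, 0.73, 0.70)
    blink_frames: frozenset = frozenset()
    blink_brightness: float = 150.0
    noise_sigma: float = 2.0
    eyelids: bool = False
    eyelid_gap: float = 0.9            # eyelid edge distance, x iris_radius
    eyelid_color: tuple[float, float, float] = (190.0, 150.0, 130.0)
    eyelashes: bool = False
    roi_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if not (self.pupil_radius < self.iris_radius < min(h, w) / 2):
            raise ValueError("need pupil_radius < iris_radius < min(H, W)/2")
        if any(g <= 0 for g in self.illumination_gains):
            raise ValueError("illumination gains must be positive")

    def center_at(self, frame_index: int) -> tuple[int, int]:
        path = list(self.eye_path)
        return path[min(frame_index, len(path) - 1)]


_texture_cache: dict = {}


def _texture(spec: SceneSpec) -> np.ndarray:
    """Eye-anchored scalar brightness texture, fixed for the whole video."""
    h, w = spec.shape
    key = (spec.seed, spec.shape, spec.iris_texture_sigma)
    if key not in _texture_cache:
        rng = np.random.default_rng(spec.seed)
        _texture_cache[key] = rng.normal(0.0, 1.0, size=(2 * h + 1, 2 * w + 1))
        if len(_texture_cache) > 8:
            _texture_cache.pop(next(iter(_texture_cache)))
    return _texture_cache[key] * spec.iris_texture_sigma


def _roi_region(
    spec: SceneSpec, drow: np.ndarray, dcol: np.ndarray, dist: np.ndarray
) -> np.ndarray:
    """The interference band: the geometric inferior-iris region."""
    inner = spec.roi_fraction * spec.iris_radius
    return (
        (dist <= inner)
        & (drow > 0)
        & (np.abs(dcol) <= spec.roi_fraction * inner)
        & (dist > spec.pupil_radius)
    )


def _eyelash_mask(spec: SceneSpec, drow: np.ndarray, dcol: np.ndarray) -> np.ndarray:
    """A few thin slanted dark streaks crossing the band from below."""
    mask = np.zeros(np.broadcast(drow, dcol).shape, dtype=bool)
    inner = spec.roi_fraction * spec.iris_radius
    for k, c0 in enumerate(np.linspace(-0.5 * inner, 0.5 * inner, 4)):
        slope = 0.35 * (-1) ** k
        line = np.abs(dcol - (c0 + slope * drow)) < 1.5
        mask |= line & (drow > 0.35 * inner) & (drow <= inner)
    return mask


def render_frame(
    spec: SceneSpec, frame_index: int, lut: ColorLUT, fps: float = 30.0
) -> tuple[Frame, dict]:
    """Composite one frame; returns the frame and its ground-truth labels.

    Labels: true eye centre, pupil/iris radius, boolean pupil and ROI
    masks, the per-pixel true thickness over the ROI (NaN elsewhere),
    and whether the frame is a blink.
    """
    h, w = spec.shape
    cr, cc = spec.center_at(frame_index)
    rr, cc_grid = np.ogrid[:h, :w]
    drow = rr - cr
    dcol = cc_grid - cc
    dist = np.sqrt(drow**2 + dcol**2)

    ideal = np.empty((h, w, 3), dtype=float)
    ideal[:] = spec.sclera_color

    iris = dist <= spec.iris_radius
    texture = _texture(spec)[drow + h, dcol + w]
    ideal[iris] = np.asarray(spec.iris_color) + texture[iris][:, None]

    band = _roi_region(spec, drow, dcol, dist)
    d_true = np.full((h, w), np.nan)
    d_true[band] = spec.thickness_field(
        np.broadcast_to(drow, (h, w))[band], np.broadcast_to(dcol, (h, w))[band]
    )
    band_colors = np.stack(
        [np.interp(d_true[band], lut.thickness_grid, lut.colors[:, ch]) for ch in range(3)],
        axis=-1,
    )
    ideal[band] = np.asarray(spec.iris_color) + band_colors

    pupil = dist <= spec.pupil_radius
    ideal[pupil] = spec.pupil_color

    if spec.eyelashes:
        lashes = _eyelash_mask(spec, np.broadcast_to(drow, (h, w)), np.broadcast_to(dcol, (h, w)))
        ideal[lashes & band] = (5.0, 5.0, 5.0)
        d_true[lashes & band] = np.nan

    if spec.eyelids:
        lid = spec.eyelid_gap * spec.iris_radius
        top = (rr < cr - lid) & np.ones((1, w), bool)
        bottom = (rr > cr + lid) & np.ones((1, w), bool)
        ideal[top | bottom] = spec.eyelid_color

    stored = ideal * np.asarray(spec.illumination_gains)
    blink = frame_index in spec.blink_frames
    if blink:
        stored = stored + spec.blink_brightness
    if spec.noise_sigma > 0:
        rng = np.random.default_rng((spec.seed * 100003 + frame_index) % (2**31))
        stored = stored + rng.normal(0.0, spec.noise_sigma, size=stored.shape)
    pixels = np.clip(np.rint(stored), 0, 255).astype(np.uint8)

    labels = {
        "frame_index": frame_index,
        "eye_center": (float(cr), float(cc)),
        "pupil_radius": spec.pupil_radius,
        "iris_radius": spec.iris_radius,
        "pupil_mask": pupil & np.ones((h, w), bool),
        "roi_mask": band if not spec.eyelashes else band & ~lashes,
        "thickness": d_true,
        "blink": blink,
        "illumination_gains": tuple(spec.illumination_gains),
        "iris_color": tuple(spec.iris_color),
    }
    return Frame(index=frame_index, time=frame_index / fps, pixels=pixels), labels


def render_video(
    spec: SceneSpec, n_frames: int, lut: ColorLUT, fps: float = 30.0
) -> tuple[FrameSequence, list[dict]]:
    """Render ``n_frames`` frames along the scene's eye path."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames = FrameSequence(fps=fps)
    labels = []
    for i in range(n_frames):
        frame, lab = render_frame(spec, i, lut, fps=fps)
        frames.append(frame)
        labels.append(lab)
    return frames, labels


def write_video(
    frames: FrameSequence, labels: list[dict], out_dir: str | Path
) -> Path:
    """Write PNG frames plus a JSON label file (masks summarized as counts)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    serializable = []
    for frame, lab in zip(frames, labels):
        iio.imwrite(out_dir / f"frame_{frame.index:04d}.png", frame.pixels)
        thickness = lab["thickness"]
        finite = thickness[np.isfinite(thickness)]
        serializable.append(
            {
                "frame_index": lab["frame_index"],
                "time_s": frame.time,
                "eye_center": list(lab["eye_center"]),
                "pupil_radius": lab["pupil_radius"],
                "iris_radius": lab["iris_radius"],
                "blink": bool(lab["blink"]),
                "roi_pixels": int(lab["roi_mask"].sum()),
                "mean_true_llt_nm": float(finite.mean()) if finite.size else None,
                "illumination_gains": list(lab["illumination_gains"]),
                "iris_color": list(lab["iris_color"]),
            }
        )
    (out_dir / "labels.json").write_text(json.dumps(serializable, indent=1))
    return out_dir


def _random_walk_path(
    n: int, start: tuple[int, int], bounds: tuple[int, int], max_step: int, seed: int
) -> tuple[tuple[int, int], ...]:
    rng = np.random.default_rng(seed)
    h, w = bounds
    pos = np.array(start, dtype=int)
    # keep the whole inferior-iris band inside the frame while wandering
    lo = (h // 2 - 70, w // 2 - 80)
    hi = (h // 2 + 70, w // 2 + 80)
    path = [tuple(pos)]
    for _ in range(n - 1):
        step = rng.integers(-max_step, max_step + 1, size=2)
        pos = np.clip(pos + step, lo, hi)
        path.append((int(pos[0]), int(pos[1])))
    return tuple(path)


def preset(name: str, seed: int = 0, n_frames: int = 75) -> SceneSpec:
    """Named study conditions.

    ``patient1``/``patient2``/``patient3``: stationary eye with constant
    true thickness 45 / 70 / 95 nm and sensor noise sigma 3, mirroring
    the thin / intermediate / thick ordering of hyposecretory MGD, dry
    eye without MGD and hypersecretory MGD.  ``blinky``: five 3-frame
    blink bursts.  ``moving``: eye translating up to 10 px/frame with
    eyelid occluders and eyelash streaks.  ``gradient``: thickness rising
    toward the lower eyelid.
    """
    base = SceneSpec(seed=seed)
    h, w = base.shape
    if name in {"patient1", "patient2", "patient3"}:
        mu = {"patient1": 45.0, "patient2": 70.0, "patient3": 95.0}[name]
        return replace(base, thickness_field=constant_field(mu), noise_sigma=3.0)
    if name == "blinky":
        bursts = []
        for start in (8, 22, 37, 52, 66):
            bursts.extend(range(start, start + 3))
        return replace(
            base,
            thickness_field=constant_field(70.0),
            blink_frames=frozenset(b for b in bursts if b < n_frames),
        )
    if name == "moving":
        path = _random_walk_path(n_frames, (h // 2, w // 2), (h, w), 10, seed + 17)
        return replace(
            base,
            eye_path=path,
            thickness_field=constant_field(70.0),
            eyelids=True,
            eyelashes=True,
        )
    if name == "gradient":
        return replace(
            base,
            thickness_field=vertical_gradient_field(
                40.0, 110.0, base.roi_fraction * base.iris_radius
            ),
            noise_sigma=3.0,
        )
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("patient1", "patient2", "patient3", "blinky", "moving", "gradient")
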