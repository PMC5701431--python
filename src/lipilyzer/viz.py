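"""Debug overlays: the per-frame geometry drawn back onto the frame."""

from __future__ import annotations

import numpy as np

from .frames import Frame
from .geometry import EyeGeometry, ROIMask

__all__ = ["render_overlay"]


def render_overlay(
    frame: Frame, geometry: EyeGeometry, roi: ROIMask | None = None
) -> np.ndarray:
    """Frame with seed dot, pupil boundary, centroid, iris circle and ROI tint.

    Returns an HxWx3 uint8 image suitable for PNG export.
    """
    out = frame.pixels.astype(float).copy()
    h, w = out.shape[:2]
    rr, cc = np.ogrid[:h, :w]

    if roi is not None:  # green tint over the ROI
        out[roi.mask] = 0.6 * out[roi.mask] + 0.4 * np.array([0.0, 255.0, 0.0])

    edge = geometry.pupil_mask ^ np.roll(geometry.pupil_mask, 1, axis=0)
    edge |= geometry.pupil_mask ^ np.roll(geometry.pupil_mask, 1, axis=1)
    out[edge] = (255.0, 0.0, 0.0)

    er, ec = geometry.eye_center
    ring = np.abs(np.hypot(rr - er, cc - ec) - geometry.iris_radius) < 1.5
    out[ring] = (255.0, 255.0, 0.0)

    sr, sc = geometry.darkest_seed
    out[max(sr - 3, 0) : sr + 4, max(sc - 3, 0) : sc + 4] = (255.0, 255.0, 255.0)
    pr, pc = (int(round(v)) for v in geometry.pupil_centroid)
    out[max(pr - 3, 0) : pr + 4, max(pc - 3, 0) : pc + 4] = (255.0, 0.0, 0.0)
    return np.clip(out, 0, 255).astype(np.uint8)
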