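"""Thickness -> colour lookup table and its nearest-colour inversion.

The table tabulates, for every thickness on a 0-240 nm grid, the 8-bit
RGB colour the interference model predicts under the chosen illuminant
and observer.  Thickness is later assigned to an image pixel as the grid
value whose table colour is closest in Euclidean RGB distance, ties going
to the smaller (more conservative) thickness.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .colorimetry import Illuminant, ObserverCMF, spectrum_to_rgb
from .optics import (
    MAX_ORDERS_DEFAULT,
    TRUNCATION_TOL_DEFAULT,
    OpticalStack,
    reflection_spectrum,
)

__all__ = ["ColorLUT", "build_lut", "srgb_encode"]


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """sRGB transfer curve on [0, 1] values (the display gamma of 8-bit camera output)."""
    linear = np.asarray(linear, dtype=float)
    lo = linear <= 0.0031308
    out = np.where(lo, 12.92 * linear, 1.055 * np.clip(linear, 1e-12, None) ** (1 / 2.4) - 0.055)
    return out


@dataclass(frozen=True)
class ColorLUT:
    """Ordered thickness grid (nm) with one 8-bit RGB triple per entry."""

    thickness_grid: np.ndarray
    colors: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.thickness_grid, dtype=float)
        colors = np.asarray(self.colors, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("thickness grid must be a nonempty 1-D array")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("thickness grid must be strictly increasing")
        if colors.shape != (grid.size, 3):
            raise ValueError("colors must have shape (len(grid), 3)")
        if colors.min() < 0 or colors.max() > 255:
            raise ValueError("colour channels must lie in [0, 255]")
        object.__setattr__(self, "thickness_grid", grid)
        object.__setattr__(self, "colors", colors)

    def __len__(self) -> int:
        return self.thickness_grid.size

    def color_for(self, thickness: float) -> np.ndarray:
        """Table colour at the grid entry nearest to ``thickness``."""
        i = int(np.argmin(np.abs(self.thickness_grid - thickness)))
        return self.colors[i]

    def nearest(self, rgb: np.ndarray) -> np.ndarray:
        """Nearest-colour thickness assignment for ``(..., 3)`` RGB data.

        Returns the grid thickness minimizing Euclidean distance in RGB
        space; exact ties resolve to the smaller thickness because the
        grid is ascending and ``argmin`` keeps the first minimum.
        """
        rgb = np.asarray(rgb, dtype=float)
        flat = rgb.reshape(-1, 3)
        # squared distances via (a-b)^2 expansion, blockwise to bound memory
        out = np.empty(flat.shape[0], dtype=float)
        lut_sq = np.einsum("ij,ij->i", self.colors, self.colors)
        for start in range(0, flat.shape[0], 65536):
            block = flat[start : start + 65536]
            d2 = lut_sq[None, :] - 2.0 * block @ self.colors.T
            out[start : start + 65536] = self.thickness_grid[np.argmin(d2, axis=1)]
        return out.reshape(rgb.shape[:-1])

    # -- plain-text persistence ------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write ``thickness_nm,R,G,B`` CSV plus a ``# key=value`` config header."""
        path = Path(path)
        with path.open("w") as fh:
            for key, value in sorted(self.meta.items()):
                fh.write(f"# {key}={value}\n")
            fh.write("thickness_nm,R,G,B\n")
            for d, (r, g, b) in zip(self.thickness_grid, self.colors):
                fh.write(f"{d:g},{int(round(r))},{int(round(g))},{int(round(b))}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ColorLUT":
        meta: dict = {}
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            if line.lower().startswith("thickness"):
                continue
            rows.append([float(tok) for tok in line.split(",")])
        arr = np.asarray(rows, dtype=float)
        if arr.size == 0:
            raise ValueError(f"no table rows found in {path}")
        return cls(arr[:, 0], arr[:, 1:4], meta=meta)


def build_lut(
    stack: OpticalStack | None = None,
    observer: ObserverCMF | None = None,
    illuminant: Illuminant | None = None,
    thickness_grid: np.ndarray | None = None,
    *,
    gamma: bool = True,
    signed_amplitudes: bool = True,
    truncation_tol: float = TRUNCATION_TOL_DEFAULT,
    max_orders: int = MAX_ORDERS_DEFAULT,
) -> ColorLUT:
    """Build the thickness -> RGB table from the interference model.

    For every thickness on the grid (default 0..240 nm in 1 nm steps) the
    unpolarized reflection spectrum is integrated against the illuminant
    (default 6500 K blackbody) and observer (default CIE 1964 10-degree),
    the resulting linear RGB curve is scaled by one global gain so its
    maximum channel value is 255, and by default the sRGB transfer curve
    is applied, since camera output is gamma-encoded 8-bit.

    ``signed_amplitudes`` defaults to True: the physical half-wave phase
    shifts make a vanishing film dark, which matches the observed colour
    scale (the d=0 entry is the darkest of the table).
    """
    stack = stack or OpticalStack()
    observer = observer or ObserverCMF.cie1964()
    illuminant = illuminant or Illuminant.blackbody(6500.0, observer.wavelengths)
    if thickness_grid is None:
        thickness_grid = np.arange(0.0, 241.0)
    thickness_grid = np.asarray(thickness_grid, dtype=float)
    if thickness_grid.size == 0:
        raise ValueError("thickness grid is empty")

    spectra = np.stack(
        [
            reflection_spectrum(
                stack,
                observer.wavelengths,
                d,
                signed_amplitudes=signed_amplitudes,
                truncation_tol=truncation_tol,
                max_orders=max_orders,
            )
            for d in thickness_grid
        ]
    )
    linear = spectrum_to_rgb(spectra, observer, illuminant)
    peak = linear.max()
    if peak <= 0:
        raise ValueError("interference colours are identically zero")
    scaled = linear / peak
    encoded = srgb_encode(scaled) if gamma else scaled
    # keep full precision on the 8-bit scale: rounding to integers merges
    # neighbouring 1-nm entries and breaks exact nearest-colour inversion
    colors = np.clip(encoded * 255.0, 0.0, 255.0)
    meta = {
        "n_air": stack.n_air,
        "n_lipid": stack.n_lipid,
        "n_tear": stack.n_tear,
        "incidence_angle_rad": stack.incidence_angle,
        "gamma": "srgb" if gamma else "none",
        "signed_amplitudes": signed_amplitudes,
        "grid_nm": f"{thickness_grid[0]:g}:{thickness_grid[-1]:g}:{len(thickness_grid)}",
    }
    return ColorLUT(thickness_grid, colors, meta=meta)
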