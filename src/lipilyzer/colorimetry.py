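"""Colorimetry: spectra to RGB through the CIE 1964 10-degree observer.

The interference spectrum computed by :mod:`lipilyzer.optics` is turned
into an RGB triple by weighting it with an illuminant spectrum and the
observer's colour-matching functions and summing over wavelength:

    Red(d)   = sum_lambda I(lambda, d) * S(lambda) * r_bar(lambda)
    Green(d) = sum_lambda I(lambda, d) * S(lambda) * g_bar(lambda)
    Blue(d)  = sum_lambda I(lambda, d) * S(lambda) * b_bar(lambda)

over the 360-830 nm range of the CIE 1964 standard observer.

The x/y/z colour-matching functions are evaluated from the single-lobe
Gaussian analytic approximations of Wyman, Sloan & Shirley (JCGT 2013),
which track the tabulated 10-degree observer to a few percent, and are
mapped to RGB colour-matching weights with the fixed linear sRGB
XYZ->RGB matrix.  Tabulated CMFs can be substituted via
:meth:`ObserverCMF.from_table`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Illuminant",
    "ObserverCMF",
    "spectrum_to_rgb",
    "cie1964_xyz",
    "blackbody_spectrum",
    "WAVELENGTH_MIN",
    "WAVELENGTH_MAX",
]

WAVELENGTH_MIN = 360.0
WAVELENGTH_MAX = 830.0

# linear sRGB primaries, D65 white (IEC 61966-2-1)
XYZ_TO_RGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


def cie1964_xyz(wavelengths: np.ndarray) -> np.ndarray:
    """CIE 1964 10-degree colour-matching functions, shape ``(n, 3)``.

    Analytic single-lobe Gaussian fits (Wyman, Sloan & Shirley 2013).
    """
    lam = np.asarray(wavelengths, dtype=float)
    x = 0.398 * np.exp(-1250.0 * np.log((lam + 570.1) / 1014.0) ** 2) + 1.132 * np.exp(
        -234.0 * np.log((1338.0 - lam) / 743.5) ** 2
    )
    y = 1.011 * np.exp(-0.5 * ((lam - 556.1) / 46.14) ** 2)
    z = 2.060 * np.exp(-32.0 * np.log((lam - 265.8) / 180.4) ** 2)
    return np.stack([x, y, z], axis=-1)


def blackbody_spectrum(wavelengths: np.ndarray, temperature: float = 6500.0) -> np.ndarray:
    """Planck blackbody spectral radiance on a nm grid, normalized to max 1."""
    lam_m = np.asarray(wavelengths, dtype=float) * 1e-9
    h, c, k = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    power = lam_m**-5 / np.expm1(h * c / (lam_m * k * temperature))
    return power / power.max()


@dataclass(frozen=True)
class Illuminant:
    """Relative spectral power distribution on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    relative_power: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        pw = np.asarray(self.relative_power, dtype=float)
        if lam.ndim != 1 or lam.shape != pw.shape:
            raise ValueError("wavelengths and relative_power must be matching 1-D arrays")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if lam[0] < WAVELENGTH_MIN - 1e-9 or lam[-1] > WAVELENGTH_MAX + 1e-9:
            raise ValueError("wavelengths must lie within [360, 830] nm")
        if np.any(pw < 0) or not np.any(pw > 0):
            raise ValueError("spectral power must be nonnegative with at least one positive entry")
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "relative_power", pw)

    @classmethod
    def blackbody(
        cls,
        temperature: float = 6500.0,
        wavelengths: np.ndarray | None = None,
    ) -> "Illuminant":
        """Blackbody illuminant, default 6500 K on a 1 nm grid (white LED proxy)."""
        if wavelengths is None:
            wavelengths = np.arange(WAVELENGTH_MIN, WAVELENGTH_MAX + 1.0)
        return cls(wavelengths, blackbody_spectrum(wavelengths, temperature))

    @classmethod
    def equal_energy(cls, wavelengths: np.ndarray | None = None) -> "Illuminant":
        if wavelengths is None:
            wavelengths = np.arange(WAVELENGTH_MIN, WAVELENGTH_MAX + 1.0)
        wavelengths = np.asarray(wavelengths, dtype=float)
        return cls(wavelengths, np.ones_like(wavelengths))


@dataclass(frozen=True)
class ObserverCMF:
    """RGB colour-matching weights ``r_bar, g_bar, b_bar`` on a nm grid."""

    wavelengths: np.ndarray
    r_bar: np.ndarray
    g_bar: np.ndarray
    b_bar: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        bars = [np.asarray(b, dtype=float) for b in (self.r_bar, self.g_bar, self.b_bar)]
        for b in bars:
            if b.shape != lam.shape:
                raise ValueError("colour-matching arrays must match the wavelength grid")
            if not np.all(np.isfinite(b)):
                raise ValueError("colour-matching values must be finite")
        object.__setattr__(self, "wavelengths", lam)
        for name, b in zip(("r_bar", "g_bar", "b_bar"), bars):
            object.__setattr__(self, name, b)

    @classmethod
    def cie1964(cls, wavelengths: np.ndarray | None = None) -> "ObserverCMF":
        """CIE 1964 10-degree observer expressed as RGB matching weights."""
        if wavelengths is None:
            wavelengths = np.arange(WAVELENGTH_MIN, WAVELENGTH_MAX + 1.0)
        xyz = cie1964_xyz(wavelengths)
        rgb = xyz @ XYZ_TO_RGB.T
        return cls(wavelengths, rgb[:, 0], rgb[:, 1], rgb[:, 2])

    @classmethod
    def from_table(
        cls, wavelengths: np.ndarray, xyz: np.ndarray, matrix: np.ndarray = XYZ_TO_RGB
    ) -> "ObserverCMF":
        """Build from tabulated XYZ colour-matching functions, shape ``(n, 3)``."""
        rgb = np.asarray(xyz, dtype=float) @ np.asarray(matrix, dtype=float).T
        return cls(np.asarray(wavelengths, dtype=float), rgb[:, 0], rgb[:, 1], rgb[:, 2])

    def as_matrix(self) -> np.ndarray:
        return np.stack([self.r_bar, self.g_bar, self.b_bar], axis=-1)


def spectrum_to_rgb(
    intensities: np.ndarray,
    observer: ObserverCMF,
    illuminant: Illuminant,
) -> np.ndarray:
    """Integrate a spectrum (or stack of spectra) to linear RGB.

    ``intensities`` has the wavelength grid on its last axis and must share
    it with both the observer and the illuminant.  Each channel is the sum
    over wavelength of intensity x illuminant weight x matching function;
    negative channel sums (possible only for near-monochromatic spectra,
    where the RGB matching weights go negative) are clipped to zero.
    """
    intensities = np.asarray(intensities, dtype=float)
    if not np.array_equal(observer.wavelengths, illuminant.wavelengths):
        raise ValueError("observer and illuminant wavelength grids differ")
    if intensities.shape[-1] != observer.wavelengths.shape[0]:
        raise ValueError("spectrum length does not match the wavelength grid")
    weighted = intensities * illuminant.relative_power
    rgb = weighted @ observer.as_matrix()
    return np.clip(rgb, 0.0, None)
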