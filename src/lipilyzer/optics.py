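"""Thin-film interference model for the tear-film lipid layer.

The precorneal tear film is modelled as a single homogeneous lipid slab
(refractive index ``n_lipid``) sandwiched between air and the aqueous
layer.  White light reflected at the air–lipid and lipid–aqueous
interfaces interferes; the resulting spectral reflectance, and hence the
perceived colour, depends on the lipid thickness ``d``.

The model is a simple reflection–transmission ray picture: ray ``m`` has
bounced ``m`` times inside the slab, its intensity follows from the
Fresnel reflectance/transmittance of the two interfaces, and its phase is
``m`` times the single-pass phase difference ``2*pi*OPD/lambda`` with
``OPD = 2 * n_lipid * d * cos(beta)``.  The rays are summed coherently as
``sum_m sqrt(I_m) * exp(i*m*delta)``.

Two sign conventions are exposed.  The default (``signed_amplitudes
=False``) carries only the intensity magnitudes, so ``d = 0`` is the
in-phase maximum of the sum.  With ``signed_amplitudes=True`` each ray
keeps the sign of its product of Fresnel amplitude coefficients; because
the lipid index exceeds the aqueous index the two leading rays then
interfere destructively at ``d = 0`` and a vanishing film is dark, which
is the behaviour of the physical film and of the colour table used for
thickness inversion (see :mod:`lipilyzer.lut`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalStack",
    "InterferenceResult",
    "snell_refraction_angle",
    "optical_path_difference",
    "phase_difference",
    "fresnel_amplitudes",
    "reflectance_transmittance",
    "multibeam_intensities",
    "interfere",
]

#: default refractive indices (dimensionless): air, meibum, aqueous tear layer
N_AIR_DEFAULT = 1.000
N_LIPID_DEFAULT = 1.48
N_TEAR_DEFAULT = 1.337


class TotalInternalReflectionError(ValueError):
    """Raised when Snell's law has no real solution for the refraction angle."""


@dataclass(frozen=True)
class OpticalStack:
    """Air / lipid / tear three-layer stack with a fixed incidence angle.

    Parameters
    ----------
    n_air, n_lipid, n_tear
        Refractive indices of the three media.  All must be >= 1.
    incidence_angle
        Angle of incidence in air, radians, in ``[0, pi/2)``.  The default
        is normal incidence.
    """

    n_air: float = N_AIR_DEFAULT
    n_lipid: float = N_LIPID_DEFAULT
    n_tear: float = N_TEAR_DEFAULT
    incidence_angle: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_air", "n_lipid", "n_tear"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.incidence_angle < math.pi / 2:
            raise ValueError("incidence_angle must lie in [0, pi/2)")

    def index(self, layer: str) -> float:
        try:
            return {"air": self.n_air, "lipid": self.n_lipid, "tear": self.n_tear}[layer]
        except KeyError:
            raise ValueError(f"unknown layer {layer!r}") from None

    @property
    def refraction_angle_lipid(self) -> float:
        """Propagation angle beta inside the lipid layer (radians)."""
        return snell_refraction_angle(self, "air", "lipid")


_ADJACENT = {("air", "lipid"), ("lipid", "air"), ("lipid", "tear"), ("tear", "lipid")}


def snell_refraction_angle(stack: OpticalStack, from_layer: str, to_layer: str) -> float:
    """Refraction angle when crossing from one layer into an adjacent one.

    The angle in the ``from`` layer is derived by tracing the stack's
    incidence angle down from air; the returned angle satisfies
    ``n_in * sin(theta_in) == n_out * sin(theta_out)``.
    """
    if (from_layer, to_layer) not in _ADJACENT:
        raise ValueError(f"layers {from_layer!r} -> {to_layer!r} are not adjacent")
    n_in = stack.index(from_layer)
    n_out = stack.index(to_layer)
    # angle in any layer follows from the invariant n*sin(theta) = n_air*sin(theta1)
    sin_in = stack.n_air * math.sin(stack.incidence_angle) / n_in
    sin_out = n_in * sin_in / n_out
    if sin_out > 1.0:
        raise TotalInternalReflectionError(
            f"total internal reflection crossing {from_layer} -> {to_layer}"
        )
    return math.asin(sin_out)


def optical_path_difference(stack: OpticalStack, d: float) -> float:
    """Optical path difference ``2 * n_lipid * d * cos(beta)`` in nm.

    ``d`` is the lipid layer thickness in nm and ``beta`` the refraction
    angle inside the lipid.
    """
    if d < 0:
        raise ValueError("thickness d must be >= 0")
    beta = stack.refraction_angle_lipid
    return 2.0 * stack.n_lipid * d * math.cos(beta)


def phase_difference(opd: float, wavelength: float) -> float:
    """Phase difference ``2*pi*OPD/lambda`` between successive rays (radians)."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return 2.0 * math.pi * opd / wavelength


def _cos_refracted(n_i: float, n_j: float, theta_i: float) -> tuple[float, float]:
    sin_j = n_i * math.sin(theta_i) / n_j
    if sin_j > 1.0:
        raise TotalInternalReflectionError("total internal reflection at interface")
    return math.cos(theta_i), math.sqrt(1.0 - sin_j * sin_j)


def fresnel_amplitudes(
    n_i: float, n_j: float, theta_i: float
) -> tuple[float, float, float, float]:
    """Fresnel amplitude coefficients ``(r_s, t_s, r_p, t_p)`` at one interface.

    ``theta_i`` is the angle of incidence in medium ``i``; the refraction
    angle in medium ``j`` follows from Snell's law.
    """
    cos_i, cos_j = _cos_refracted(n_i, n_j, theta_i)
    r_s = (n_i * cos_i - n_j * cos_j) / (n_i * cos_i + n_j * cos_j)
    t_s = 2.0 * n_i * cos_i / (n_i * cos_i + n_j * cos_j)
    r_p = (n_j * cos_i - n_i * cos_j) / (n_j * cos_i + n_i * cos_j)
    t_p = 2.0 * n_i * cos_i / (n_i * cos_j + n_j * cos_i)
    return r_s, t_s, r_p, t_p


def reflectance_transmittance(
    n_i: float, n_j: float, theta_i: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Energy reflectance and transmittance ``((R_s, T_s), (R_p, T_p))``.

    ``R = |r|**2`` and ``T = (n_j cos(theta_j))/(n_i cos(theta_i)) |t|**2``;
    for a lossless dielectric interface ``R + T == 1`` per polarization.
    """
    cos_i, cos_j = _cos_refracted(n_i, n_j, theta_i)
    r_s, t_s, r_p, t_p = fresnel_amplitudes(n_i, n_j, theta_i)
    geom = (n_j * cos_j) / (n_i * cos_i)
    return (r_s * r_s, geom * t_s * t_s), (r_p * r_p, geom * t_p * t_p)


#: stop summing reflection orders once I_m / I_incident drops below this
TRUNCATION_TOL_DEFAULT = 1e-9
MAX_ORDERS_DEFAULT = 50


@dataclass(frozen=True)
class _InterfaceSet:
    """Per-polarization energy coefficients of the three relevant interfaces."""

    R12: float
    T12: float
    R21: float
    T21: float
    R23: float
    sign0: float   # sign of r12
    sign1: float   # sign of t12 * r23 * t21 (and of every later ray: r21*r23 > 0)

    @property
    def bounce_ratio(self) -> float:
        return self.R21 * self.R23


def _interfaces(stack: OpticalStack, polarization: str) -> _InterfaceSet:
    idx = {"s": 0, "p": 1}[polarization]
    theta1 = stack.incidence_angle
    theta2 = snell_refraction_angle(stack, "air", "lipid")
    amp12 = fresnel_amplitudes(stack.n_air, stack.n_lipid, theta1)
    amp21 = fresnel_amplitudes(stack.n_lipid, stack.n_air, theta2)
    amp23 = fresnel_amplitudes(stack.n_lipid, stack.n_tear, theta2)
    r12, t12 = amp12[2 * idx], amp12[2 * idx + 1]
    r21, t21 = amp21[2 * idx], amp21[2 * idx + 1]
    r23 = amp23[2 * idx]
    rt12 = reflectance_transmittance(stack.n_air, stack.n_lipid, theta1)[idx]
    rt21 = reflectance_transmittance(stack.n_lipid, stack.n_air, theta2)[idx]
    rt23 = reflectance_transmittance(stack.n_lipid, stack.n_tear, theta2)[idx]
    return _InterfaceSet(
        R12=rt12[0],
        T12=rt12[1],
        R21=rt21[0],
        T21=rt21[1],
        R23=rt23[0],
        sign0=math.copysign(1.0, r12) if r12 != 0 else 0.0,
        sign1=math.copysign(1.0, t12 * r23 * t21) if r23 != 0 else 0.0,
    )


def multibeam_intensities(
    stack: OpticalStack,
    wavelength: float,
    d: float,
    incident_intensity: float = 1.0,
    *,
    polarization: str = "s",
    truncation_tol: float = TRUNCATION_TOL_DEFAULT,
    max_orders: int = MAX_ORDERS_DEFAULT,
) -> list[tuple[float, float]]:
    """Intensities and phases ``(I_m, theta_m)`` of the reflected ray series.

    Ray 0 reflects directly off the air–lipid surface; ray ``m`` makes
    ``m`` round trips inside the film, so ``I_m = R21*R23*I_{m-1}`` for
    ``m > 1`` and ``theta_m = m * delta``.  The series is truncated when
    ``I_m / I_incident`` falls below ``truncation_tol`` or ``max_orders``
    rays have been emitted.
    """
    if d < 0:
        raise ValueError("thickness d must be >= 0")
    if incident_intensity <= 0:
        raise ValueError("incident intensity must be positive")
    iface = _interfaces(stack, polarization)
    if iface.bounce_ratio >= 1.0:
        raise ValueError("internal bounce ratio >= 1: series does not converge")
    delta = phase_difference(optical_path_difference(stack, d), wavelength)
    out = [(iface.R12 * incident_intensity, 0.0)]
    i_m = iface.T12 * iface.R23 * iface.T21 * incident_intensity
    m = 1
    while m < max_orders and i_m / incident_intensity >= truncation_tol:
        out.append((i_m, m * delta))
        i_m *= iface.bounce_ratio
        m += 1
    return out


@dataclass(frozen=True)
class InterferenceResult:
    """Coherent sum of the reflected ray series at one ``(wavelength, d)``."""

    wavelength: float
    thickness: float
    amplitude: complex
    intensity: float
    n_orders: int = field(default=0, compare=False)


def interfere(
    stack: OpticalStack,
    wavelength: float,
    d: float,
    incident_intensity: float = 1.0,
    *,
    polarization: str = "s",
    signed_amplitudes: bool = False,
    truncation_tol: float = TRUNCATION_TOL_DEFAULT,
    max_orders: int = MAX_ORDERS_DEFAULT,
) -> InterferenceResult:
    """Coherent interference of the reflected rays at one wavelength.

    The resultant is ``sum_m sqrt(I_m) * exp(i * theta_m)`` and the
    intensity its squared magnitude.  With ``signed_amplitudes=True`` each
    ``sqrt(I_m)`` additionally carries the sign of the ray's product of
    Fresnel amplitude coefficients (the physical half-wave phase shifts).
    """
    rays = multibeam_intensities(
        stack,
        wavelength,
        d,
        incident_intensity,
        polarization=polarization,
        truncation_tol=truncation_tol,
        max_orders=max_orders,
    )
    iface = _interfaces(stack, polarization)
    amp = 0j
    for m, (i_m, theta_m) in enumerate(rays):
        a = math.sqrt(abs(i_m))
        if signed_amplitudes:
            a *= iface.sign0 if m == 0 else iface.sign1
        amp += a * complex(math.cos(theta_m), math.sin(theta_m))
    return InterferenceResult(
        wavelength=wavelength,
        thickness=d,
        amplitude=amp,
        intensity=abs(amp) ** 2,
        n_orders=len(rays),
    )


def reflection_spectrum(
    stack: OpticalStack,
    wavelengths: np.ndarray,
    d: float,
    *,
    signed_amplitudes: bool = False,
    truncation_tol: float = TRUNCATION_TOL_DEFAULT,
    max_orders: int = MAX_ORDERS_DEFAULT,
) -> np.ndarray:
    """Unpolarized interference intensity over a wavelength grid.

    The incident LED light is unpolarized, so the s- and p-polarized
    intensities are computed independently and averaged.  Vectorized over
    wavelength; used by the colour-table builder.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if d < 0:
        raise ValueError("thickness d must be >= 0")
    opd = optical_path_difference(stack, d)
    delta = 2.0 * math.pi * opd / wavelengths
    total = np.zeros_like(wavelengths)
    for pol in ("s", "p"):
        iface = _interfaces(stack, pol)
        amp = np.zeros_like(wavelengths, dtype=complex)
        a0 = math.sqrt(iface.R12)
        if signed_amplitudes:
            a0 *= iface.sign0
        amp += a0
        i_m = iface.T12 * iface.R23 * iface.T21
        m = 1
        while m < max_orders and i_m >= truncation_tol:
            a_m = math.sqrt(i_m)
            if signed_amplitudes:
                a_m *= iface.sign1
            amp += a_m * np.exp(1j * m * delta)
            i_m *= iface.bounce_ratio
            m += 1
        total += np.abs(amp) ** 2
    return total / 2.0
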