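"""Voltage-dependent light scattering of a single polymer antenna.

The mushroom-shaped antenna (hemispherical cap on a cylindrical stem) is
reduced to a volume-equivalent homogeneous sphere in water and its scattering
cross section is evaluated with the full Mie series.  This surrogate keeps
the voltage -> doping -> permittivity -> scattering mechanism and all of its
monotone trends (bigger caps scatter more, dedoping brightens) while avoiding
a finite-element treatment of the layered substrate; absolute cross sections
therefore carry the surrogate's geometry error and should be read as trends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .permittivity import (
    ComplexPermittivitySpectrum,
    PermittivityModel,
    index_from_permittivity,
    voltage_to_doping,
)

__all__ = [
    "AntennaGeometry",
    "MediumOptics",
    "ScatteringSpectrum",
    "mie_efficiency",
    "mie_cross_section",
    "equivalent_sphere_radius",
    "scattering_spectrum_vs_bias",
    "scattering_vs_bias",
    "sensitivity_vs_bias",
    "wiscombe_order",
]

DEFAULT_BIAS_RANGE = (-0.8, 0.2)


@dataclass(frozen=True)
class AntennaGeometry:
    """Mushroom antenna dimensions in nm.

    The stem fills the opening etched in the silicon nitride passivation
    (250 nm diameter, 50 nm thick by default); the electrodeposited cap
    sits on top of it.
    """

    cap_diameter: float = 1000.0
    stem_diameter: float = 250.0
    stem_height: float = 50.0

    def __post_init__(self) -> None:
        if not self.stem_diameter > 0:
            raise ValueError("stem_diameter must be > 0")
        if self.cap_diameter < self.stem_diameter:
            raise ValueError("cap_diameter must be >= stem_diameter")
        if not self.stem_height > 0:
            raise ValueError("stem_height must be > 0")


@dataclass(frozen=True)
class MediumOptics:
    """Embedding medium; water has relative permittivity 1.77 in the visible."""

    eps_medium: float = 1.77

    def __post_init__(self) -> None:
        if not self.eps_medium > 0:
            raise ValueError("eps_medium must be > 0")

    @property
    def refractive_index(self) -> float:
        return float(np.sqrt(self.eps_medium))


@dataclass(frozen=True)
class ScatteringSpectrum:
    """Scattering cross section sigma_sc (nm^2) on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    sigma_sc: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        sig = np.asarray(self.sigma_sc, dtype=float)
        if wl.shape != sig.shape:
            raise ValueError("wavelengths and sigma_sc must share a shape")
        if np.any(sig < 0):
            raise ValueError("sigma_sc must be >= 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "sigma_sc", sig)


def wiscombe_order(x: float) -> int:
    """Standard series truncation order n_max = x + 4 x^(1/3) + 2."""
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_efficiency(x: float, m: complex, n_max: int | None = None) -> float:
    """Scattering efficiency Q_sca of a homogeneous sphere.

    Parameters
    ----------
    x:
        Size parameter 2*pi*n_medium*radius/lambda.
    m:
        Refractive index of the sphere relative to the (non-absorbing)
        medium; may be complex.
    n_max:
        Series truncation order; defaults to the Wiscombe criterion.

    Notes
    -----
    Mie coefficients a_n, b_n are built from the logarithmic derivative
    D_n(mx) computed by downward recurrence (numerically stable for
    absorbing spheres) and Riccati-Bessel functions psi_n, chi_n of the
    real argument x by upward recurrence.
    """
    if not np.isfinite(x) or x <= 0:
        raise ValueError("size parameter x must be finite and > 0")
    if not np.isfinite(m.real) or not np.isfinite(m.imag):
        raise ValueError("relative index m must be finite")
    if n_max is None:
        n_max = wiscombe_order(x)
    mx = m * x

    # Downward recurrence for D_n(mx), started well above n_max.
    n_start = n_max + max(16, int(np.ceil(1.5 * abs(mx) ** 0.5)) + 16)
    d = np.zeros(n_start + 1, dtype=complex)
    for n in range(n_start, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    # Riccati-Bessel psi, chi by upward recurrence in the real argument x.
    psi_nm1, psi_n = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_nm1, chi_n = -np.sin(x), np.cos(x)  # chi_{-1}, chi_0
    qsca = 0.0
    for n in range(1, n_max + 1):
        psi_np = (2 * n - 1) / x * psi_n - psi_nm1
        chi_np = (2 * n - 1) / x * chi_n - chi_nm1
        psi_nm1, psi_n = psi_n, psi_np
        chi_nm1, chi_n = chi_n, chi_np
        xi_n = psi_n - 1j * chi_n
        xi_nm1 = psi_nm1 - 1j * chi_nm1
        dn = d[n]
        a_n = ((dn / m + n / x) * psi_n - psi_nm1) / ((dn / m + n / x) * xi_n - xi_nm1)
        b_n = ((dn * m + n / x) * psi_n - psi_nm1) / ((dn * m + n / x) * xi_n - xi_nm1)
        qsca += (2 * n + 1) * (abs(a_n) ** 2 + abs(b_n) ** 2)
    return 2.0 / x**2 * qsca


def mie_cross_section(radius: float, particle_index: complex, medium_index: float, wavelength: float) -> float:
    """Scattering cross section (nm^2) of a sphere of given radius (nm)."""
    if not np.isfinite(radius) or radius <= 0:
        raise ValueError("radius must be finite and > 0")
    if not np.isfinite(medium_index) or medium_index <= 0:
        raise ValueError("medium_index must be finite and > 0")
    if not np.isfinite(wavelength) or wavelength <= 0:
        raise ValueError("wavelength must be finite and > 0")
    particle_index = complex(particle_index)
    if not (np.isfinite(particle_index.real) and np.isfinite(particle_index.imag)):
        raise ValueError("particle_index must be finite")
    x = 2.0 * np.pi * medium_index * radius / wavelength
    m = particle_index / medium_index
    if abs(m - 1.0) < 1e-12:
        return 0.0  # index-matched particle scatters nothing
    q = mie_efficiency(x, m)
    return q * np.pi * radius**2


def equivalent_sphere_radius(geometry: AntennaGeometry) -> float:
    """Radius (nm) of the sphere matching the mushroom's volume.

    Cap modeled as a hemisphere of ``cap_diameter``; stem as a cylinder of
    ``stem_diameter`` x ``stem_height``.
    """
    r_cap = geometry.cap_diameter / 2.0
    r_stem = geometry.stem_diameter / 2.0
    v = (2.0 / 3.0) * np.pi * r_cap**3 + np.pi * r_stem**2 * geometry.stem_height
    return float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0))


def _spectrum_from_eps(
    eps_spectrum: ComplexPermittivitySpectrum, radius: float, medium: MediumOptics
) -> ScatteringSpectrum:
    n, k = index_from_permittivity(eps_spectrum.eps)
    sigma = np.array(
        [
            mie_cross_section(radius, complex(ni, ki), medium.refractive_index, wl)
            for ni, ki, wl in zip(n, k, eps_spectrum.wavelengths)
        ]
    )
    return ScatteringSpectrum(eps_spectrum.wavelengths, sigma)


def scattering_spectrum_vs_bias(
    geometry: AntennaGeometry,
    biases: Sequence[float],
    permittivity_model: PermittivityModel,
    wavelengths: Sequence[float],
    medium: MediumOptics = MediumOptics(),
) -> Dict[float, ScatteringSpectrum]:
    """Scattering spectra of one antenna for each bias voltage.

    Per bias: doping from the calibration, permittivity by linear mixing,
    complex index, then the Mie cross section at the volume-equivalent
    radius.
    """
    lo, hi = DEFAULT_BIAS_RANGE
    biases = [float(v) for v in biases]
    if any(v < lo or v > hi for v in biases):
        warnings.warn(
            f"bias outside the characterized window [{lo}, {hi}] V vs Ag/AgCl",
            stacklevel=2,
        )
    radius = equivalent_sphere_radius(geometry)
    out: Dict[float, ScatteringSpectrum] = {}
    for v in biases:
        eps = permittivity_model.spectrum_at_bias(v, wavelengths)
        out[v] = _spectrum_from_eps(eps, radius, medium)
    return out


def scattering_vs_bias(
    geometry: AntennaGeometry,
    biases: Sequence[float],
    permittivity_model: PermittivityModel,
    wavelength: float = 640.0,
    medium: MediumOptics = MediumOptics(),
) -> np.ndarray:
    """sigma_sc (nm^2) at one wavelength for each bias; vectorized helper."""
    spectra = scattering_spectrum_vs_bias(
        geometry, biases, permittivity_model, [wavelength], medium
    )
    return np.array([spectra[float(v)].sigma_sc[0] for v in biases])


def sensitivity_vs_bias(
    geometry: AntennaGeometry,
    biases: Sequence[float],
    permittivity_model: PermittivityModel,
    wavelength: float = 640.0,
    medium: MediumOptics = MediumOptics(),
) -> Dict[float, float]:
    """Central-difference d(sigma_sc)/dV (nm^2/V) at a fixed wavelength.

    The magnitude of this derivative is the antenna's intrinsic electro-optic
    sensitivity; with the default calibration it peaks near -0.5 V.
    """
    biases = np.asarray(list(biases), dtype=float)
    if biases.size < 3:
        raise ValueError("need at least 3 biases for central differencing")
    if np.any(np.diff(biases) <= 0):
        order = np.argsort(biases)
        biases = biases[order]
    sigma = scattering_vs_bias(geometry, biases, permittivity_model, wavelength, medium)
    grad = np.gradient(sigma, biases)
    return {float(v): float(g) for v, g in zip(biases, grad)}
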