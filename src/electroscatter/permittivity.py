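"""Voltage-dependent complex permittivity of PEDOT:PSS.

PEDOT:PSS is a mixed ionic/electronic conductor whose optical constants track
its electrochemical doping level.  In the fully doped (oxidized, metallic)
state the free-carrier response is captured by a Drude term; in the fully
dedoped (reduced, dielectric) state the response is a sum of bound Lorentz
resonances plus Tauc-Lorentz absorption-edge terms.  Because both limits vary
linearly with the volumetric carrier density, permittivities at intermediate
doping are obtained by linear interpolation between the two endpoint spectra.
The doping level itself is tied to the applied electrochemical bias through a
monotone saturating (logistic) calibration curve.

All oscillator models are parameterized in photon energy (eV) and evaluated
on wavelength grids in nm, using E [eV] = 1239.84193 / lambda [nm].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EV_NM",
    "DrudeParams",
    "OscillatorSet",
    "ComplexPermittivitySpectrum",
    "DopingCalibration",
    "PermittivityModel",
    "drude_permittivity",
    "dedoped_permittivity",
    "mix_permittivity",
    "voltage_to_doping",
    "index_from_permittivity",
    "default_wavelength_grid",
]

#: Photon energy-wavelength conversion constant, eV * nm.
EV_NM = 1239.84193

_WAVELENGTH_MIN_NM = 300.0
_WAVELENGTH_MAX_NM = 1200.0


def default_wavelength_grid() -> np.ndarray:
    """400-1000 nm in 10-nm steps, the standard visible/NIR evaluation grid."""
    return np.arange(400.0, 1000.0 + 1e-9, 10.0)


def _check_wavelengths(wavelengths: Sequence[float]) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D array")
    if np.any(~np.isfinite(wl)) or np.any(wl <= 0):
        raise ValueError("wavelengths must be finite and positive (nm)")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if wl[0] < _WAVELENGTH_MIN_NM or wl[-1] > _WAVELENGTH_MAX_NM:
        raise ValueError(
            f"wavelengths must lie within [{_WAVELENGTH_MIN_NM:.0f}, "
            f"{_WAVELENGTH_MAX_NM:.0f}] nm"
        )
    return wl


@dataclass(frozen=True)
class DrudeParams:
    """Free-carrier (Drude) model of the fully doped, metallic state.

    Parameters
    ----------
    eps_inf:
        High-frequency background permittivity (dimensionless, >= 1).
    plasma_energy:
        Plasma energy E_p in eV (>= 0).
    damping_energy:
        Carrier scattering broadening Gamma in eV (> 0).
    """

    eps_inf: float
    plasma_energy: float
    damping_energy: float

    def __post_init__(self) -> None:
        if not self.eps_inf >= 1:
            raise ValueError("eps_inf must be >= 1")
        if not self.plasma_energy >= 0:
            raise ValueError("plasma_energy must be >= 0")
        if not self.damping_energy > 0:
            raise ValueError("damping_energy must be > 0")


@dataclass(frozen=True)
class OscillatorSet:
    """Bound-oscillator model of the fully dedoped, dielectric state.

    ``lorentz_terms`` are (amplitude, center_energy eV, width eV) triples;
    ``tauc_lorentz_terms`` are (amplitude eV, center_energy eV, width eV,
    gap_energy eV) quadruples.  The Tauc-Lorentz real part uses the standard
    Kramers-Kronig closed form, which requires width < 2 * center_energy.
    """

    eps_inf: float
    lorentz_terms: tuple = field(default_factory=tuple)
    tauc_lorentz_terms: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.eps_inf >= 1:
            raise ValueError("eps_inf must be >= 1")
        object.__setattr__(self, "lorentz_terms", tuple(tuple(map(float, t)) for t in self.lorentz_terms))
        object.__setattr__(
            self, "tauc_lorentz_terms", tuple(tuple(map(float, t)) for t in self.tauc_lorentz_terms)
        )
        for amp, e0, width in self.lorentz_terms:
            if width <= 0:
                raise ValueError("Lorentz width must be > 0")
            if e0 <= 0:
                raise ValueError("Lorentz center energy must be > 0")
            if amp < 0:
                raise ValueError("Lorentz amplitude must be >= 0 (passive material)")
        for amp, e0, width, gap in self.tauc_lorentz_terms:
            if width <= 0:
                raise ValueError("Tauc-Lorentz width must be > 0")
            if e0 <= 0:
                raise ValueError("Tauc-Lorentz center energy must be > 0")
            if gap < 0:
                raise ValueError("Tauc-Lorentz gap energy must be >= 0")
            if amp < 0:
                raise ValueError("Tauc-Lorentz amplitude must be >= 0")
            if width >= 2.0 * e0:
                raise ValueError(
                    "Tauc-Lorentz closed form requires width < 2 * center_energy"
                )


@dataclass(frozen=True)
class ComplexPermittivitySpectrum:
    """Complex relative permittivity eps1 + i*eps2 on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        e1 = np.asarray(self.eps_real, dtype=float)
        e2 = np.asarray(self.eps_imag, dtype=float)
        if not (wl.shape == e1.shape == e2.shape):
            raise ValueError("wavelengths, eps_real, eps_imag must share a shape")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(e2 < -1e-12):
            raise ValueError("eps_imag must be >= 0 (passive material)")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_real", e1)
        object.__setattr__(self, "eps_imag", np.clip(e2, 0.0, None))

    @property
    def eps(self) -> np.ndarray:
        return self.eps_real + 1j * self.eps_imag

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class DopingCalibration:
    """Logistic map from bias (V vs Ag/AgCl) to doping fraction in (0, 1).

    ``v_half`` is the bias of half-doping and ``v_width`` the transition
    width; more positive bias means more doped (oxidized) polymer.
    """

    v_half: float = -0.35
    v_width: float = 0.12

    def __post_init__(self) -> None:
        if not self.v_width > 0:
            raise ValueError("v_width must be > 0")


def drude_permittivity(params: DrudeParams, wavelengths: Sequence[float]) -> ComplexPermittivitySpectrum:
    """Drude dielectric function eps(E) = eps_inf - E_p^2 / (E^2 + i E Gamma).

    Evaluated on a wavelength grid (nm); photon energy E = 1239.84193/lambda.
    """
    wl = _check_wavelengths(wavelengths)
    energy = EV_NM / wl
    denom = energy**2 + 1j * energy * params.damping_energy
    eps = params.eps_inf - params.plasma_energy**2 / denom
    return ComplexPermittivitySpectrum(wl, eps.real, eps.imag)


def _lorentz(amp: float, e0: float, width: float, energy: np.ndarray) -> np.ndarray:
    return amp * e0**2 / (e0**2 - energy**2 - 1j * width * energy)


def _tauc_lorentz_eps2(amp: float, e0: float, c: float, eg: float, energy: np.ndarray) -> np.ndarray:
    e = np.asarray(energy, dtype=float)
    eps2 = np.zeros_like(e)
    above = e > eg
    ea = e[above]
    eps2[above] = (amp * e0 * c * (ea - eg) ** 2) / (((ea**2 - e0**2) ** 2 + c**2 * ea**2) * ea)
    return eps2


def _tauc_lorentz_eps1(amp: float, e0: float, c: float, eg: float, energy: np.ndarray) -> np.ndarray:
    """Closed-form Kramers-Kronig transform of the Tauc-Lorentz eps2.

    Standard analytic expression (Jellison-Modine parameterization with the
    published erratum); valid for c < 2*e0 so that ``alpha`` is real.
    """
    e = np.asarray(energy, dtype=float)
    # Avoid the logarithmic singularity exactly at the gap edge.
    e = np.where(np.abs(e - eg) < 1e-9, e + 1e-9, e)

    a_ln = (eg**2 - e0**2) * e**2 + eg**2 * c**2 - e0**2 * (e0**2 + 3 * eg**2)
    a_atan = (e**2 - e0**2) * (e0**2 + eg**2) + eg**2 * c**2
    alpha = np.sqrt(4 * e0**2 - c**2)
    gamma2 = e0**2 - c**2 / 2
    zeta4 = (e**2 - gamma2) ** 2 + alpha**2 * c**2 / 4

    term1 = (
        (amp * c * a_ln)
        / (2 * np.pi * zeta4 * alpha * e0)
        * np.log((e0**2 + eg**2 + alpha * eg) / (e0**2 + eg**2 - alpha * eg))
    )
    term2 = (
        -(amp / (np.pi * zeta4))
        * (a_atan / e0)
        * (np.pi - np.arctan((2 * eg + alpha) / c) + np.arctan((alpha - 2 * eg) / c))
    )
    term3 = (
        (2 * amp * e0 / (np.pi * zeta4 * alpha))
        * eg
        * (e**2 - gamma2)
        * (np.pi + 2 * np.arctan(2 * (gamma2 - eg**2) / (alpha * c)))
    )
    term4 = (
        -(amp * e0 * c / (np.pi * zeta4))
        * ((e**2 + eg**2) / e)
        * np.log(np.abs(e - eg) / (e + eg))
    )
    term5 = (
        (2 * amp * e0 * c / (np.pi * zeta4))
        * eg
        * np.log((np.abs(e - eg) * (e + eg)) / np.sqrt((e0**2 - eg**2) ** 2 + eg**2 * c**2))
    )
    return term1 + term2 + term3 + term4 + term5


def dedoped_permittivity(params: OscillatorSet, wavelengths: Sequence[float]) -> ComplexPermittivitySpectrum:
    """Lorentz + Tauc-Lorentz dielectric function of the dedoped state."""
    wl = _check_wavelengths(wavelengths)
    energy = EV_NM / wl
    eps = np.full(wl.shape, params.eps_inf, dtype=complex)
    for amp, e0, width in params.lorentz_terms:
        eps += _lorentz(amp, e0, width, energy)
    for amp, e0, width, gap in params.tauc_lorentz_terms:
        eps += _tauc_lorentz_eps1(amp, e0, width, gap, energy)
        eps += 1j * _tauc_lorentz_eps2(amp, e0, width, gap, energy)
    return ComplexPermittivitySpectrum(wl, eps.real, eps.imag)


def mix_permittivity(
    doped: ComplexPermittivitySpectrum,
    dedoped: ComplexPermittivitySpectrum,
    doping: float,
) -> ComplexPermittivitySpectrum:
    """Linear interpolation between endpoint spectra at a doping fraction.

    Both permittivity limits scale linearly with their volumetric carrier
    densities, so an intermediate doping level c gives pointwise
    eps = c * eps_doped + (1 - c) * eps_dedoped.
    """
    if not 0.0 <= doping <= 1.0:
        raise ValueError("doping must lie in [0, 1]")
    if doped.wavelengths.shape != dedoped.wavelengths.shape or not np.allclose(
        doped.wavelengths, dedoped.wavelengths
    ):
        raise ValueError("spectra must share an identical wavelength grid")
    e1 = doping * doped.eps_real + (1.0 - doping) * dedoped.eps_real
    e2 = doping * doped.eps_imag + (1.0 - doping) * dedoped.eps_imag
    return ComplexPermittivitySpectrum(doped.wavelengths, e1, e2)


def voltage_to_doping(v_bias, cal: DopingCalibration = DopingCalibration()):
    """Logistic doping fraction c(V) = 1 / (1 + exp(-(V - v_half)/v_width)).

    Monotone increasing: positive bias oxidizes (dopes) the polymer.
    Accepts scalars or arrays.
    """
    from scipy.special import expit  # overflow-safe logistic

    v = np.asarray(v_bias, dtype=float)
    c = expit((v - cal.v_half) / cal.v_width)
    return float(c) if np.isscalar(v_bias) else c


def index_from_permittivity(eps):
    """Complex refractive index (n, k) with (n + ik)^2 = eps and k >= 0."""
    root = np.sqrt(np.asarray(eps, dtype=complex))
    # principal sqrt has non-negative imaginary part for Im(eps) >= 0;
    # flip the branch where rounding produced k < 0
    root = np.where(root.imag < 0, -root, root)
    if np.ndim(eps) == 0:
        root = complex(root)
        return root.real, root.imag
    return root.real, root.imag


@dataclass(frozen=True)
class PermittivityModel:
    """Bundle of the doped/dedoped endpoints and the bias calibration."""

    doped: DrudeParams
    dedoped: OscillatorSet
    calibration: DopingCalibration = DopingCalibration()

    def spectrum_at_doping(self, doping: float, wavelengths: Sequence[float]) -> ComplexPermittivitySpectrum:
        return mix_permittivity(
            drude_permittivity(self.doped, wavelengths),
            dedoped_permittivity(self.dedoped, wavelengths),
            doping,
        )

    def spectrum_at_bias(self, v_bias: float, wavelengths: Sequence[float]) -> ComplexPermittivitySpectrum:
        return self.spectrum_at_doping(voltage_to_doping(v_bias, self.calibration), wavelengths)
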