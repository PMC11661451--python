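"""Equivalent-circuit model of the antenna-electrolyte interface.

The interface is modeled as a series chain: solution resistance R_s, polymer
series resistance R_p, and polymer volumetric capacitance C_p, with the
transferred (electro-optically active) voltage read across the capacitor.
This is the minimal topology consistent with a single-exponential step
response of time constant tau = (R_s + R_p) * C_p.  Larger antennas carry a
larger volumetric capacitance and are therefore slower.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CircuitParams",
    "StimulusProtocol",
    "VoltageTrace",
    "EISFitResult",
    "biased_polymer_resistance",
    "impedance_spectrum",
    "transferred_voltage",
    "time_constant",
    "fit_eis",
]


@dataclass(frozen=True)
class CircuitParams:
    """Series R_s - R_p - C_p interface circuit (ohms, ohms, farads)."""

    r_s: float
    r_p: float
    c_p: float

    def __post_init__(self) -> None:
        for name in ("r_s", "r_p", "c_p"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Pulse:
    """A rectangular stimulus pulse added on top of the holding bias."""

    amplitude: float  # V
    onset: float  # s
    duration: float  # s

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("pulse onset must be >= 0 and duration > 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Holding bias plus a train of rectangular pulses, uniformly sampled."""

    v_bias: float
    pulses: Tuple[Pulse, ...] = field(default_factory=tuple)
    total_duration: float = 3.0
    sampling_rate: float = 200.0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.total_duration > 0:
            raise ValueError("total_duration must be > 0")
        pulses = tuple(p if isinstance(p, Pulse) else Pulse(*p) for p in self.pulses)
        for p in pulses:
            if p.onset + p.duration > self.total_duration + 1e-12:
                raise ValueError("pulses must fit within total_duration")
        object.__setattr__(self, "pulses", pulses)

    @property
    def time(self) -> np.ndarray:
        n = int(round(self.total_duration * self.sampling_rate))
        return np.arange(n) / self.sampling_rate

    def applied_voltage(self, t: np.ndarray | None = None) -> np.ndarray:
        """The commanded voltage V_stim(t): bias plus rectangular pulses."""
        if t is None:
            t = self.time
        v = np.full_like(t, self.v_bias, dtype=float)
        for p in self.pulses:
            v += p.amplitude * ((t >= p.onset) & (t < p.onset + p.duration))
        return v


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled voltage time series (s, V)."""

    time: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and v must be 1-D arrays of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time must be strictly increasing and uniform")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "v", v)


def biased_polymer_resistance(
    r_p0: float, doping: float, kappa: float = 0.0
) -> float:
    """Optional dedoping-dependent series resistance R_p(V) = R_p0*(1 + kappa*(1-c)).

    Dedoped PEDOT is less conductive, which lengthens the time constant at
    negative bias; the effect is known qualitatively only, so kappa defaults
    to 0 (off).
    """
    if not 0.0 <= doping <= 1.0:
        raise ValueError("doping must lie in [0, 1]")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    return r_p0 * (1.0 + kappa * (1.0 - doping))


def impedance_spectrum(params: CircuitParams, frequencies: Sequence[float]) -> np.ndarray:
    """Complex impedance Z(f) = R_s + R_p + 1/(i 2 pi f C_p)."""
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0) or np.any(~np.isfinite(f)):
        raise ValueError("frequencies must be finite and > 0 (series capacitor diverges at DC)")
    omega = 2.0 * np.pi * f
    return params.r_s + params.r_p + 1.0 / (1j * omega * params.c_p)


def time_constant(params: CircuitParams) -> float:
    """Charging time constant tau = (R_s + R_p) * C_p in seconds."""
    return (params.r_s + params.r_p) * params.c_p


def transferred_voltage(params: CircuitParams, protocol: StimulusProtocol) -> VoltageTrace:
    """Voltage across C_p under the protocol, by exact superposition.

    Each rectangular pulse contributes a charging exponential at its onset
    and a discharging one at its offset; the circuit is linear so the
    contributions add on top of the (fully settled) holding bias.
    """
    tau = time_constant(params)
    t = protocol.time
    v = np.full_like(t, protocol.v_bias, dtype=float)
    for p in protocol.pulses:
        for edge, sign in ((p.onset, 1.0), (p.onset + p.duration, -1.0)):
            active = t >= edge
            v[active] += sign * p.amplitude * (1.0 - np.exp(-(t[active] - edge) / tau))
    return VoltageTrace(t, v)


@dataclass(frozen=True)
class EISFitResult:
    """Outcome of a least-squares equivalent-circuit fit to an EIS spectrum."""

    params: CircuitParams
    residual_norm: float
    converged: bool
    degenerate: bool = False
    message: str = ""

    @property
    def flagged(self) -> bool:
        """True when the fit failed, visibly misfits, or is degenerate."""
        return (not self.converged) or self.degenerate or self.residual_norm > 0.1


def fit_eis(
    frequencies: Sequence[float],
    z: Sequence[complex],
    r_s: float | None = None,
) -> EISFitResult:
    """Fit the series R_s-R_p-C_p model to a measured impedance spectrum.

    The fit is performed on log10|Z| and phase (radians) jointly, with the
    parameters themselves in log space to enforce positivity; this matches
    how EIS spectra are displayed (Bode) and weighted in practice.

    In a purely series chain only R_s + R_p is identifiable from the
    spectrum.  Pass ``r_s`` (the independently measured solution resistance)
    to apportion the fitted total; otherwise the whole resistance is
    assigned to R_p and R_s is returned as a negligible placeholder.

    A spectrum with no capacitive feature inside the measured band (for
    example one generated by a pure resistor, which the model mimics with
    C -> infinity) is reported with ``degenerate=True``.
    """
    f = np.asarray(frequencies, dtype=float)
    z = np.asarray(z, dtype=complex)
    if f.size != z.size:
        raise ValueError("frequencies and impedances must have equal length")
    if f.size < 5:
        raise ValueError("need at least 5 frequencies")
    if np.log10(f.max() / f.min()) < 2:
        raise ValueError("frequencies must span at least 2 decades")

    def model(log_params: np.ndarray) -> np.ndarray:
        r_tot, c_p = np.exp(log_params)
        return r_tot + 1.0 / (1j * 2.0 * np.pi * f * c_p)

    def residuals(log_params: np.ndarray) -> np.ndarray:
        zm = model(log_params)
        return np.concatenate(
            [np.log10(np.abs(zm)) - np.log10(np.abs(z)), np.angle(zm) - np.angle(z)]
        )

    # Heuristic start: high-f plateau gives R_s + R_p, low-f reactance gives C_p.
    hi = np.argmax(f)
    lo = np.argmin(f)
    r_tot0 = max(abs(z[hi].real), 1e-3)
    c0 = 1.0 / max(2.0 * np.pi * f[lo] * abs(z[lo].imag), 1e-18)
    sol = least_squares(residuals, np.log([r_tot0, c0]), method="lm", max_nfev=2000)
    r_tot, c_p = np.exp(sol.x)
    if r_s is not None:
        if not 0 < r_s < r_tot:
            raise ValueError("known r_s must lie in (0, fitted total resistance)")
        params = CircuitParams(r_s, r_tot - r_s, c_p)
    else:
        params = CircuitParams(1e-9 * r_tot, r_tot, c_p)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    converged = bool(sol.success) and np.all(np.isfinite(sol.x))
    # Capacitor invisible in-band: reactance at the lowest frequency below
    # 1% of the resistive plateau means the RC model is not constrained.
    degenerate = 1.0 / (2.0 * np.pi * f[lo] * c_p) < 0.01 * r_tot
    return EISFitResult(params, rms, converged, degenerate, message=str(sol.message))
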