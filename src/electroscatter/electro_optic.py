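"""Digital twin: circuit dynamics composed with the static optics.

The static scattering-versus-voltage characteristic of an antenna is well
described by a decreasing sigmoid (dedoping at negative bias brightens the
antenna until both endpoint states saturate).  The dynamic optical response
to an arbitrary stimulus protocol is obtained by pushing the transferred
(capacitor) voltage of the equivalent circuit through that sigmoid, i.e. the
optics are assumed quasi-static relative to the electrochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .circuit import CircuitParams, StimulusProtocol, transferred_voltage

__all__ = [
    "SigmoidTransfer",
    "OpticalTrace",
    "fit_sigmoid_transfer",
    "dynamic_optical_response",
]


@dataclass(frozen=True)
class SigmoidTransfer:
    """Decreasing logistic sigma(V) between sigma_max (negative V) and sigma_min.

    sigma(V) = sigma_min + (sigma_max - sigma_min) / (1 + exp((V - v_mid)/v_slope_width))
    """

    sigma_min: float
    sigma_max: float
    v_mid: float
    v_slope_width: float

    def __post_init__(self) -> None:
        if not self.sigma_max > self.sigma_min > 0:
            raise ValueError("need sigma_max > sigma_min > 0")
        if not self.v_slope_width > 0:
            raise ValueError("v_slope_width must be > 0")

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        out = self.sigma_min + (self.sigma_max - self.sigma_min) / (
            1.0 + np.exp((v - self.v_mid) / self.v_slope_width)
        )
        return float(out) if out.ndim == 0 else out

    def slope(self, v):
        """d sigma / dV; most negative (steepest) at v_mid."""
        v = np.asarray(v, dtype=float)
        s = np.exp((v - self.v_mid) / self.v_slope_width)
        out = -(self.sigma_max - self.sigma_min) * s / (self.v_slope_width * (1.0 + s) ** 2)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class OpticalTrace:
    """Uniformly sampled optical signal (s, nm^2 in model space)."""

    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time must be a uniform increasing grid")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class SigmoidFitResult:
    transfer: SigmoidTransfer
    residual_norm: float
    converged: bool
    degenerate: bool

    @property
    def flagged(self) -> bool:
        return (not self.converged) or self.degenerate


def fit_sigmoid_transfer(
    samples: Sequence[Tuple[float, float]],
) -> SigmoidFitResult:
    """Least-squares logistic fit of (bias, sigma_sc) samples.

    A fit whose dynamic range (sigma_max - sigma_min) is below 1% of
    sigma_max is reported as degenerate (flat transfer; v_mid meaningless).
    """
    pts = np.asarray(samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 (bias, sigma) samples")
    v, sigma = pts[:, 0], pts[:, 1]
    if np.any(sigma <= 0):
        raise ValueError("sigma samples must be > 0")

    def model(vv, s_min, ds, v_mid, width):
        return s_min + ds / (1.0 + np.exp((vv - v_mid) / width))

    smin0 = max(sigma.min() * 0.99, 1e-12 * sigma.max() + 1e-300)
    ds0 = max(sigma.max() - sigma.min(), 1e-6 * sigma.max())
    p0 = [smin0, ds0, float(np.median(v)), max(np.ptp(v) / 6.0, 1e-3)]
    lower = [1e-300, 0.0, v.min() - 10 * np.ptp(v) - 1.0, 1e-6]
    upper = [np.inf, np.inf, v.max() + 10 * np.ptp(v) + 1.0, np.inf]
    converged = True
    try:
        popt, _ = curve_fit(model, v, sigma, p0=p0, bounds=(lower, upper), maxfev=20000)
    except RuntimeError:
        popt = p0
        converged = False
    s_min, ds, v_mid, width = popt
    s_min = max(s_min, 1e-300)
    ds = max(ds, 1e-9 * max(s_min, sigma.max()))
    transfer = SigmoidTransfer(s_min, s_min + ds, v_mid, width)
    resid = float(np.sqrt(np.mean((model(v, s_min, ds, v_mid, width) - sigma) ** 2)))
    degenerate = ds < 0.01 * (s_min + ds)
    return SigmoidFitResult(transfer, resid, converged, degenerate)


def dynamic_optical_response(
    protocol: StimulusProtocol,
    circuit: CircuitParams,
    transfer: SigmoidTransfer,
) -> OpticalTrace:
    """sigma(t) = transfer(V_C(t)) on the protocol's time grid.

    The transferred voltage (across the polymer capacitance) follows the
    protocol with first-order lag tau = (R_s + R_p) C_p, so a negative
    stimulus pulse produces a positive, exponentially rising brightness
    deflection whose kinetics inherit the circuit's time constant.
    """
    vtrace = transferred_voltage(circuit, protocol)
    return OpticalTrace(vtrace.time, transfer(vtrace.v))
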