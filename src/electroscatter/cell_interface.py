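"""Cardiomyocyte action potential coupled to the cell-sensor interface.

The membrane model is the Luo-Rudy 1991 guinea-pig ventricular action
potential: six ionic currents (fast Na+, slow inward Ca2+, time-dependent
K+, time-independent K+, plateau K+, background) with Hodgkin-Huxley gating
and a simple intracellular calcium pool.

The extracellular sensor sees the action potential through the junctional
cleft formed between the cell and the protruding antenna: the membrane
potential v_m drives the cleft through the junctional resistance R_j, the
cleft leaks to the grounded bath through the seal resistance R_Seal, and the
sensor's own R-C branch loads the cleft node.  With a high-impedance sensor
branch the transferred voltage reduces to the resistive divider
v_sensor ~= v_m * R_Seal / (R_Seal + R_j); the coupling is one-way (the
sensor does not feed back into the membrane currents, its impedance being
orders of magnitude above the membrane's).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import CircuitParams

__all__ = [
    "LR91State",
    "InterfaceParams",
    "APTrace",
    "lr91_derivatives",
    "lr91_resting_state",
    "simulate_ap",
    "interface_transfer",
    "peak_amplitude",
]

# Ionic concentrations (mM) and derived Nernst potentials (mV), original values.
_KO, _KI = 5.4, 145.0
_NAO, _NAI = 140.0, 18.0
_RT_F = 26.71  # mV at 37 C, as in the original formulation (RT/F with F in C/mmol)
_PR_NAK = 0.01833

E_NA = _RT_F * np.log(_NAO / _NAI)  # ~ +54.8 mV
E_K = _RT_F * np.log((_KO + _PR_NAK * _NAO) / (_KI + _PR_NAK * _NAI))  # ~ -77 mV
E_K1 = _RT_F * np.log(_KO / _KI)  # ~ -87.9 mV
E_KP = E_K1

G_NA = 23.0  # mS/cm^2
G_SI = 0.09
G_K = 0.282 * np.sqrt(_KO / 5.4)
G_K1 = 0.6047 * np.sqrt(_KO / 5.4)
G_KP = 0.0183
G_B = 0.03921
C_M = 1.0  # uF/cm^2


@dataclass(frozen=True)
class LR91State:
    """Membrane state: potential (mV), six gates in [0,1], calcium (mM)."""

    v_m: float
    m: float
    h: float
    j: float
    d: float
    f: float
    x: float
    ca_i: float

    def __post_init__(self) -> None:
        for g in ("m", "h", "j", "d", "f", "x"):
            if not 0.0 <= getattr(self, g) <= 1.0:
                raise ValueError(f"gate {g} must lie in [0, 1]")
        if not self.ca_i > 0:
            raise ValueError("ca_i must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.v_m, self.m, self.h, self.j, self.d, self.f, self.x, self.ca_i])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "LR91State":
        # Solver trial steps can overshoot the gate bounds by rounding error;
        # clip rather than reject so validation reflects physics, not epsilons.
        y = np.asarray(y, dtype=float)
        gates = np.clip(y[1:7], 0.0, 1.0)
        ca = max(y[7], 1e-12)
        return cls(float(y[0]), *map(float, gates), ca)


def _safe_exp_ratio(num_coeff: float, v: float, v0: float, k: float) -> float:
    """num_coeff*(v - v0) / (1 - exp(-k*(v - v0))) with the v -> v0 limit."""
    dv = v - v0
    if abs(dv) < 1e-9:
        return num_coeff / k
    return num_coeff * dv / (1.0 - np.exp(-k * dv))


def _gate_rates(v: float) -> dict:
    """Original LR91 alpha/beta rate constants (1/ms) at potential v (mV)."""
    r = {}
    r["m"] = (
        _safe_exp_ratio(0.32, v, -47.13, 0.1),
        0.08 * np.exp(-v / 11.0),
    )
    if v < -40.0:
        r["h"] = (
            0.135 * np.exp((80.0 + v) / -6.8),
            3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
        )
        r["j"] = (
            (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + np.exp(0.311 * (v + 79.23))),
            0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
        )
    else:
        r["h"] = (0.0, 1.0 / (0.13 * (1.0 + np.exp((v + 10.66) / -11.1))))
        r["j"] = (0.0, 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))))
    r["d"] = (
        0.095 * np.exp(-0.01 * (v - 5.0)) / (1.0 + np.exp(-0.072 * (v - 5.0))),
        0.07 * np.exp(-0.017 * (v + 44.0)) / (1.0 + np.exp(0.05 * (v + 44.0))),
    )
    r["f"] = (
        0.012 * np.exp(-0.008 * (v + 28.0)) / (1.0 + np.exp(0.15 * (v + 28.0))),
        0.0065 * np.exp(-0.02 * (v + 30.0)) / (1.0 + np.exp(-0.2 * (v + 30.0))),
    )
    r["x"] = (
        0.0005 * np.exp(0.083 * (v + 50.0)) / (1.0 + np.exp(0.057 * (v + 50.0))),
        0.0013 * np.exp(-0.06 * (v + 20.0)) / (1.0 + np.exp(-0.04 * (v + 20.0))),
    )
    return r


def _xi(v: float) -> float:
    """Inactivation factor of the time-dependent K+ current."""
    if v > -100.0:
        if abs(v + 77.0) < 1e-9:
            # limit of 2.837*(exp(0.04*(v+77))-1)/((v+77)*exp(0.04*(v+35)))
            return 2.837 * 0.04 / np.exp(0.04 * (v + 35.0))
        return (
            2.837
            * (np.exp(0.04 * (v + 77.0)) - 1.0)
            / ((v + 77.0) * np.exp(0.04 * (v + 35.0)))
        )
    return 1.0


def _k1_inf(v: float) -> float:
    ak1 = 1.02 / (1.0 + np.exp(0.2385 * (v - E_K1 - 59.215)))
    bk1 = (
        0.49124 * np.exp(0.08032 * (v - E_K1 + 5.476))
        + np.exp(0.06175 * (v - E_K1 - 594.31))
    ) / (1.0 + np.exp(-0.5143 * (v - E_K1 + 4.753)))
    return ak1 / (ak1 + bk1)


def ionic_current(state: LR91State) -> float:
    """Total ionic current (uA/cm^2), positive outward."""
    v = state.v_m
    e_si = 7.7 - 13.0287 * np.log(state.ca_i)
    i_na = G_NA * state.m**3 * state.h * state.j * (v - E_NA)
    i_si = G_SI * state.d * state.f * (v - e_si)
    i_k = G_K * state.x * _xi(v) * (v - E_K)
    i_k1 = G_K1 * _k1_inf(v) * (v - E_K1)
    i_kp = G_KP * (v - E_KP) / (1.0 + np.exp((7.488 - v) / 5.98))
    i_b = G_B * (v + 59.87)
    return i_na + i_si + i_k + i_k1 + i_kp + i_b


def lr91_derivatives(state: LR91State, stimulus_current: float = 0.0) -> np.ndarray:
    """Right-hand side d(state)/dt; time in ms.

    ``stimulus_current`` is in uA/cm^2, positive outward (a depolarizing
    stimulus is negative, per convention).
    """
    v = state.v_m
    e_si = 7.7 - 13.0287 * np.log(state.ca_i)
    i_si = G_SI * state.d * state.f * (v - e_si)
    dv = -(ionic_current(state) + stimulus_current) / C_M
    rates = _gate_rates(v)
    dg = {}
    for g, (alpha, beta) in rates.items():
        dg[g] = alpha * (1.0 - getattr(state, g)) - beta * getattr(state, g)
    dca = -1e-4 * i_si + 0.07 * (1e-4 - state.ca_i)
    return np.array([dv, dg["m"], dg["h"], dg["j"], dg["d"], dg["f"], dg["x"], dca])


def lr91_resting_state(v0: float = -84.5, settle_ms: float = 2000.0) -> LR91State:
    """Quiescent steady state, found by relaxing from gate steady values."""
    rates = _gate_rates(v0)
    gates = {g: a / (a + b) if (a + b) > 0 else 0.0 for g, (a, b) in rates.items()}
    start = LR91State(v0, gates["m"], gates["h"], gates["j"], gates["d"], gates["f"], gates["x"], 2e-4)
    sol = solve_ivp(
        lambda t, y: lr91_derivatives(LR91State.from_array(y)),
        (0.0, settle_ms),
        start.as_array(),
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"resting-state relaxation failed: {sol.message}")
    return LR91State.from_array(sol.y[:, -1])


@dataclass(frozen=True)
class StimulusPulse:
    """Rectangular stimulus current (uA/cm^2, negative = depolarizing)."""

    amplitude: float = -40.0
    onset_ms: float = 10.0
    duration_ms: float = 1.0


@dataclass
class APTrace:
    """Action-potential trace: time (ms), v_m (mV), optional v_sensor (mV)."""

    time: np.ndarray
    v_m: np.ndarray
    v_sensor: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.time.shape != self.v_m.shape:
            raise ValueError("time and v_m must have equal length")


def simulate_ap(
    stimulus: StimulusPulse = StimulusPulse(),
    duration_ms: float = 500.0,
    dt_ms: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    initial_state: Optional[LR91State] = None,
) -> APTrace:
    """Integrate one action potential on a uniform output grid.

    Uses a stiff-capable solver (LSODA) with the stimulus pulse edges
    protected by explicit solver restarts so the rectangular pulse is not
    stepped over.
    """
    if duration_ms < 500.0:
        raise ValueError("duration must cover the full action potential (>= 500 ms)")
    state = initial_state if initial_state is not None else lr91_resting_state()
    t_grid = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    edges = [0.0, stimulus.onset_ms, stimulus.onset_ms + stimulus.duration_ms, duration_ms]
    edges = sorted(set(min(max(e, 0.0), duration_ms) for e in edges))

    y0 = state.as_array()
    vs: list[np.ndarray] = []
    ts: list[np.ndarray] = []
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 - t0 <= 0:
            continue
        mid = 0.5 * (t0 + t1)
        i_stim = (
            stimulus.amplitude
            if stimulus.onset_ms <= mid < stimulus.onset_ms + stimulus.duration_ms
            else 0.0
        )
        t_eval = t_grid[(t_grid >= t0) & (t_grid <= t1)]
        sol = solve_ivp(
            lambda t, y: lr91_derivatives(LR91State.from_array(y), i_stim),
            (t0, t1),
            y0,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
            max_step=min(1.0, t1 - t0),
        )
        if not sol.success:
            raise RuntimeError(f"action-potential integration failed: {sol.message}")
        y0 = sol.y[:, -1]
        if sol.t.size:
            ts.append(sol.t)
            vs.append(sol.y[0])
    t = np.concatenate(ts)
    v = np.concatenate(vs)
    t, keep = np.unique(np.round(t / dt_ms).astype(int), return_index=True)
    return APTrace(t * dt_ms, v[keep])


def default_single_antenna_circuit() -> CircuitParams:
    """Sensor branch of a single intermediate-size (1.4 um cap) antenna.

    The polymer's volumetric capacitance (~39 F/cm^3, a standard figure for
    electrodeposited PEDOT:PSS) over a 1.4-um hemispherical cap gives
    C_p ~ 28 pF; the measured intermediate-antenna time constant of 34.7 ms
    then fixes R_p ~ 1.2 GOhm (the narrow stem dominates the series
    resistance).  The spreading/solution resistance of a micrometer opening
    is of order 100 kOhm.
    """
    return CircuitParams(r_s=1e5, r_p=1.2e9, c_p=2.8e-11)


@dataclass(frozen=True)
class InterfaceParams:
    """Cell-sensor coupling: seal and junctional resistances plus the sensor RC.

    ``sensor_circuit=None`` selects the purely resistive quasi-static
    divider limit (a sensor branch of infinite impedance).  The default is
    the single-antenna branch, whose ~GOhm impedance is far above the
    divider's at DC but still shaves the fastest (millisecond) part of the
    upstroke.
    """

    r_seal: float = 2e8
    r_j: float = 5e8
    sensor_circuit: Optional[CircuitParams] = field(
        default_factory=default_single_antenna_circuit
    )

    def __post_init__(self) -> None:
        if not self.r_seal > 0 or not self.r_j > 0:
            raise ValueError("r_seal and r_j must be > 0")

    @property
    def divider_ratio(self) -> float:
        return self.r_seal / (self.r_seal + self.r_j)


def interface_transfer(ap: APTrace, params: InterfaceParams = InterfaceParams()) -> APTrace:
    """Voltage transferred to the polymer sensor element under the cell.

    The cleft node obeys Kirchhoff's law
    (v_m - V_cleft)/R_j = V_cleft/R_seal + (V_cleft - V_C)/(R_s + R_p),
    with the sensor branch current charging C_p.  v_sensor is the drop
    across the polymer element (R_p + C_p), i.e. the cleft voltage minus
    the solution-resistance share of the branch drop.  Without a sensor
    circuit the quasi-static divider v_sensor = v_m * R_seal/(R_seal + R_j)
    is returned.
    """
    v_cleft_qs = ap.v_m * params.divider_ratio
    if params.sensor_circuit is None:
        return APTrace(ap.time, ap.v_m, v_cleft_qs)

    cp = params.sensor_circuit
    r_rc = cp.r_s + cp.r_p
    g = 1.0 / params.r_j + 1.0 / params.r_seal + 1.0 / r_rc
    # dV_C/dt = a*v_m + b*V_C  (v_m held constant over each sample step)
    b = (1.0 / (g * r_rc) - 1.0) / (r_rc * cp.c_p) * 1e-3  # per ms
    a = 1.0 / (params.r_j * g * r_rc * cp.c_p) * 1e-3
    v_c = np.empty_like(ap.v_m)
    v_c[0] = -a * ap.v_m[0] / b  # start settled at the resting potential
    dts = np.diff(ap.time)
    for i, dt in enumerate(dts, start=1):
        v_inf = -a * ap.v_m[i] / b
        v_c[i] = v_inf + (v_c[i - 1] - v_inf) * np.exp(b * dt)
    v_cleft = (ap.v_m / params.r_j + v_c / r_rc) / g
    i_branch = (v_cleft - v_c) / r_rc
    v_sensor = v_cleft - i_branch * cp.r_s
    return APTrace(ap.time, ap.v_m, v_sensor)


def peak_amplitude(trace: APTrace, channel: str = "v_sensor") -> float:
    """Peak-to-peak amplitude (max - min, mV) of the selected channel."""
    y = getattr(trace, channel)
    if y is None:
        raise ValueError(f"trace has no channel {channel!r}")
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty trace")
    return float(y.max() - y.min())
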