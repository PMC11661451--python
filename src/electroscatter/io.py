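"""Delimited-text readers/writers for spectra, EIS data and time traces."""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .circuit import VoltageTrace
from .permittivity import ComplexPermittivitySpectrum
from .scattering import ScatteringSpectrum

__all__ = [
    "write_permittivity",
    "read_permittivity",
    "write_scattering",
    "read_scattering",
    "write_eis",
    "read_eis",
    "write_trace",
    "read_trace",
]


def write_permittivity(spec: ComplexPermittivitySpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "eps1": spec.eps_real, "eps2": spec.eps_imag}
    ).to_csv(path, index=False)


def read_permittivity(path: str | Path) -> ComplexPermittivitySpectrum:
    df = pd.read_csv(path)
    return ComplexPermittivitySpectrum(
        df["wavelength_nm"].to_numpy(), df["eps1"].to_numpy(), df["eps2"].to_numpy()
    )


def write_scattering(spec: ScatteringSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "sigma_sc_nm2": spec.sigma_sc}
    ).to_csv(path, index=False)


def read_scattering(path: str | Path) -> ScatteringSpectrum:
    df = pd.read_csv(path)
    return ScatteringSpectrum(df["wavelength_nm"].to_numpy(), df["sigma_sc_nm2"].to_numpy())


def write_eis(frequencies: np.ndarray, z: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"frequency_hz": frequencies, "z_real_ohm": np.real(z), "z_imag_ohm": np.imag(z)}
    ).to_csv(path, index=False)


def read_eis(path: str | Path) -> Tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (
        df["frequency_hz"].to_numpy(),
        df["z_real_ohm"].to_numpy() + 1j * df["z_imag_ohm"].to_numpy(),
    )


def write_trace(trace: VoltageTrace, path: str | Path, value_column: str = "volts") -> None:
    pd.DataFrame({"time_s": trace.time, value_column: trace.v}).to_csv(path, index=False)


def read_trace(path: str | Path, value_column: str = "volts") -> VoltageTrace:
    df = pd.read_csv(path)
    return VoltageTrace(df["time_s"].to_numpy(), df[value_column].to_numpy())
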