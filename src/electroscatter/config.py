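"""Structured configuration: default model parameters and user config files."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .circuit import CircuitParams
from .permittivity import (
    DopingCalibration,
    DrudeParams,
    OscillatorSet,
    PermittivityModel,
)
from .scattering import AntennaGeometry, MediumOptics

__all__ = [
    "load_config",
    "default_config",
    "permittivity_model_from_config",
    "geometry_from_config",
    "medium_from_config",
    "circuit_from_config",
]


def default_config() -> Dict[str, Any]:
    """The packaged default model parameters (editable copy)."""
    text = resources.files("electroscatter.data").joinpath("default_model.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: Optional[str | Path] = None) -> Dict[str, Any]:
    """Load a YAML config file, or the packaged defaults when path is None."""
    if path is None:
        return default_config()
    return yaml.safe_load(Path(path).read_text())


def permittivity_model_from_config(cfg: Dict[str, Any]) -> PermittivityModel:
    p = cfg["permittivity"]
    drude = DrudeParams(
        eps_inf=float(p["doped_drude"]["eps_inf"]),
        plasma_energy=float(p["doped_drude"]["plasma_energy_ev"]),
        damping_energy=float(p["doped_drude"]["damping_energy_ev"]),
    )
    osc_cfg = p["dedoped_oscillators"]
    osc = OscillatorSet(
        eps_inf=float(osc_cfg["eps_inf"]),
        lorentz_terms=tuple(
            (float(t["amplitude"]), float(t["center_ev"]), float(t["width_ev"]))
            for t in osc_cfg.get("lorentz", [])
        ),
        tauc_lorentz_terms=tuple(
            (
                float(t["amplitude_ev"]),
                float(t["center_ev"]),
                float(t["width_ev"]),
                float(t["gap_ev"]),
            )
            for t in osc_cfg.get("tauc_lorentz", [])
        ),
    )
    cal_cfg = p["doping_calibration"]
    cal = DopingCalibration(v_half=float(cal_cfg["v_half"]), v_width=float(cal_cfg["v_width"]))
    return PermittivityModel(drude, osc, cal)


def geometry_from_config(cfg: Dict[str, Any]) -> AntennaGeometry:
    g = cfg["geometry"]
    return AntennaGeometry(
        cap_diameter=float(g["cap_diameter_nm"]),
        stem_diameter=float(g["stem_diameter_nm"]),
        stem_height=float(g["stem_height_nm"]),
    )


def medium_from_config(cfg: Dict[str, Any]) -> MediumOptics:
    return MediumOptics(eps_medium=float(cfg["medium"]["eps"]))


def circuit_from_config(cfg: Dict[str, Any], cap_um: Optional[float] = None) -> CircuitParams:
    """Interface circuit for a given cap diameter (um), or the default."""
    c = cfg["circuit"]
    entry = c["default"]
    if cap_um is not None:
        per_cap = {float(k): v for k, v in c.get("per_cap_um", {}).items()}
        if cap_um in per_cap:
            entry = per_cap[cap_um]
    return CircuitParams(
        r_s=float(entry["r_s_ohm"]),
        r_p=float(entry["r_p_ohm"]),
        c_p=float(entry["c_p_farad"]),
    )
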