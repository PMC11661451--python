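"""Array-scale bookkeeping: recording density and field-of-view capacity."""

from __future__ import annotations

__all__ = [
    "array_density_per_cm2",
    "field_diameter_um",
    "antennas_in_field",
]

import math


def array_density_per_cm2(pitch_um: float) -> float:
    """Recording-site density (sites/cm^2) of a square array at given pitch.

    A 5-um pitch gives 4e6 sites on a 1 x 1 cm^2 area.
    """
    if not pitch_um > 0:
        raise ValueError("pitch must be > 0")
    return (1e4 / pitch_um) ** 2


def field_diameter_um(sensor_field_mm: float, magnification: float) -> float:
    """Sample-plane diameter (um) of a camera field through an objective.

    A 25-mm field number at 60x or 40x projects to 417 or 625 um circles
    on the sample.
    """
    if not sensor_field_mm > 0 or not magnification > 0:
        raise ValueError("field and magnification must be > 0")
    return sensor_field_mm * 1e3 / magnification


def antennas_in_field(
    field_diameter: float, pitch_um: float, round_to: int = 1000
) -> int:
    """Number of array sites inside a circular field, rounded.

    Computed as circle area / pitch^2 and rounded to the nearest
    ``round_to`` (nearest thousand by default, the convention used when
    quoting imaging capacity).
    """
    if not field_diameter > 0 or not pitch_um > 0:
        raise ValueError("field diameter and pitch must be > 0")
    n = math.pi * (field_diameter / 2.0) ** 2 / pitch_um**2
    if round_to <= 1:
        return round(n)
    return int(round(n / round_to) * round_to)
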