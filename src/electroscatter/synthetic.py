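"""Ground-truthed synthetic data: camera stacks and noisy EIS spectra.

The camera generator emulates the acquisition used for electro-optic
characterization: a 16 x 16 antenna array at 5-um pitch imaged through a
laser-illuminated dark-field microscope at 20-2000 frames per second.  Each
antenna appears as an isotropic Gaussian spot whose intensity follows the
electro-optic digital twin under the programmed stimulus protocol.  Noise is
applied in physical order: slowly drifting speckle background (the dominant
noise source with coherent illumination, modeled as a per-pixel AR(1) random
walk), Poisson shot noise on the expected counts, Gaussian read noise, then
quantization to the camera bit depth.  Every generated stack is returned
with its full ground truth so each pipeline estimate has a programmed true
value to be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import tifffile
import yaml

from .circuit import CircuitParams, StimulusProtocol, impedance_spectrum, time_constant
from .electro_optic import SigmoidTransfer, dynamic_optical_response
from .imaging import ImageSequence

__all__ = [
    "ArrayLayout",
    "NoiseModel",
    "GroundTruth",
    "render_sequence",
    "predict_figures_of_merit",
    "synth_eis",
    "write_sequence",
    "read_sequence",
    "roundtrip_sequence",
]


@dataclass(frozen=True)
class ArrayLayout:
    """Regular antenna array as seen by the camera."""

    n_rows: int = 16
    n_cols: int = 16
    pitch: float = 5.0  # um
    pixel_size: float = 0.325  # um per pixel
    spot_sigma: float = 2.0  # px, Gaussian point-spread width
    peak_counts: float = 8000.0  # expected counts at spot center, baseline
    margin_px: int = 12

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("array must have at least one antenna")
        if self.pitch / self.pixel_size < 4:
            raise ValueError("pitch must be at least 4 pixels")
        if not self.spot_sigma > 0 or not self.peak_counts > 0:
            raise ValueError("spot_sigma and peak_counts must be > 0")

    @property
    def pitch_px(self) -> float:
        return self.pitch / self.pixel_size

    @property
    def frame_shape(self) -> Tuple[int, int]:
        h = int(np.ceil((self.n_rows - 1) * self.pitch_px)) + 2 * self.margin_px + 1
        w = int(np.ceil((self.n_cols - 1) * self.pitch_px)) + 2 * self.margin_px + 1
        return h, w

    def centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) spot centers in (row, col) pixels."""
        rr, cc = np.meshgrid(
            self.margin_px + np.arange(self.n_rows) * self.pitch_px,
            self.margin_px + np.arange(self.n_cols) * self.pitch_px,
            indexing="ij",
        )
        return np.column_stack([rr.ravel(), cc.ravel()])


@dataclass(frozen=True)
class NoiseModel:
    """Camera and illumination noise settings (counts units)."""

    read_noise_sd: float = 3.0
    shot_noise: bool = True
    background_level: float = 100.0
    speckle_drift_sd: float = 0.0  # counts per frame per pixel (random walk)
    speckle_corr: float = 0.999  # AR(1) coefficient; ~1 means slow drift
    jitter_sd: float = 0.0  # px per frame rigid jitter

    def __post_init__(self) -> None:
        for name in ("read_noise_sd", "background_level", "speckle_drift_sd", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.speckle_corr < 1.0:
            raise ValueError("speckle_corr must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Programmed truth serialized alongside every generated stack."""

    protocol: StimulusProtocol
    centers: np.ndarray  # (n, 2) px
    sensitivity: float  # programmed Z per mV at the spot mean (see notes)
    relative_amplitude_per_mv: float  # fractional intensity change per mV
    tau_ms: float
    baseline_peak_counts: float
    shifts: np.ndarray  # (n_frames, 2) applied rigid shifts, px
    snr_programmed: Optional[float] = None


def _gaussian_spot_patch(sigma: float, half: int) -> np.ndarray:
    ax = np.arange(-half, half + 1)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    return np.outer(g, g)


def render_sequence(
    layout: ArrayLayout,
    circuit: CircuitParams,
    transfer: SigmoidTransfer,
    noise: NoiseModel,
    protocol: StimulusProtocol,
    seed: int,
    bit_depth: int = 16,
) -> Tuple[ImageSequence, GroundTruth]:
    """Render a ground-truthed camera stack of a modulating antenna array.

    The expected image per frame is
    ``background + sum_antennas peak_counts * (sigma(t)/sigma(bias)) * spot``
    with sigma(t) from the electro-optic twin; noise is then applied in the
    order speckle drift -> shot -> read -> quantize.  Fully reproducible
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    half = int(np.ceil(4 * layout.spot_sigma))
    # Neighbouring spots must be separated by >= 3 sigma on each side;
    # beyond that the Gaussian tails contribute < 1e-4 of the peak.
    if layout.pitch_px < 6 * layout.spot_sigma:
        raise ValueError("spots overlap: pitch too small for spot_sigma")
    shape = layout.frame_shape
    centers = layout.centers()

    optical = dynamic_optical_response(protocol, circuit, transfer)
    sigma_bias = transfer(protocol.v_bias)
    modulation = optical.signal / sigma_bias  # relative brightness vs baseline
    n_frames = modulation.size

    patch = _gaussian_spot_patch(layout.spot_sigma, half)
    base = np.full(shape, float(noise.background_level))
    spots = np.zeros(shape)
    for r0, c0 in centers:
        r, c = int(round(r0)), int(round(c0))
        if r - half < 0 or c - half < 0 or r + half >= shape[0] or c + half >= shape[1]:
            raise ValueError("spot extends outside the frame; increase margin_px")
        spots[r - half : r + half + 1, c - half : c + half + 1] += patch

    shifts = np.zeros((n_frames, 2))
    if noise.jitter_sd > 0:
        shifts = rng.normal(0.0, noise.jitter_sd, size=(n_frames, 2))

    speckle = np.zeros(shape)
    frames = np.empty((n_frames, *shape), dtype=np.uint16)
    max_count = 2**bit_depth - 1
    from scipy import ndimage  # local import keeps module import light

    for i in range(n_frames):
        if noise.speckle_drift_sd > 0:
            speckle = noise.speckle_corr * speckle + rng.normal(
                0.0, noise.speckle_drift_sd, size=shape
            )
        expected = base + speckle + layout.peak_counts * modulation[i] * spots
        if noise.jitter_sd > 0 and np.any(shifts[i] != 0):
            expected = ndimage.shift(expected, shifts[i], order=1, mode="nearest")
        expected = np.clip(expected, 0.0, None)
        img = rng.poisson(expected).astype(float) if noise.shot_noise else expected.copy()
        if noise.read_noise_sd > 0:
            img += rng.normal(0.0, noise.read_noise_sd, size=shape)
        img = np.clip(np.round(img), 0, None)
        if np.any(img > max_count):
            raise ValueError(
                f"expected counts exceed the {bit_depth}-bit range; lower peak_counts"
            )
        frames[i] = img.astype(np.uint16)

    seq = ImageSequence(frames, protocol.sampling_rate, layout.pixel_size, bit_depth)

    # Programmed truth. The fractional intensity change per mV at the holding
    # bias follows from the transfer slope; the per-pixel Z sensitivity
    # depends on the noise realization, so the truth records the programmed
    # *relative* modulation, which the pipeline estimates via Z scores.
    dsigma_dv = transfer.slope(protocol.v_bias)  # nm^2 per V
    rel_per_mv = -dsigma_dv / sigma_bias * 1e-3  # fractional per mV, >0
    truth = GroundTruth(
        protocol=protocol,
        centers=centers,
        sensitivity=rel_per_mv,
        relative_amplitude_per_mv=rel_per_mv,
        tau_ms=time_constant(circuit) * 1e3,
        baseline_peak_counts=layout.peak_counts,
        shifts=shifts,
    )
    return seq, truth


def predict_figures_of_merit(
    layout: ArrayLayout,
    circuit: CircuitParams,
    transfer: SigmoidTransfer,
    noise: NoiseModel,
    protocol: StimulusProtocol,
    inclusion_threshold: float = 3.0,
    plateau_fraction: float = 0.5,
) -> Dict[str, float]:
    """Analytic (noise-model) prediction of the pipeline's figures of merit.

    Propagates the programmed relative modulation through the camera noise
    model pixel by pixel: a pixel with baseline expectation I has Z-score
    noise of 1 by construction and plateau response
    dZ = peak * patch * r_a / sd(I), so the mask-averaged trace has noise
    ~ 1/sqrt(n_mask) and the predicted SNR, sensitivity and LOD follow.
    These are the programmed truths that the imaging pipeline should
    recover from a rendered stack of the same configuration.
    """
    optical = dynamic_optical_response(protocol, circuit, transfer)
    sigma_bias = transfer(protocol.v_bias)
    modulation = optical.signal / sigma_bias - 1.0
    t = protocol.time

    half = int(np.ceil(4 * layout.spot_sigma))
    patch = _gaussian_spot_patch(layout.spot_sigma, half).ravel()
    base_counts = noise.background_level + layout.peak_counts * patch
    var = np.full_like(base_counts, noise.read_noise_sd**2)
    if noise.shot_noise:
        var = var + base_counts
    if noise.speckle_drift_sd > 0 and noise.speckle_corr < 1:
        var = var + noise.speckle_drift_sd**2 / (1.0 - noise.speckle_corr**2)
    sd = np.sqrt(var)

    plateau_rel: Dict[float, float] = {}
    for p in protocol.pulses:
        sel = (t >= p.onset + (1 - plateau_fraction) * p.duration) & (
            t < p.onset + p.duration
        )
        plateau_rel[p.amplitude] = float(modulation[sel].mean())
    r_max = max(abs(r) for r in plateau_rel.values())
    z_amp_max = layout.peak_counts * patch * r_max / sd
    mask = z_amp_max > inclusion_threshold
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("no pixel exceeds the inclusion threshold; raise peak_counts")

    z_plateau = {
        a: float((layout.peak_counts * patch[mask] * r / sd[mask]).mean())
        for a, r in plateau_rel.items()
    }
    trace_noise = 1.0 / np.sqrt(n_mask)
    amp_mv = np.array([abs(a) * 1e3 for a in z_plateau])
    z = np.array(list(z_plateau.values()))
    slope, intercept = np.polyfit(amp_mv, z, 1)
    z_100 = (
        float(np.mean([z_plateau[a] for a in z_plateau if abs(abs(a) - 0.1) < 1e-9]))
        if any(abs(abs(a) - 0.1) < 1e-9 for a in z_plateau)
        else float(slope * 100.0 + intercept)
    )
    return {
        "sensitivity": float(slope),
        "noise": float(trace_noise),
        "snr": float(z_100 / trace_noise),
        "lod_mv": float(trace_noise / slope),
        "n_mask": float(n_mask),
    }


def synth_eis(
    params: CircuitParams,
    noise_frac: float = 0.0,
    n_freq: int = 30,
    seed: int = 0,
    f_min: float = 1.0,
    f_max: float = 1e5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Noisy single-time-constant EIS spectrum on a log-spaced grid.

    Returns (frequencies_hz, complex_impedance); multiplicative complex
    Gaussian noise of relative SD ``noise_frac`` models instrument error.
    """
    if n_freq < 5:
        raise ValueError("n_freq must be >= 5")
    rng = np.random.default_rng(seed)
    f = np.logspace(np.log10(f_min), np.log10(f_max), n_freq)
    z = impedance_spectrum(params, f)
    if noise_frac > 0:
        z = z * (
            1.0
            + noise_frac * rng.standard_normal(n_freq)
            + 1j * noise_frac * rng.standard_normal(n_freq)
        )
    return f, z


def write_sequence(seq: ImageSequence, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    if seq.frames.dtype != np.uint16:
        if np.any(seq.frames > 2**seq.bit_depth - 1):
            raise ValueError("counts exceed the stack's bit depth; refusing to wrap")
        frames = seq.frames.astype(np.uint16)
    else:
        frames = seq.frames
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "format_version": 1,
                "frame_rate_fps": float(seq.frame_rate),
                "pixel_size_um": float(seq.pixel_size),
                "bit_depth": int(seq.bit_depth),
                "n_frames": int(seq.n_frames),
            }
        )
    )
    return path


def read_sequence(path: str | Path) -> ImageSequence:
    """Read a multi-page TIFF stack with its YAML metadata sidecar."""
    path = Path(path)
    frames = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    meta = yaml.safe_load(sidecar.read_text())
    return ImageSequence(
        frames,
        frame_rate=float(meta["frame_rate_fps"]),
        pixel_size=float(meta["pixel_size_um"]),
        bit_depth=int(meta["bit_depth"]),
    )


def roundtrip_sequence(seq: ImageSequence, path: str | Path) -> ImageSequence:
    """Write then re-read a stack; frames are bit-identical by contract."""
    return read_sequence(write_sequence(seq, path))
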