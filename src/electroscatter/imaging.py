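"""Electro-optic characterization of antenna arrays from camera stacks.

The measurement chain implemented here mirrors standard practice for
scattering-based voltage imaging: rigid registration of the raw stack,
per-pixel Z scoring against a stimulus-free baseline window, segmentation of
each antenna inside a circular region of interest by thresholding the
Z-score excursion, and extraction of per-antenna figures of merit:

* sensitivity  - slope of the plateau Z response versus stimulus amplitude
  (Z per mV),
* noise        - SD of the Z-score trace over a 1-s stimulus-free window,
* SNR          - plateau Z response to a 100-mV stimulus divided by noise,
* LOD          - noise / sensitivity, the stimulus amplitude at SNR = 1 (mV),
* tau          - single-exponential rise time constant of the response (ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.registration import phase_cross_correlation

from .circuit import StimulusProtocol

__all__ = [
    "ImageSequence",
    "RoiSpec",
    "ZScoreTrace",
    "ElectroOpticSummary",
    "BoxChart",
    "register_translation",
    "pixel_zscores",
    "extract_antenna_trace",
    "plateau_response",
    "characterize",
    "characterize_stack",
    "fit_time_constant",
    "summarize_boxchart",
]


@dataclass
class ImageSequence:
    """Camera stack (time x rows x cols) of non-negative counts."""

    frames: np.ndarray
    frame_rate: float  # fps
    pixel_size: float  # um per pixel
    bit_depth: int = 16

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise ValueError("frames must be a (time, rows, cols) stack with >= 2 frames")
        if np.any(frames < 0):
            raise ValueError("camera counts must be non-negative")
        if not self.frame_rate > 0 or not self.pixel_size > 0:
            raise ValueError("frame_rate and pixel_size must be > 0")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class RoiSpec:
    """Circular region of interest around one antenna (pixel units)."""

    center: Tuple[float, float]  # (row, col)
    radius: float = 20.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be > 0")

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        r0, c0 = self.center
        if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
            raise ValueError("ROI center outside the frame")
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius**2


@dataclass
class ZScoreTrace:
    """Per-antenna Z-score time series with its contributing pixel mask."""

    time: np.ndarray
    z: np.ndarray
    pixel_mask: np.ndarray  # boolean, frame-shaped
    roi: RoiSpec

    @property
    def has_responsive_pixels(self) -> bool:
        return bool(self.pixel_mask.any())


@dataclass(frozen=True)
class ElectroOpticSummary:
    """Figures of merit for one antenna."""

    sensitivity: float  # Z per mV
    noise: float  # Z units
    snr: float  # dimensionless
    lod: Optional[float]  # mV; None when sensitivity <= 0
    tau_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.noise > 0:
            raise ValueError("noise must be > 0")


def register_translation(
    seq: ImageSequence, reference: int = 0, upsample_factor: int = 20
) -> Tuple[ImageSequence, np.ndarray]:
    """Align every frame to a reference frame by subpixel rigid translation.

    Shifts are estimated by phase correlation and applied in the Fourier
    domain (exact subpixel translation, no interpolation smoothing of the
    pixel noise, periodic boundary); the per-frame (row, col) shifts that
    were applied are returned alongside the registered stack.
    """
    frames = np.asarray(seq.frames, dtype=float)
    ref = frames[reference]
    if np.ptp(ref) == 0:
        raise ValueError("reference frame is featureless (zero variance)")
    shifts = np.zeros((seq.n_frames, 2))
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        if i == reference:
            out[i] = frame
            continue
        if np.ptp(frame) == 0:
            raise ValueError(f"frame {i} is featureless (zero variance)")
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        shifts[i] = shift
        shifted = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(frame), shift)).real
        out[i] = np.clip(shifted, 0.0, None)
    registered = ImageSequence(out, seq.frame_rate, seq.pixel_size, seq.bit_depth)
    return registered, shifts


def pixel_zscores(
    seq: ImageSequence, baseline: Tuple[int, int]
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel Z scores z(t) = (x(t) - mu_baseline) / sd_baseline.

    ``baseline`` is a stimulus-free frame-index window [start, stop).
    Returns (zstack, valid) where ``valid`` marks pixels with non-zero
    baseline variance; invalid pixels hold zeros in the stack and must be
    excluded downstream rather than NaN-propagated.
    """
    b0, b1 = baseline
    if not (0 <= b0 < b1 <= seq.n_frames):
        raise ValueError("baseline window out of range")
    if b1 - b0 < 10:
        raise ValueError("baseline window must contain at least 10 frames")
    frames = np.asarray(seq.frames, dtype=np.float64)
    mu = frames[b0:b1].mean(axis=0)
    sd = frames[b0:b1].std(axis=0, ddof=0)
    valid = sd > 0
    sd_safe = np.where(valid, sd, 1.0)
    z = (frames - mu) / sd_safe
    z[:, ~valid] = 0.0
    return z.astype(np.float32), valid


def extract_antenna_trace(
    zstack: np.ndarray,
    roi: RoiSpec,
    frame_rate: float,
    stimulation_window: Optional[Tuple[int, int]] = None,
    inclusion_threshold: float = 3.0,
    valid: Optional[np.ndarray] = None,
    stat: str = "mean",
) -> ZScoreTrace:
    """Mean Z-score trace over the responsive pixels of one antenna.

    A pixel inside the circular ROI belongs to the antenna when its Z-score
    variation during the stimulation window exceeds ``inclusion_threshold``.
    The variation statistic is the |mean| Z over the window by default
    (robust: a true response of amplitude 3 is ~30 baseline-SD above the
    statistic's own noise for a 100-frame window); ``stat="max"`` selects
    the literal per-frame maximum |Z|, which for long windows also trips on
    pure noise pixels.  Pass the settled plateau of the strongest stimulus
    as the window.  An empty mask yields a trace with
    ``has_responsive_pixels`` False (explicitly distinct from a zero trace).
    """
    n_frames = zstack.shape[0]
    shape = zstack.shape[1:]
    roi_mask = roi.mask(shape)
    if valid is not None:
        roi_mask &= valid
    s0, s1 = stimulation_window if stimulation_window is not None else (0, n_frames)
    if stat == "mean":
        excursion = np.abs(zstack[s0:s1].mean(axis=0))
    elif stat == "max":
        excursion = np.abs(zstack[s0:s1]).max(axis=0)
    else:
        raise ValueError("stat must be 'mean' or 'max'")
    pixel_mask = roi_mask & (excursion > inclusion_threshold)
    time = np.arange(n_frames) / frame_rate
    if not pixel_mask.any():
        return ZScoreTrace(time, np.zeros(n_frames), pixel_mask, roi)
    trace = zstack[:, pixel_mask].mean(axis=1)
    return ZScoreTrace(time, np.asarray(trace, dtype=float), pixel_mask, roi)


def plateau_response(
    trace: ZScoreTrace, protocol: StimulusProtocol, plateau_fraction: float = 0.5
) -> Dict[float, float]:
    """Mean Z over the settled tail of each pulse, keyed by amplitude (V).

    The plateau is the final ``plateau_fraction`` of each pulse, where the
    1-s pulses have settled (pulse length >> circuit time constant).
    """
    out: Dict[float, float] = {}
    for p in protocol.pulses:
        t0 = p.onset + (1.0 - plateau_fraction) * p.duration
        t1 = p.onset + p.duration
        sel = (trace.time >= t0) & (trace.time < t1)
        if not sel.any():
            raise ValueError("no samples in the plateau window; check frame rate")
        out[p.amplitude] = float(trace.z[sel].mean())
    return out


def characterize(
    responses: Dict[float, float],
    noise_trace: np.ndarray,
    reference_amplitude_mv: float = 100.0,
    tau_ms: Optional[float] = None,
) -> ElectroOpticSummary:
    """Figures of merit from plateau responses and a stimulus-free segment.

    Parameters
    ----------
    responses:
        Plateau Z response per stimulus amplitude (amplitude in V; negative
        pulses give positive Z).  At least 3 distinct amplitudes.
    noise_trace:
        Z-score samples over a >= 1-s stimulus-free window.
    reference_amplitude_mv:
        Stimulus magnitude defining the SNR (100 mV by convention).

    Sensitivity is the least-squares slope of plateau Z versus stimulus
    magnitude in mV (|amplitude|, since the response polarity is opposite
    to the pulse).  SNR uses the response at the reference amplitude,
    interpolated from the linear fit when that amplitude was not applied.
    LOD = noise / sensitivity, undefined (None) for non-positive sensitivity.
    """
    if len(responses) < 3:
        raise ValueError("need >= 3 distinct stimulus amplitudes for the linear fit")
    noise_trace = np.asarray(noise_trace, dtype=float)
    if noise_trace.size < 2:
        raise ValueError("noise trace too short")
    noise = float(noise_trace.std(ddof=0))
    if noise <= 0:
        raise ValueError("noise trace has zero variance")

    amp_mv = np.array([abs(a) * 1e3 for a in responses])  # mV
    z = np.array([responses[a] for a in responses])
    slope, intercept = np.polyfit(amp_mv, z, 1)
    sensitivity = float(slope)

    ref_amps = [a for a in responses if abs(abs(a) * 1e3 - reference_amplitude_mv) < 1e-6]
    if ref_amps:
        z_ref = float(np.mean([responses[a] for a in ref_amps]))
    else:
        z_ref = float(slope * reference_amplitude_mv + intercept)
    snr = z_ref / noise
    lod = noise / sensitivity if sensitivity > 0 else None
    return ElectroOpticSummary(sensitivity, noise, snr, lod, tau_ms)


def fit_time_constant(
    trace: ZScoreTrace | Tuple[np.ndarray, np.ndarray],
    onset: float,
    window: Optional[float] = None,
) -> float:
    """Exponential-rise time constant (ms) of a step response.

    Fits A * (1 - exp(-(t - onset)/tau)) by least squares on
    [onset, onset + 5*tau_hat], where tau_hat is first estimated from the
    63.2% crossing and the window is refined once.  Raises RuntimeError on
    non-convergence.
    """
    if isinstance(trace, ZScoreTrace):
        t, y = trace.time, trace.z
    else:
        t, y = np.asarray(trace[0], float), np.asarray(trace[1], float)
    after = t >= onset
    if after.sum() < 5:
        raise ValueError("need >= 5 samples after onset")
    ta, ya = t[after] - onset, y[after]
    dt = np.median(np.diff(t))

    # Initial tau from the 1 - 1/e crossing of a smoothed trace.
    plateau = np.median(ya[ta >= 0.5 * ta.max()]) if ta.max() > 0 else ya[-1]
    if plateau == 0:
        plateau = ya.max() if ya.max() != 0 else 1.0
    crossing = np.nonzero(ya >= (1 - np.exp(-1)) * plateau)[0]
    tau0 = max(ta[crossing[0]], dt / 2) if crossing.size else max(ta.max() / 5, dt / 2)

    def model(tt, a, tau):
        return a * (1.0 - np.exp(-tt / tau))

    tau_hat = tau0
    for _ in range(2):  # fit, then refine the window once
        sel = ta <= 5.0 * tau_hat
        if sel.sum() < 5:
            sel = np.zeros_like(ta, dtype=bool)
            sel[:5] = True
        try:
            popt, _ = curve_fit(
                model,
                ta[sel],
                ya[sel],
                p0=[plateau, tau_hat],
                bounds=([-np.inf, dt * 1e-6], [np.inf, np.inf]),
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"time-constant fit did not converge: {exc}") from exc
        tau_hat = float(popt[1])
    return tau_hat * 1e3


def characterize_stack(
    seq: ImageSequence,
    centers: Sequence[Tuple[float, float]],
    protocol: StimulusProtocol,
    baseline_window: Optional[Tuple[int, int]] = None,
    roi_radius: float = 20.0,
    inclusion_threshold: float = 3.0,
    reference_amplitude_mv: float = 100.0,
) -> List[Optional[ElectroOpticSummary]]:
    """Full per-antenna characterization of a registered stack.

    Z scores each pixel against the baseline window (default: the second
    preceding the first pulse), segments each antenna on the settled
    plateau of the strongest pulse, and extracts the figures of merit.
    Antennas without responsive pixels yield None.
    """
    if baseline_window is None:
        first_onset = min(p.onset for p in protocol.pulses)
        b1 = int(first_onset * seq.frame_rate)
        b0 = max(0, b1 - int(round(seq.frame_rate)))
        baseline_window = (b0, b1)
    zstack, valid = pixel_zscores(seq, baseline_window)
    strongest = max(protocol.pulses, key=lambda p: abs(p.amplitude))
    s0 = int((strongest.onset + 0.5 * strongest.duration) * seq.frame_rate)
    s1 = int((strongest.onset + strongest.duration) * seq.frame_rate)
    noise_slice = slice(*baseline_window)
    out: List[Optional[ElectroOpticSummary]] = []
    for center in centers:
        roi = RoiSpec((float(center[0]), float(center[1])), radius=roi_radius)
        trace = extract_antenna_trace(
            zstack,
            roi,
            seq.frame_rate,
            (s0, s1),
            inclusion_threshold,
            valid=valid,
        )
        if not trace.has_responsive_pixels:
            out.append(None)
            continue
        responses = plateau_response(trace, protocol)
        out.append(
            characterize(responses, trace.z[noise_slice], reference_amplitude_mv)
        )
    return out


@dataclass(frozen=True)
class BoxChart:
    """Tukey box-chart summary of a sample."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple = field(default_factory=tuple)


def summarize_boxchart(values: Sequence[float]) -> BoxChart:
    """Median, linear-interpolation quartiles, 1.5*IQR whiskers, outliers."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 values for a box chart")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(sorted(v[(v < lo_fence) | (v > hi_fence)].tolist()))
    return BoxChart(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inliers.min()),
        whisker_hi=float(inliers.max()),
        outliers=outliers,
    )
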