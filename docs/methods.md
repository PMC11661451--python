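# Methods

This note records the models implemented in `electroscatter`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Electro-optic model chain

### Doping-dependent permittivity

PEDOT:PSS switches between a metallic-like doped state and a dielectric
dedoped state as holes are injected or extracted. The two endpoint
permittivities are parameterized in photon energy (E [eV] = 1239.84193/λ [nm]):

- **Doped:** Drude, ε(E) = ε∞ − E_p²/(E² + iEΓ).
- **Dedoped:** ε∞ plus Lorentz terms A·E₀²/(E₀² − E² − iBE) and Tauc-Lorentz
  terms, whose ε₂ vanishes below the gap energy and whose ε₁ is the
  closed-form Kramers-Kronig transform (valid for width < 2·E₀; the
  implementation is verified against direct principal-value integration to
  better than 0.5%).

Both endpoint permittivities vary linearly with their carrier densities, so
intermediate doping c mixes them linearly, and the bias-to-doping map is a
logistic c(V) = 1/(1 + exp(−(V − V_half)/w)) with V_half = −0.35 V vs
Ag/AgCl and w = 0.12 V. The logistic is the minimal monotone saturating
form; the defaults place the steepest brightness change between −0.3 and
−0.4 V and the model sensitivity peak near −0.5 V, as observed for real
devices.

**Default oscillator parameters** (in `data/default_model.yaml`) are
literature-informed stand-ins, not fits to any specific film:

| parameter | value | rationale |
|---|---|---|
| Drude ε∞, E_p, Γ | 2.2, 1.36 eV, 0.8 eV | weak free-carrier metal; n(640 nm) ≈ 1.34, close to water — the doped antenna is nearly index-matched, which is what makes the dedoping contrast large |
| dedoped ε∞ | 1.8 | visible-range background |
| Lorentz (A, E₀, B) | 0.6, 4.5 eV, 0.5 eV | UV bound-electron response |
| Tauc-Lorentz (A, E₀, C, E_g) | 3.0 eV, 2.4 eV, 1.0 eV, 1.55 eV | neutral-polymer π–π* absorption edge; gives n(640 nm) ≈ 1.7 when dedoped |

All downstream acceptance properties are parameter-robust trends
(monotonicity, peak-location windows, endpoint identities), not absolute
values; anyone with ellipsometry data for their film should replace these
defaults.

### Scattering surrogate

The full-wave electromagnetic problem (mushroom on a layered substrate
under evanescent illumination) is out of scope. The surrogate treats the
antenna as a homogeneous sphere in water (ε = 1.77) whose volume equals the
hemispherical cap plus the cylindrical stem, and evaluates the Mie series
with relative index m = (n + ik)/n_water. Consequences:

- monotone trends (bias dependence, cap-size dependence, sensitivity peak
  location) are preserved and tested;
- absolute σ_sc values and spectral fine structure are **not** faithful to
  the on-substrate device and are not asserted anywhere;
- all scattering angles are integrated; collection-NA weighting is ignored.

The Mie coefficients use the logarithmic derivative D_n(mx) by downward
recurrence (stable for absorbing spheres), Riccati-Bessel functions of the
real argument by upward recurrence, and the Wiscombe truncation
n_max = x + 4x^{1/3} + 2; truncation convergence is verified to 1e-6 and the
x ≤ 0.1 limit against the Rayleigh closed form to 1%.

### Interface circuit and digital twin

The antenna–electrolyte interface is a series R_s–R_P–C_P chain, the unique
minimal circuit consistent with a single-exponential step response of
τ = (R_s + R_P)·C_P. The transferred (electro-optically active) voltage is
read across C_P and computed analytically per pulse edge by superposition;
the analytic trace matches a stiff ODE integration to 1e-6.

Only R_s + R_P is identifiable from an impedance spectrum of this topology,
so `fit_eis` fits (R_total, C_P) in joint log-magnitude/phase space and
apportions R_total using an optionally supplied, independently measured
R_s. A spectrum with no capacitive feature inside the measured band (e.g. a
pure resistor, which the model mimics exactly as C → ∞) is reported as
degenerate rather than fitted silently.

Default circuit values reproduce the measured charging time constants (6.0,
34.7, 233.9 ms for 0.7, 1.4, 1.8 µm caps) with C_P scaling with polymer
volume; they are order-of-magnitude defaults, not device fits. An optional
bias-dependent series resistance R_P(V) = R_P0·(1 + κ·(1 − c)) is exposed
with κ = 0 by default, since dedoping-induced resistance growth is known
only qualitatively.

The digital twin composes the static sigmoid transfer σ(V) — decreasing,
because dedoping at negative voltage brightens the antenna — with the
transferred-voltage trace: σ(t) = σ(V_C(t)). The sigmoid is evaluated on
the *transferred* voltage, consistent with interpolating cross sections at
the voltage levels actually reached at each time point. For small signals
the optical rise time equals the circuit τ within 2% (tested).

## Cell–sensor interface

The membrane model is the original Luo-Rudy 1991 ventricular action
potential (six currents, Hodgkin-Huxley gating, simple calcium pool) with
the original parameter set; the implementation rests at −84.54 mV
(published value −84.5 mV) and reproduces >100 mV/ms upstrokes. The
stimulus default is a 1-ms, −40 µA/cm² rectangular pulse; solver restarts
at the pulse edges keep the stiff integrator (LSODA) from stepping over
them.

The coupling is one-way (sensor impedances are orders of magnitude above
membrane impedance): v_m drives the cleft through R_j = 500 MΩ, the cleft
leaks to the bath through R_Seal = 200 MΩ, and the sensor branch
(R_s + R_P + C_P from cleft to ground) loads the node. The reported sensor
voltage is the drop across the polymer element (R_P + C_P). Defaults for
the single-antenna branch are derived from stated quantities: C_P ≈ 28 pF
(volumetric capacitance ≈ 39 F/cm³ × 1.4-µm hemispherical cap volume) and
R_P ≈ 1.2 GΩ (fixed by the measured 34.7-ms time constant). With these
defaults the transferred amplitude is ≈ 32 mV: the DC divider passes
2/7 ≈ 0.286 of the 126.6-mV action potential, and the branch loading shaves
the fastest (millisecond) part of the Na⁺ upstroke. In the
`sensor_circuit=None` (infinite-impedance) limit the closed-form divider is
recovered exactly, and is tested against the dynamic solution at C_P → 0.

Junctional membrane capacitance and cleft capacitance are taken as zero
(purely resistive divider with RC loading); both would further low-pass the
upstroke.

## Imaging pipeline

- **Registration:** rigid translation by phase correlation, applied in the
  Fourier domain. Fourier translation is exact and variance-preserving;
  interpolation-based shifting smooths the pixel noise, deflates the
  baseline SD and inflates Z-score sensitivities by ~7%, which would break
  the 5% registration-invariance requirement. Rotation and shear are out
  of scope.
- **Z scores:** per pixel against a stimulus-free baseline window (default:
  the second preceding the first pulse; at least 10 frames). Pixels with
  zero baseline variance are flagged invalid and excluded, never
  NaN-propagated.
- **Segmentation:** pixels inside a circular ROI (default radius 20 px)
  whose Z-score variation during stimulation exceeds 3 belong to the
  antenna. The variation statistic is |mean z| over the settled plateau of
  the strongest pulse. The per-frame max |z| reading is also available
  (`stat="max"`), but for windows of ~10³ frames pure noise pixels exceed 3
  with ~98% probability, so the max statistic dilutes the antenna trace
  with background pixels roughly two-fold; the plateau mean is a ~30σ
  discriminator at the same threshold.
- **Figures of merit:** sensitivity is the least-squares slope of plateau Z
  (mean over the final 50% of each 1-s pulse, which is ≫ τ) versus stimulus
  magnitude in mV; noise is the SD of the trace over the stimulus-free
  baseline second; SNR divides the 100-mV response (interpolated from the
  fit if 100 mV was not applied) by the noise; V_LOD = noise/sensitivity
  exactly. Exponential rise times are fitted as A(1 − e^{−t/τ}) on
  [onset, onset + 5τ̂] with one window refinement; box charts use linear
  interpolation quartiles and 1.5×IQR Tukey fences.

## Synthetic data

The generator emulates the characterization acquisitions: 16×16 arrays at
5-µm pitch, isotropic Gaussian spots (σ = 2 px at 0.325 µm/px), frame rates
20–2000 fps, 16-bit counts. Noise is applied in physical order: slowly
drifting speckle background (per-pixel AR(1), correlation 0.995, innovation
0.2 counts — the dominant noise source of coherent-illumination scattering
setups, with magnitudes chosen only to make recovery tests meaningfully
noisy, since no measured value exists), Poisson shot noise, Gaussian read
noise (3 counts), quantization. Identical seeds give bit-identical stacks.

The reference stack for recovery testing uses peak counts of 1200, which
puts the predicted SNR at a 100-mV pulse near 50 and the predicted LOD near
2 mV — the regime of the characterized devices. `predict_figures_of_merit`
computes the programmed sensitivity/noise/SNR/LOD analytically from the
noise model (per-pixel Z response = peak·patch·Δrel/sd, mask-averaged,
trace noise 1/√n_mask); these are the ground truths the pipeline recovers
within 10–15%.

What the generator does **not** emulate: diffraction ring structure (spots
are Gaussian), cell silhouettes, common-mode speckle correlations across
pixels, illumination drift of the laser line, and nonstationary noise. A
green recovery test therefore establishes correctness of the pipeline
arithmetic and its robustness to stationary per-pixel noise and rigid
jitter — not performance on a real microscope's correlated background.

## Numerical notes

- Tauc-Lorentz ε₁ is evaluated with a 1e-9 eV guard at the gap edge where
  the closed form has a removable logarithmic singularity.
- The logistic calibration uses `scipy.special.expit` (overflow-safe).
- LR91 gate variables are clipped to [0, 1] when reconstructing states from
  solver vectors; solvers overshoot bounds only by rounding error.
- `fit_time_constant` seeds τ from the 63.2% crossing and refines the fit
  window once; an instantaneous step yields τ below one frame period.
- Mie size parameters relevant here are x ≈ 2–8; downward recurrence starts
  ≥ 16 orders above the Wiscombe cutoff.

## Known limitations

- Absolute scattering cross sections carry the volume-equivalent-sphere
  approximation; only trends are quantitative.
- The EIS model has no constant-phase element, Warburg diffusion, or
  faradaic branch; cyclic-voltammetry currents are out of scope.
- Electro-optic hysteresis/memory effects are not modeled; σ(V) is
  single-valued.
- The cell model is a single cell, one-way coupled; electroporation and
  engulfment mechanics are out of scope.
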