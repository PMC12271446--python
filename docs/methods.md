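# Methods

`octflow` implements three quantitative flow estimators for spectral-domain
OCT of microfluidic devices — number-fluctuation DLS-OCT, PIV-OCT and
phase-resolved Doppler OCT — together with a particle-level signal
simulator.  The simulator is the package's validation instrument: every
estimator is tested by recovering known velocity fields from synthetic
data, with no external data required.

## Signal model and PSF conventions

The simulator represents a dilute suspension of point scatterers advected
through a prescribed flow field (uniform, rectangular-duct Poiseuille, or
gridded).  The detected complex OCT field at lateral pixel x, physical
depth z and frame t is

    a(x, z, t) = Σ_j A_j · exp(−2((x−x_j)² + y_j²)/w_r(z_j)²)
                        · exp(−(z−z_j)²/w_z²) · exp(i·4π·n_k·z_j/λ₀)
                 + noise,

where `w_r(z)` is the e⁻¹ radius of the Gaussian **field** profile of the
beam mode and `w_z` the axial coherence waist.  Two convention choices are
load-bearing and fixed deliberately:

* **Lateral: confocal double pass.**  The same mode illuminates and
  collects, so the detected field from a scatterer at lateral offset r is
  attenuated by `exp(−2r²/w_r²)` (amplitude e⁻² at one beam radius).  The
  intensity autocovariance of a particle transit then decays as
  `exp(−2v²cos²θ·τ²/w_r²)` — the factor 2 in the model the speed fit uses.
  A single-pass convention would produce `exp(−v²τ²/w_r²)` and bias every
  recovered speed by √2.
* **Axial: single coherence gate**, detected field `exp(−Δz²/w_z²)`, giving
  the autocovariance decay `exp(−v²sin²θ·τ²/w_z²)`.

With these two conventions the matched-apodization condition
`√2·w_z(z) = w_r(z)` collapses the decay exponent to `2/w_r²` for every
flow direction — verified numerically in the test suite (in-plane vs axial
fits at equal speed agree within a few percent), which is the package's
justification for the two-parameter speed fit.

Both a k-space path (`synthesize_spectra` → `reconstruct_fixed`/
`reconstruct_depth_matched`) and a direct path
(`synthesize_complex_series`) exist; they agree to ~1e-5 relative RMS on
identical inputs.  The spectral grid holds 2·n_axial uniform wavenumber
samples centred on 2π/λ₀ with spacing δk = π/(M·Δz_opt); the Gaussian
spectral window `exp(−(k−k_c)²/2σ_k²)` (truncated at ±4σ_k) yields an
axial field envelope of e⁻¹ half-width `w_z = 1/(√2·σ_k·n_k)` in physical
depth, and the reconstructed carrier phase advances at `4π·n_k/λ₀` per
unit physical depth (so the per-frame phase of an axially moving particle
is `4π·n_k·v_z·Δt/λ₀`).

## Study conditions (simulator defaults)

* Geometry: 200×1024 px B-scans, Δx = 15.6 µm, Δz = 1.8 µm optical,
  Δt = 40 ms, 2000 frames, 5.5 kHz line rate (DLS/PIV) — the acquisition
  this toolkit targets; recovery studies shrink the lateral extent
  (32 px) and the axial slab (10–64 px) to keep runs at desk scale,
  which reduces statistics but changes no estimator property.
* Beam: w₀ = 6 µm focal e⁻¹ field radius, Rayleigh-type range
  z_R = πw₀²n/λ ≈ 167 µm; matched waists `w_z = w_r/√2` throughout.
* Tracers: number density 3.3·10⁻³ µm⁻³, i.e. N ≈ 0.5 particles per e⁻²
  scattering volume (≈150 µm³ at focus) — the dilute regime where number
  fluctuations dominate; consistent with a 0.005–0.01 % volume fraction of
  ~0.4 µm tracers.  Unit scattering amplitudes (monodispersity).
* Noise: additive circular Gaussian complex noise in the reconstructed
  domain; SNR is defined as peak single-particle intensity over noise
  variance (default 10).  Note the per-voxel mean-intensity SNR that
  `estimate_snr` reports equals ≈ N·SNR_config under this definition.
* Advection: forward Euler at the frame interval, exact for uniform
  fields; 10 sub-steps when the per-frame displacement exceeds w₀/4.
  Particles leaving the box re-inject at the opposite face with fresh
  transverse coordinates (stationary concentration, constant count).
* Brownian motion is **off** by default: at Δt = 40 ms the diffusive
  (Gaussian-speckle) decay completes within one lag in the targeted
  experiments, so it carries no information; an optional diffusion term
  (D in µm²/s) exists and is used by the amplitude-consistency test
  (D = 2.2 µm²/s, Stokes–Einstein for 0.2 µm tracers in water).
* Intra-frame A-scan timing is neglected (all A-scans of a frame share
  one time stamp): the window acquisition time (0.7 ms) is three orders
  below the shortest correlation separations used.

### Scan orientation of in-plane flows

For uniform in-plane scenarios the transverse velocity component points
through the B-scan plane (y) by default.  With flow along the scan
direction the whole image shares one frozen, convected speckle history:
per-voxel g₂ estimates are strongly correlated across the image and the
nonlinear fit acquires a systematic low bias (measured ≈ −10 % at
200 µm/s with 2000 frames) that longer records reduce only slowly.
Scanning across the flow — the usual channel-width geometry — gives every
lateral pixel an independent history and unbiased recovery.  PIV
scenarios necessarily keep the along-scan orientation.

## Number-fluctuation DLS-OCT

`compute_g2` estimates `g₂(τ) = ⟨δI(t)δI(t+τ)⟩/⟨I⟩²` per voxel with
unbiased per-lag averaging (divide by n−j), lag 0 excluded (noise spike).
The autocovariance (not autocorrelation) form is used so the model decays
to zero.  `fit_g2` fits `A·exp(−2v₀²τ²/w_r(z)²)` by nonlinear least
squares over the first 32 lags (or until g₂ < 0.05·A, whichever is
later), initialising A from the first lag and v₀ from the first lag below
A/e, with v₀ ≥ 0.  A non-positive first lag short-circuits to v₀ = 0
(static voxel).

Identifiability: the fit carries speed information only while the decay
is sampled, i.e. v ≲ w_r/(√2·Δt) (≈106 µm/s at w_r = 6 µm, Δt = 40 ms).
`build_speed_map` therefore masks voxels whose fitted model has already
decayed into the residual noise at the first lag
(model(τ₁) ≤ 2·residual RMS), along with non-converged fits and voxels
below the SNR threshold (default 3).  Direction-independence studies at
200 µm/s use a 12 µm waist so the decay spans the first lags.

The full forward model (`eval_nf_model`) with field kurtosis κ, SNR and
mean particle number N is kept for validation only — its amplitude
pre-factors are absorbed into A for speed maps.  Useful identities that
the tests exercise: with N = c·V_eff (V_eff the intensity-PSF volume over
its peak), the noise-free field kurtosis is κ = 2 + 1/(2^{3/2}N), and the
model's amplitude equals the number-fluctuation fraction of the intensity
variance; converting it from a variance normalization to the package's
⟨I⟩² normalization multiplies by (κ−2+(1+1/SNR)²)/(1+1/SNR)².

## PIV-OCT

Intensity frames are tiled into non-overlapping 4×32-px windows anchored
at pixel (0,0); edge remainders are discarded.  For every window and
frame pair (t, t+NΔt) the normalized unbiased cross-covariance is
computed (window mean and σ per frame; out-of-window samples excluded;
per-sample normalization by (W_x−|m|)(W_z−|n|)), averaged over all
available pairs, and the integer argmax converts to velocity via
`v_x = m·Δx/(NΔt)`, `v_z = n·Δz/(n_k·N·Δt)`.  Defaults N = 5 (axial),
N = 20 (lateral), N = 15 for both inside a configured center region.
Reported velocities are exact integer multiples of these quanta;
sub-pixel (3-point parabolic) refinement exists but is off by default.

The peak search inside `run_piv` is restricted to half the window size:
the unbiased normalization divides extreme-shift cells by a handful of
samples, making them noise-dominated — and for static or frozen speckle
those cells are *persistent*, so temporal averaging cannot suppress them.
The measurable lateral speed at N = 20 is correspondingly
≤ (W_x/2)·Δx/(NΔt) ≈ 39 µm/s; faster flows need smaller N (the reason
the center region uses N = 15).  Ties take the first maximum in row-major
order and are flagged ambiguous.

## Phase-resolved Doppler OCT

`kasai_phase` forms the lag-1 complex autocorrelation
`Δφ = arg Σ a(t+τ_A)·conj(a(t))` with complex-sum averaging over
n_avg = 20 repeats; `phase_to_axial_velocity` applies
`v_axial = λ₀·Δφ/(4π·n_k·τ_A)`.  The configured Doppler angle is the
**in-air** alignment angle; a flat observation window normal to the beam
refracts it to `θ_med = arcsin(sin θ_air/n_k)` and
`speed = v_axial/sin θ_med` (θ is the tilt out of the transverse plane,
so sin θ is the axial projection).  At 10.5° in air and n_k = 1.33 the
projection factor is 0.1370.  Voxels at the ±π wrapping limit are masked;
the Nyquist speed λ₀/(4·n_k·τ_A) ≈ 6.09 mm/s at 36 kHz and 900 nm.
Axial 1-D unwrapping is available but off by default.

End-to-end Doppler recovery is validated against the analytic duct
profile using a per-voxel phasor-ramp synthesizer driven by the
ground-truth axial velocity: this isolates the estimator chain (phase →
velocity → refraction/angle correction) from speckle statistics, where
the noiseless recovery is exact and SNR-10 recovery with 20 averages
stays within a few percent RMS.  Particle-level phase fidelity is tested
separately (inter-frame phase of a moving scatterer).

## Reconstruction and beam calibration

`reconstruct_depth_matched` assembles, for each axial pixel, the row of a
full reconstruction windowed at that pixel's σ_k(z) = 1/(n_k·w_r(z)).  An
accuracy-equivalent coarse-σ_k mode (`n_levels`) reconstructs one
transform per level with nearest-level row assignment; it agrees with the
exact path to <1 % field RMS on reflector stacks (the check the suite
performs; a full fitted-speed comparison between the two paths would
dominate the suite's runtime and adds no information at that agreement
level).

Beam calibration estimates w_r(z) from a zero-flow acquisition as the
e⁻¹ radius of the magnitude of the lateral complex-field autocovariance
per depth, fitted over lags ≥ 1 (lag 0 carries noise power).  Under the
double-pass PSF the fitted radius *is* w_r — convention constant 1.0,
frozen by a regression test against simulated ground truth.  Depths with
fewer than 50 independent speckles or no lateral correlation support
(pure noise) are flagged.  Calibration needs the lateral pitch to sample
the beam (scenarios use 1.5 µm; a 15.6 µm pitch undersamples a 6 µm
beam).  `fit_beam_profile` then fits `w₀√(1+(z−z₀)²/z_R²)` by least
squares.

## Degenerate inputs and numerical choices

Zero-mean intensity voxels are flagged invalid (NaN) by `compute_g2`;
zero-variance PIV windows are flagged invalid; zero Kasai autocorrelation
masks the voxel.  The dB conversion clamps at 1e-12 of the frame maximum.
Spectral windows are truncated at ±4σ_k and centred on the grid centroid.
The duct series is evaluated in log space (overflow-safe at high aspect
ratio), normalized analytically so the truncated series' flux equals the
pump discharge exactly, and is identically zero on the expansion walls.
All randomness descends from explicit integer seeds; identical seeds give
bit-identical stacks.

## What the synthetic data does and does not establish

The simulator reproduces the features the estimators rely on — Gaussian
beam and coherence envelopes, carrier phase, dilute-suspension number
statistics, detection noise, advection with stationary concentration —
and omits multiple scattering, Brownian motion (by default), flow
gradients within the PSF, intra-frame scan timing, sample-induced
aberrations and spectrometer non-idealities.  Passing recovery tests
therefore demonstrates estimator correctness under the stated model, not
instrument-level accuracy on real devices; with real data the same
estimator surface applies unchanged to measured k-space or complex
stacks in the HDF5 container.
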