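# octflow

Multi-modal optical coherence tomography (OCT) flowmetry for microfluidic
and organ-on-chip devices: three quantitative velocity estimators plus a
synthetic spectral-domain OCT simulator that validates every estimator by
parameter recovery on flows with known ground truth.

Microfluidic culture devices need their flow fields characterized in situ —
nutrient refresh rates, shear at tissue interfaces, channel speeds — but the
speeds span four orders of magnitude, from ~10 µm/s in a culture well to
mm/s in the supply channel. No single OCT mode covers that range, so this
package implements the three that together do:

* **Number-fluctuation DLS-OCT** (`octflow.dls`) — total speed, slow flows.
  The per-voxel intensity autocovariance
  `g₂(x,z,τ) = ⟨δI(t)δI(t+τ)⟩/⟨I⟩²` decays as particles transit the focal
  volume. After depth-matched spectral apodization, which enforces
  `√2·w_z(z) = w_r(z) = (σ_k(z)·n_k)⁻¹`, the decay is independent of flow
  direction and a two-parameter fit

      g₂(τ) = A·exp(−2·v₀²·τ²/w_r(z)²)

  yields the total speed v₀ at every voxel, down to tens of µm/s.
* **PIV-OCT** (`octflow.piv`) — in-plane velocity *vectors*, slow flows.
  Intensity frames are tiled into 4×32-px windows; the normalized unbiased
  cross-covariance ρ(m,n) between frames N·Δt apart is temporally averaged
  and its integer peak converts to velocity:
  `v_x = m·Δx/(NΔt)`, `v_z = n·Δz/(n_k·N·Δt)`.
* **Phase-resolved Doppler OCT** (`octflow.doppler`) — axial velocity, fast
  channel flows. The lag-1 Kasai phase Δφ maps to
  `v_axial = λ₀·Δφ/(4π·n_k·τ_A)`, corrected for window refraction and the
  Doppler angle.

The simulator (`octflow.simulate`) advects dilute point scatterers through
uniform, rectangular-duct Poiseuille, or gridded flow fields and renders
k-space interferograms or complex B-scan series with a confocal Gaussian
beam PSF, coherence gating, and configurable detection noise. Matched
reconstruction lives in `octflow.reconstruct` (depth-dependent Gaussian
apodization, beam calibration and the `w_r(z)=w₀√(1+(z−z₀)²/z_R²)` fit);
`octflow.validation` bundles the recovery studies. See `docs/methods.md`
for the model conventions and their rationale.

## Worked example

Simulate a uniform 39 µm/s in-plane flow at SNR 10, estimate speed maps
with both slow-flow modalities from the same stack, and compare:

```sh
$ cat scenario.yaml
version: 1
seed: 7
output_dir: out
stages: [simulate, dls, piv, compare]
geometry: {n_lateral: 8, n_axial: 32, n_frames: 600}
beam: {w0: 6.0, z0: 21.7, z_R: 167.0}
scenario: {field: uniform, speed_um_s: 39.0, theta_deg: 0.0, snr: 10.0, in_plane_axis: x}
piv: {window_axial: 32}

$ octflow run --config scenario.yaml
octflow INFO simulate: 8 x 32 x 600 voxels
octflow INFO dls: 256/256 voxels valid
octflow INFO piv: 2/2 windows valid
octflow INFO compare: median relative difference 0.059 over 2 windows
```

`out/report.json` then holds

```json
{
  "dls_median_um_s": 41.78,
  "piv_median_um_s": 39.29,
  "median_relative_difference": 0.059,
  "truth_bias_um_s": 1.08,
  "truth_rmse_um_s": 6.67
}
```

DLS recovers the 39 µm/s ground truth with a +1.1 µm/s bias and 6.7 µm/s
per-voxel RMSE at this record length; PIV reports 39.0 µm/s lateral
velocity exactly (the speed sits on its quantization grid, 2 px per 20
frames) and the two modalities agree to 6 % — the cross-check that makes
the combined speed + vector maps trustworthy. Subcommands
`octflow simulate|calibrate-beam|reconstruct|dls|piv|doppler|run` expose
each stage separately; the library functions take and return the same
objects.

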