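"""Number-fluctuation DLS-OCT: g₂ estimation and total-speed fitting.

The second-order normalized autocovariance of the per-voxel intensity time
series, g₂(τ) = ⟨δI(t)·δI(t+τ)⟩/⟨I⟩², decays with the TOTAL speed of the
tracer particles transiting the focal volume — independently of diffusion
at coarse frame intervals, and, after matched spectral apodization
(√2·w_z = w_r), independently of flow direction:

    g₂(τ) = A · exp(−2·v₀²·τ²/w_r(z)²)

with only (A, v₀) free.  The full forward model including the amplitude
pre-factor (field kurtosis κ, SNR, mean particle number N) is available for
validation but is not needed for speed maps.

Estimator choices: autoCOVARIANCE normalized by ⟨I⟩² (so the model decays
to zero), lag 0 excluded (shot-noise/detection-noise spike), unbiased
per-lag averaging (divide by n−j at lag j).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .geometry import ComplexBScanSeries
from .reconstruct import BeamModel

__all__ = [
    "G2Curve",
    "NFModelParams",
    "G2FitResult",
    "SpeedMap",
    "compute_g2",
    "eval_nf_model",
    "fit_g2",
    "estimate_snr",
    "estimate_field_kurtosis",
    "build_speed_map",
]


@dataclass
class G2Curve:
    """Sampled g₂ at lags τ_j = j·Δt, j ≥ 1."""

    lags_s: np.ndarray
    values: np.ndarray
    n_samples: np.ndarray  # samples averaged per lag

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        # NaN marks invalid voxels (zero mean intensity); infinities are bugs
        if np.any(np.isinf(self.values)):
            raise ValueError("g2 values must be finite")


@dataclass(frozen=True)
class NFModelParams:
    """Parameters of the number-fluctuation g₂ forward model."""

    v0: float  # total speed, µm/s
    theta: float  # rad; 90°−θ is the angle to the optical axis
    w_r: float  # µm
    w_z: float  # µm
    snr: float  # linear
    n_particles: float  # mean particles per scattering volume
    kurtosis: float  # of the noise-subtracted complex field

    def __post_init__(self) -> None:
        if self.v0 < 0 or self.w_r <= 0 or self.w_z <= 0:
            raise ValueError("require v0 >= 0 and w_r, w_z > 0")
        if self.snr <= 0 or self.n_particles <= 0 or self.kurtosis <= 1:
            raise ValueError("require SNR > 0, N > 0, kurtosis > 1")


@dataclass
class G2FitResult:
    amplitude: float
    v0: float
    residual_rms: float
    converged: bool


@dataclass
class SpeedMap:
    """Per-voxel total speed v₀(x, z) with validity mask and fit diagnostics."""

    v0: np.ndarray
    mask: np.ndarray  # True where the fit converged and passed thresholds
    amplitude: np.ndarray
    residual_rms: np.ndarray


def compute_g2(series: np.ndarray, max_lag: int, dt_s: float = 1.0) -> G2Curve:
    """Normalized intensity autocovariance of one or many voxel time series.

    ``series`` is real intensity with time on the LAST axis; returns lags
    1..max_lag with unbiased per-lag averaging.  Voxels with zero mean
    intensity yield NaN (flagged invalid downstream).
    """
    I = np.asarray(series, dtype=float)
    n = I.shape[-1]
    if n < 100:
        raise ValueError("need at least 100 frames for a stable g2 estimate")
    if max_lag >= n // 4:
        raise ValueError("max_lag must be below n_frames/4")
    mean = I.mean(axis=-1, keepdims=True)
    d = I - mean
    denom = np.squeeze(mean, axis=-1) ** 2
    bad = denom == 0
    vals = np.empty(I.shape[:-1] + (max_lag,))
    counts = np.empty(max_lag, dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(1, max_lag + 1):
            cov = (d[..., : n - j] * d[..., j:]).sum(axis=-1) / (n - j)
            vals[..., j - 1] = cov / denom
            counts[j - 1] = n - j
    if np.any(bad):
        vals[bad] = np.nan
    lags = np.arange(1, max_lag + 1) * dt_s
    return G2Curve(lags_s=lags, values=vals, n_samples=counts)


def eval_nf_model(p: NFModelParams, tau_s) -> np.ndarray:
    """Number-fluctuation g₂ forward model.

    g₂(τ) = (κ−1)·exp(−v₀²sin²θ·τ²/w_z²)·exp(−2v₀²cos²θ·τ²/w_r²)
            / [(κ−2+(1+1/SNR)²)·(2^{3/2}·N+1)]
    """
    tau = np.asarray(tau_s, dtype=float)
    denom = (p.kurtosis - 2.0 + (1.0 + 1.0 / p.snr) ** 2) * (
        2.0 ** 1.5 * p.n_particles + 1.0
    )
    if denom <= 0:
        raise ValueError("invalid kurtosis/SNR combination: non-positive denominator")
    decay = np.exp(
        -(p.v0**2) * np.sin(p.theta) ** 2 * tau**2 / p.w_z**2
        - 2.0 * p.v0**2 * np.cos(p.theta) ** 2 * tau**2 / p.w_r**2
    )
    return (p.kurtosis - 1.0) * decay / denom


def fit_g2(
    curve: G2Curve,
    w_r_local: float,
    max_fit_lags: int = 32,
    tail_fraction: float = 0.05,
) -> G2FitResult:
    """Two-parameter fit g₂(τ) = A·exp(−2·v₀²·τ²/w_r²) (matched apodization).

    Fit range: the first ``max_fit_lags`` lags, or until g₂ drops below
    ``tail_fraction``·A, whichever is later.  Initialization: A from the
    first lag; v₀ from the first lag τ_e where g₂ < A/e (v₀ = 0 if never).
    Negative fitted amplitude or non-convergence flags the result.
    """
    y_all = np.asarray(curve.values, dtype=float)
    tau_all = curve.lags_s
    if y_all.ndim != 1:
        raise ValueError("fit_g2 expects a single-voxel curve")
    if not np.all(np.isfinite(y_all)):
        return G2FitResult(np.nan, np.nan, np.nan, False)
    a0 = y_all[0]
    below = np.nonzero(y_all < tail_fraction * a0)[0]
    n_use = max_fit_lags
    if below.size:
        n_use = max(max_fit_lags, below[0] + 1)
    n_use = min(n_use, y_all.size)
    tau, y = tau_all[:n_use], y_all[:n_use]
    if a0 <= 0:
        # no positive correlation at the first lag: static/noise voxel
        return G2FitResult(float(a0), 0.0, float(np.sqrt(np.mean(y**2))), True)
    sub = np.nonzero(y < a0 / np.e)[0]
    v0_init = w_r_local / (np.sqrt(2.0) * tau[sub[0]]) if sub.size else 0.0

    def resid(params):
        amp, v0 = params
        return amp * np.exp(-2.0 * v0**2 * tau**2 / w_r_local**2) - y

    try:
        sol = least_squares(
            resid, x0=[a0, v0_init], bounds=([-np.inf, 0.0], [np.inf, np.inf]),
            max_nfev=2000,
        )
    except Exception:
        return G2FitResult(np.nan, np.nan, np.nan, False)
    amp, v0 = float(sol.x[0]), float(sol.x[1])
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    converged = bool(sol.success) and amp > 0
    return G2FitResult(amp, v0, rms, converged)


def estimate_snr(
    intensity_series: np.ndarray, noise_region: np.ndarray
) -> np.ndarray:
    """Per-voxel SNR = (⟨I⟩_voxel − ⟨I⟩_noise)/⟨I⟩_noise, clipped at 0.

    ``intensity_series`` is (x, z, t); ``noise_region`` a boolean (x, z)
    mask designating sample-free voxels.
    """
    noise_region = np.asarray(noise_region, dtype=bool)
    if not np.any(noise_region):
        raise ValueError("noise region is empty")
    I = np.asarray(intensity_series, dtype=float)
    mean_map = I.mean(axis=-1)
    noise_mean = float(mean_map[noise_region].mean())
    if noise_mean <= 0:
        raise ValueError("noise region has non-positive mean intensity")
    return np.clip(mean_map / noise_mean - 1.0, 0.0, None)


def estimate_field_kurtosis(
    complex_series: np.ndarray, noise_power: float = 0.0
) -> float:
    """κ = ⟨|E|⁴⟩/⟨|E|²⟩² of the noise-subtracted complex field at one voxel.

    Noise subtraction assumes additive circular Gaussian noise of the given
    power P_n, independent of the signal:  m₂ = ⟨|a|²⟩ − P_n and
    m₄ = ⟨|a|⁴⟩ − 4·P_n·m₂ − 2·P_n².  κ → 2 for fully developed (circular
    Gaussian) speckle, κ = 1 for a constant-amplitude phasor.
    """
    a = np.asarray(complex_series).ravel()
    if a.size < 500:
        raise ValueError("need at least 500 samples to estimate kurtosis")
    m2_tot = float(np.mean(np.abs(a) ** 2))
    m4_tot = float(np.mean(np.abs(a) ** 4))
    m2 = m2_tot - noise_power
    if m2 <= 0:
        raise ValueError("non-positive signal power after noise subtraction")
    m4 = m4_tot - 4.0 * noise_power * m2 - 2.0 * noise_power**2
    return m4 / m2**2


def build_speed_map(
    series: ComplexBScanSeries,
    beam: BeamModel,
    max_lag: int = 32,
    snr_min: float = 3.0,
    noise_region: Optional[np.ndarray] = None,
) -> SpeedMap:
    """Per-voxel g₂ + speed fit over a (depth-matched) complex B-scan series.

    The local beam waist w_r(z) supplies the fit's length scale.  Voxels
    below ``snr_min`` (when a noise region is given or an SNR map is
    attached to the series), with non-converged fits, or whose fitted
    amplitude is not significant against the fit residual (no real decay,
    e.g. a static scene where g₂ is pure estimator noise) are masked out.
    """
    g = series.geometry
    I = np.abs(series.values) ** 2
    curve = compute_g2(I, max_lag=max_lag, dt_s=g.frame_interval)
    w_r_z = beam.w_r(g.z_physical_um)
    n_x, n_z = g.n_lateral, g.n_axial
    v0 = np.full((n_x, n_z), np.nan)
    amp = np.full((n_x, n_z), np.nan)
    rms = np.full((n_x, n_z), np.nan)
    mask = np.zeros((n_x, n_z), dtype=bool)
    for ix in range(n_x):
        for iz in range(n_z):
            single = G2Curve(
                lags_s=curve.lags_s,
                values=curve.values[ix, iz],
                n_samples=curve.n_samples,
            ) if np.all(np.isfinite(curve.values[ix, iz])) else None
            if single is None:
                continue
            res = fit_g2(single, float(w_r_z[iz]), max_fit_lags=max_lag)
            v0[ix, iz] = res.v0
            amp[ix, iz] = res.amplitude
            rms[ix, iz] = res.residual_rms
            # significance at the first measured lag: a fit whose model has
            # already decayed into the residual noise there carries no speed
            # information (static scenes, or decays faster than the sampling)
            tau1 = curve.lags_s[0]
            m1 = res.amplitude * np.exp(
                -2.0 * res.v0**2 * tau1**2 / float(w_r_z[iz]) ** 2
            )
            mask[ix, iz] = res.converged and m1 > 2.0 * res.residual_rms
    snr_map = series.snr_map
    if snr_map is None and noise_region is not None:
        snr_map = estimate_snr(I, noise_region)
    if snr_map is not None:
        mask &= snr_map >= snr_min
    return SpeedMap(v0=v0, mask=mask, amplitude=amp, residual_rms=rms)
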