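"""PIV-OCT: windowed cross-covariance velocimetry on intensity frame pairs.

B-scan intensity images are tiled into small windows (default 4 lateral ×
32 axial pixels).  For each window and frame pair separated by N·Δt the
normalized unbiased 2D cross-covariance

    ρ(m, n, t) = Σ_overlap δI(ε,η,t)·δI(ε+m,η+n,t+NΔt)
                 / [σ(t)·σ(t+NΔt)·(W_x−|m|)·(W_z−|n|)]

is computed (mean and σ over the whole window; out-of-window samples
excluded; the (W−|shift|) factors remove the triangular overlap taper).
Coefficients are averaged over all available pairs and the integer argmax
(m_max, n_max) converts to velocity via

    v_x = m_max·Δx/(N·Δt),   v_z = n_max·Δz/(n_k·N·Δt).

The axial and lateral components use different temporal separations N (the
axial pixel is ~10× finer than the lateral one), with a third value inside
a designated high-speed center region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import ScanGeometry

__all__ = [
    "PIVConfig",
    "CrossCovMatrix",
    "VelocityVectorMap",
    "compute_xcov",
    "average_xcov",
    "peak_to_velocity",
    "run_piv",
    "window_acquisition_time_s",
    "window_extent_um",
]


@dataclass
class PIVConfig:
    """Windowing and temporal-separation protocol."""

    window_lateral: int = 4
    window_axial: int = 32
    n_lateral: int = 20  # frame separation N for v_x
    n_axial: int = 5  # frame separation N for v_z
    n_center: int = 15  # N for both components inside the center region
    center_region: Optional[tuple] = None  # (x0, x1, z0, z1) pixel rectangle
    n_pairs: Optional[int] = None  # cap on temporally averaged pairs
    subpixel: bool = False

    def __post_init__(self) -> None:
        if min(self.window_lateral, self.window_axial) < 1:
            raise ValueError("window dimensions must be >= 1")
        if min(self.n_lateral, self.n_axial, self.n_center) < 1:
            raise ValueError("all temporal separations N must be >= 1")


@dataclass
class CrossCovMatrix:
    """ρ(m, n) on shifts m ∈ [−(W_x−1), W_x−1], n ∈ [−(W_z−1), W_z−1]."""

    rho: np.ndarray
    origin: tuple  # window anchor (x, z) in pixels
    valid: bool = True

    @property
    def m_range(self) -> np.ndarray:
        half = (self.rho.shape[0] - 1) // 2
        return np.arange(-half, half + 1)

    @property
    def n_range(self) -> np.ndarray:
        half = (self.rho.shape[1] - 1) // 2
        return np.arange(-half, half + 1)


@dataclass
class VelocityVectorMap:
    """Per-window velocity vectors on the PIV window grid."""

    v_x: np.ndarray  # µm/s, (n_win_x, n_win_z)
    v_z: np.ndarray
    peak_m: np.ndarray
    peak_n: np.ndarray
    peak_value: np.ndarray
    mask: np.ndarray
    ambiguous: np.ndarray
    window_origin_x_um: np.ndarray
    window_origin_z_um: np.ndarray
    window_extent_um: tuple = (0.0, 0.0)


def window_acquisition_time_s(config: PIVConfig, geometry: ScanGeometry) -> float:
    """Time to acquire one window's A-scans: W_x / a_scan_rate."""
    return config.window_lateral / geometry.a_scan_rate


def window_extent_um(config: PIVConfig, geometry: ScanGeometry) -> tuple:
    """Physical window extent (lateral, axial) in µm; axial uses Δz/n_k."""
    return (
        config.window_lateral * geometry.lateral_pitch,
        config.window_axial * geometry.axial_pitch / geometry.group_index,
    )


def _parabolic_offset(line: np.ndarray, idx: int) -> float:
    """3-point parabolic sub-sample peak offset in [-0.5, 0.5]."""
    if idx <= 0 or idx >= line.size - 1:
        return 0.0
    y0, y1, y2 = line[idx - 1], line[idx], line[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def compute_xcov(frame_a: np.ndarray, frame_b: np.ndarray, origin=(0, 0)) -> CrossCovMatrix:
    """Normalized unbiased 2D cross-covariance of two intensity windows."""
    A = np.asarray(frame_a, dtype=float)
    B = np.asarray(frame_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("windows must be two identically shaped 2D arrays")
    wx, wz = A.shape
    da = A - A.mean()
    db = B - B.mean()
    sa = A.std()
    sb = B.std()
    rho = np.zeros((2 * wx - 1, 2 * wz - 1))
    if sa == 0 or sb == 0:
        return CrossCovMatrix(rho=rho, origin=tuple(origin), valid=False)
    for m in range(-(wx - 1), wx):
        a_sl = slice(max(0, -m), wx - max(0, m))
        b_sl = slice(max(0, m), wx - max(0, -m))
        for n in range(-(wz - 1), wz):
            a_sz = slice(max(0, -n), wz - max(0, n))
            b_sz = slice(max(0, n), wz - max(0, -n))
            s = float(np.sum(da[a_sl, a_sz] * db[b_sl, b_sz]))
            rho[m + wx - 1, n + wz - 1] = s / (sa * sb * (wx - abs(m)) * (wz - abs(n)))
    return CrossCovMatrix(rho=rho, origin=tuple(origin))


def average_xcov(matrices) -> CrossCovMatrix:
    """Elementwise mean of valid cross-covariance matrices."""
    valid = [m for m in matrices if m.valid]
    if not valid:
        first = next(iter(matrices), None)
        if first is None:
            raise ValueError("no matrices to average")
        return CrossCovMatrix(
            rho=np.zeros_like(first.rho), origin=first.origin, valid=False
        )
    rho = np.mean([m.rho for m in valid], axis=0)
    return CrossCovMatrix(rho=rho, origin=valid[0].origin)


def peak_to_velocity(
    matrix: CrossCovMatrix,
    n_sep: int,
    geometry: ScanGeometry,
    max_shift: Optional[tuple] = None,
    subpixel: bool = False,
):
    """Integer peak → (v_x, v_z) per the PIV velocity relations.

    Returns ``(v_x, v_z, m_max, n_max, peak, ambiguous)``.  Ties take the
    first maximum in row-major order and are flagged ambiguous.
    ``subpixel`` applies a 3-point parabolic refinement around the integer
    peak (off by default; the reported m_max/n_max stay integer).

    ``max_shift=(m_lim, n_lim)`` restricts the peak search to
    |m| ≤ m_lim, |n| ≤ n_lim.  The unbiased overlap factors divide by very
    few samples at extreme shifts, so those cells are noise-dominated (and,
    for static or frozen speckle, persistently so — temporal averaging does
    not suppress them); the pipeline searches within half the window size.
    """
    if not matrix.valid:
        raise ValueError("cannot extract a peak from an invalid matrix")
    rho = matrix.rho
    if max_shift is not None:
        sel_m = np.abs(matrix.m_range) <= max_shift[0]
        sel_n = np.abs(matrix.n_range) <= max_shift[1]
        search = np.where(np.outer(sel_m, sel_n), rho, -np.inf)
    else:
        search = rho
    flat = int(np.argmax(search))
    peak = float(search.flat[flat])
    ambiguous = bool(np.count_nonzero(search == peak) > 1)
    i, j = np.unravel_index(flat, rho.shape)
    m_max = int(matrix.m_range[i])
    n_max = int(matrix.n_range[j])
    m_eff, n_eff = float(m_max), float(n_max)
    if subpixel:
        m_eff += _parabolic_offset(rho[:, j], i)
        n_eff += _parabolic_offset(rho[i, :], j)
    g = geometry
    ndt = n_sep * g.frame_interval
    v_x = m_eff * g.lateral_pitch / ndt
    v_z = n_eff * g.axial_pitch / (g.group_index * ndt)
    return v_x, v_z, m_max, n_max, peak, ambiguous


def _averaged_xcov_timeseries(win: np.ndarray, n_sep: int, n_pairs: Optional[int]):
    """Mean ρ over all frame pairs (t, t+N) of one window stack (wx, wz, T).

    Vectorized over time: per shift the overlap product is summed for every
    pair at once, normalized per pair by σ(t)·σ(t+NΔt) and the unbiased
    overlap factors, then averaged over valid pairs.
    """
    wx, wz, T = win.shape
    if T <= n_sep:
        return None
    a = win[:, :, : T - n_sep]
    b = win[:, :, n_sep:]
    if n_pairs is not None:
        a = a[:, :, :n_pairs]
        b = b[:, :, :n_pairs]
    da = a - a.mean(axis=(0, 1), keepdims=True)
    db = b - b.mean(axis=(0, 1), keepdims=True)
    sa = a.std(axis=(0, 1))
    sb = b.std(axis=(0, 1))
    ok = (sa > 0) & (sb > 0)
    if not np.any(ok):
        return None
    da, db = da[:, :, ok], db[:, :, ok]
    norm = sa[ok] * sb[ok]
    rho = np.zeros((2 * wx - 1, 2 * wz - 1))
    for m in range(-(wx - 1), wx):
        a_sl = slice(max(0, -m), wx - max(0, m))
        b_sl = slice(max(0, m), wx - max(0, -m))
        for n in range(-(wz - 1), wz):
            a_sz = slice(max(0, -n), wz - max(0, n))
            b_sz = slice(max(0, n), wz - max(0, -n))
            s = np.einsum(
                "xzt,xzt->t", da[a_sl, a_sz, :], db[b_sl, b_sz, :]
            )
            rho[m + wx - 1, n + wz - 1] = float(
                np.mean(s / (norm * (wx - abs(m)) * (wz - abs(n))))
            )
    return rho


def run_piv(
    intensity_series: np.ndarray,
    config: PIVConfig,
    geometry: ScanGeometry,
) -> VelocityVectorMap:
    """Tile frames into windows and extract per-window velocity vectors.

    ``intensity_series`` is (n_lateral, n_axial, n_frames).  v_z uses frame
    separation ``n_axial`` and v_x uses ``n_lateral`` (``n_center`` for both
    inside the configured center rectangle).  Edge windows smaller than the
    window size are discarded; windows with degenerate statistics are
    masked.
    """
    I = np.asarray(intensity_series, dtype=float)
    nx, nz, T = I.shape
    wx, wz = config.window_lateral, config.window_axial
    if T <= 2 * max(config.n_lateral, config.n_axial, config.n_center):
        raise ValueError("not enough frames for the configured separations")
    n_win_x = nx // wx
    n_win_z = nz // wz
    shape = (n_win_x, n_win_z)
    v_x = np.full(shape, np.nan)
    v_z = np.full(shape, np.nan)
    pk_m = np.zeros(shape, dtype=int)
    pk_n = np.zeros(shape, dtype=int)
    pk_v = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    amb = np.zeros(shape, dtype=bool)
    cx = config.center_region

    for ix in range(n_win_x):
        for iz in range(n_win_z):
            x0, z0 = ix * wx, iz * wz
            win = I[x0 : x0 + wx, z0 : z0 + wz, :]
            in_center = (
                cx is not None
                and cx[0] <= x0 < cx[1]
                and cx[2] <= z0 < cx[3]
            )
            n_for_x = config.n_center if in_center else config.n_lateral
            n_for_z = config.n_center if in_center else config.n_axial
            res = {}
            okay = True
            for key, n_sep in (("x", n_for_x), ("z", n_for_z)):
                rho = _averaged_xcov_timeseries(win, n_sep, config.n_pairs)
                if rho is None:
                    okay = False
                    break
                mat = CrossCovMatrix(rho=rho, origin=(x0, z0))
                res[key] = (
                    peak_to_velocity(
                        mat, n_sep, geometry, max_shift=(wx // 2, wz // 2),
                        subpixel=config.subpixel,
                    ),
                    mat,
                )
            if not okay:
                continue
            (vx_i, _, m_i, _, pv_x, amb_x), _ = res["x"]
            (_, vz_i, _, n_i, pv_z, amb_z), _ = res["z"]
            v_x[ix, iz] = vx_i
            v_z[ix, iz] = vz_i
            pk_m[ix, iz] = m_i
            pk_n[ix, iz] = n_i
            pk_v[ix, iz] = max(pv_x, pv_z)
            amb[ix, iz] = amb_x or amb_z
            mask[ix, iz] = True

    return VelocityVectorMap(
        v_x=v_x, v_z=v_z, peak_m=pk_m, peak_n=pk_n, peak_value=pk_v,
        mask=mask, ambiguous=amb,
        window_origin_x_um=np.arange(n_win_x) * wx * geometry.lateral_pitch,
        window_origin_z_um=np.arange(n_win_z) * wz * geometry.axial_pitch
        / geometry.group_index,
        window_extent_um=window_extent_um(config, geometry),
    )
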