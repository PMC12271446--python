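"""Scan geometry, in-memory containers and unit conversions.

Axis order throughout the package is (lateral x, axial z, time t), 0-based.
Axial pixel 0 sits at zero optical delay; the axial pitch is stored in
OPTICAL path-length units, so every physical-depth quantity divides by the
group refractive index ``n_k`` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ScanGeometry",
    "SpectralFrameStack",
    "ComplexBScanSeries",
    "IntensityImage",
    "to_intensity",
    "to_db",
    "optical_to_physical_depth",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry and timing for one OCT measurement.

    Parameters
    ----------
    lateral_pitch : float
        Lateral pixel pitch Δx in µm/pixel.
    axial_pitch : float
        Axial pixel pitch Δz in µm of OPTICAL path length per pixel.
    n_lateral, n_axial, n_frames : int
        Pixels per B-scan, pixels per A-scan, number of frames.
    frame_interval : float
        B-scan sampling interval Δt in seconds.
    a_scan_rate : float
        A-scan line rate in Hz.
    group_index : float
        Group refractive index n_k of the medium (1.33 for water).
    center_wavelength : float
        Source center wavelength λ₀ in µm (in vacuo).
    """

    lateral_pitch: float = 15.6
    axial_pitch: float = 1.8
    n_lateral: int = 200
    n_axial: int = 1024
    n_frames: int = 2000
    frame_interval: float = 0.040
    a_scan_rate: float = 5500.0
    group_index: float = 1.33
    center_wavelength: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "lateral_pitch", "axial_pitch", "n_lateral", "n_axial",
            "n_frames", "frame_interval", "a_scan_rate", "group_index",
            "center_wavelength",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"ScanGeometry.{name} must be strictly positive")
        if self.n_lateral / self.a_scan_rate > self.frame_interval * (1 + 1e-12):
            raise ValueError(
                "inconsistent timing: acquiring n_lateral A-scans at a_scan_rate "
                f"takes {self.n_lateral / self.a_scan_rate:.4g} s, longer than the "
                f"frame interval {self.frame_interval:.4g} s"
            )

    # -- derived axes ------------------------------------------------------
    @property
    def x_um(self) -> np.ndarray:
        """Lateral pixel-center coordinates in µm."""
        return np.arange(self.n_lateral) * self.lateral_pitch

    @property
    def z_optical_um(self) -> np.ndarray:
        """Axial pixel-center coordinates in µm of optical path."""
        return np.arange(self.n_axial) * self.axial_pitch

    @property
    def z_physical_um(self) -> np.ndarray:
        """Axial pixel-center coordinates in µm of physical depth."""
        return self.z_optical_um / self.group_index

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def with_(self, **kw) -> "ScanGeometry":
        return replace(self, **kw)


@dataclass
class SpectralFrameStack:
    """Raw k-space interferogram frames S(k, x, t) on a uniform wavenumber grid."""

    wavenumber_grid: np.ndarray  # µm^-1, uniform, length n_k_samples
    values: np.ndarray  # real, (n_k_samples, n_lateral, n_frames)
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        k = np.asarray(self.wavenumber_grid, dtype=float)
        if k.ndim != 1 or k.size < 2:
            raise ValueError("wavenumber_grid must be 1D with >= 2 samples")
        dk = np.diff(k)
        if np.max(np.abs(dk - dk[0])) > 1e-9 * abs(dk[0]):
            raise ValueError("wavenumber grid must be uniform to 1 part in 1e9")
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[0] != k.size:
            raise ValueError("values must be (n_k_samples, n_lateral, n_frames)")
        if v.shape[1] != self.geometry.n_lateral:
            raise ValueError("lateral dimension inconsistent with geometry")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectral values must be finite")
        self.wavenumber_grid = k
        self.values = v

    @property
    def dk(self) -> float:
        return float(self.wavenumber_grid[1] - self.wavenumber_grid[0])


@dataclass
class ComplexBScanSeries:
    """Reconstructed complex OCT field a(x, z, t)."""

    values: np.ndarray  # complex, (n_lateral, n_axial, n_frames)
    geometry: ScanGeometry
    snr_map: Optional[np.ndarray] = None  # linear, (n_lateral, n_axial)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("values must be (n_lateral, n_axial, n_frames)")
        g = self.geometry
        if v.shape[0] != g.n_lateral or v.shape[1] != g.n_axial:
            raise ValueError(
                f"series shape {v.shape[:2]} inconsistent with geometry "
                f"({g.n_lateral}, {g.n_axial})"
            )
        if self.snr_map is not None:
            s = np.asarray(self.snr_map, dtype=float)
            if s.shape != v.shape[:2]:
                raise ValueError("snr_map shape must be (n_lateral, n_axial)")
            if np.any(s < 0):
                raise ValueError("SNR must be >= 0")
            self.snr_map = s
        self.values = np.asarray(v, dtype=complex)

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]


@dataclass
class IntensityImage:
    """Intensity data I(x, z) or I(x, z, t); linear (>= 0) unless ``db`` is set."""

    values: np.ndarray
    geometry: ScanGeometry
    db: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim not in (2, 3):
            raise ValueError("intensity must be 2D (x, z) or 3D (x, z, t)")
        if not self.db and np.any(v < 0):
            raise ValueError("linear intensity must be >= 0")
        self.values = v


def to_intensity(series: ComplexBScanSeries) -> IntensityImage:
    """Squared modulus I = |a|² of a complex B-scan series."""
    return IntensityImage(np.abs(series.values) ** 2, series.geometry, db=False)


def to_db(image: IntensityImage, floor: Optional[float] = None) -> IntensityImage:
    """Convert linear intensity to dB, 10·log10(max(I, floor)).

    ``floor`` defaults to 1e-12 of the maximum so that empty voxels map to a
    finite value instead of −inf.
    """
    if image.db:
        return image
    if floor is None:
        peak = float(np.max(image.values)) if image.values.size else 1.0
        floor = 1e-12 * peak if peak > 0 else 1e-300
    if floor <= 0:
        raise ValueError("dB floor must be > 0")
    vals = 10.0 * np.log10(np.maximum(image.values, floor))
    return IntensityImage(vals, image.geometry, db=True)


def optical_to_physical_depth(z_optical_um, group_index: float):
    """Convert optical path length to physical depth: z / n_k."""
    if group_index < 1:
        raise ValueError("group index must be >= 1")
    return np.asarray(z_optical_um, dtype=float) / group_index
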