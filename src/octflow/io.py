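"""HDF5 container I/O plus TIFF/CSV export.

One HDF5 file holds one acquisition: datasets ``/spectral`` (real, with a
``/wavenumber_grid`` axis), ``/complex_re`` + ``/complex_im``, and/or
``/intensity``, with the scan geometry stored as attributes of a
``/geometry`` group.  Round-trips are bit-exact for float payloads.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .geometry import (
    ComplexBScanSeries,
    IntensityImage,
    ScanGeometry,
    SpectralFrameStack,
)

__all__ = ["write_stack", "read_stack", "export_tiff", "export_profile_csv"]

_GEOM_FIELDS = [f.name for f in dataclasses.fields(ScanGeometry)]
_INT_FIELDS = {"n_lateral", "n_axial", "n_frames"}

Stack = Union[SpectralFrameStack, ComplexBScanSeries, IntensityImage]


def _write_geometry(h5: h5py.File, geometry: ScanGeometry) -> None:
    grp = h5.require_group("geometry")
    for name in _GEOM_FIELDS:
        grp.attrs[name] = getattr(geometry, name)


def _read_geometry(h5: h5py.File) -> ScanGeometry:
    if "geometry" not in h5:
        raise KeyError("container is missing the /geometry metadata group")
    attrs = h5["geometry"].attrs
    kwargs = {}
    for name in _GEOM_FIELDS:
        if name not in attrs:
            raise KeyError(f"geometry metadata is missing required field {name!r}")
        val = attrs[name]
        kwargs[name] = int(val) if name in _INT_FIELDS else float(val)
    return ScanGeometry(**kwargs)


def write_stack(path, stack: Stack, extra_attrs: dict | None = None) -> None:
    """Write a spectral / complex / intensity stack to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        _write_geometry(h5, stack.geometry)
        if isinstance(stack, SpectralFrameStack):
            h5.create_dataset("spectral", data=stack.values)
            h5.create_dataset("wavenumber_grid", data=stack.wavenumber_grid)
        elif isinstance(stack, ComplexBScanSeries):
            h5.create_dataset("complex_re", data=stack.values.real)
            h5.create_dataset("complex_im", data=stack.values.imag)
            if stack.snr_map is not None:
                h5.create_dataset("snr_map", data=stack.snr_map)
        elif isinstance(stack, IntensityImage):
            ds = h5.create_dataset("intensity", data=stack.values)
            ds.attrs["db"] = bool(stack.db)
        else:  # pragma: no cover - defensive
            raise TypeError(f"unsupported stack type {type(stack).__name__}")
        if extra_attrs:
            for key, val in extra_attrs.items():
                h5.attrs[key] = val


def read_stack(path, kind: str) -> Stack:
    """Read a stack of the named kind (``spectral``/``complex``/``intensity``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as h5:
        geometry = _read_geometry(h5)
        if kind == "spectral":
            if "spectral" not in h5:
                raise KeyError("container holds no /spectral dataset")
            return SpectralFrameStack(
                wavenumber_grid=h5["wavenumber_grid"][()],
                values=h5["spectral"][()],
                geometry=geometry,
            )
        if kind == "complex":
            if "complex_re" not in h5:
                raise KeyError("container holds no /complex_re dataset")
            values = h5["complex_re"][()] + 1j * h5["complex_im"][()]
            snr = h5["snr_map"][()] if "snr_map" in h5 else None
            return ComplexBScanSeries(values=values, geometry=geometry, snr_map=snr)
        if kind == "intensity":
            if "intensity" not in h5:
                raise KeyError("container holds no /intensity dataset")
            ds = h5["intensity"]
            return IntensityImage(ds[()], geometry, db=bool(ds.attrs.get("db", False)))
    raise ValueError(f"unknown stack kind {kind!r}")


def export_tiff(path, image_2d: np.ndarray) -> None:
    """Export a 2D map as 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(image_2d, dtype=np.float32))


def export_profile_csv(path, x_um, z_um, value, unit: str) -> None:
    """Export a profile/table as CSV with columns x_um, z_um, value, unit."""
    df = pd.DataFrame(
        {
            "x_um": np.ravel(x_um),
            "z_um": np.ravel(z_um),
            "value": np.ravel(value),
            "unit": unit,
        }
    )
    df.to_csv(path, index=False)
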