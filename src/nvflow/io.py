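"""Readers and writers for volumes, masks, traces and results.

One HDF5 container per acquisition with a declared schema version: complex
volumes live in separate ``real``/``imag`` datasets plus a ``metadata``
attribute group, so round trips are bit-exact.  Tabular outputs use CSV
(pandas) with fixed float formatting; scalar results use JSON.  Angiograms,
masks and kymographs can additionally be exported as multi-page TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import ComplexVolume, ScanMetadata, VelocityTrace

__all__ = [
    "write_volume",
    "read_volume",
    "read_magnitude_tiff",
    "write_trace_csv",
    "read_trace_csv",
    "write_mask",
    "read_mask",
    "write_json",
    "write_tiff_stack",
]

SCHEMA_VERSION = 1
_META_KEYS = tuple(ScanMetadata().to_dict())
_CSV_FLOAT_FORMAT = "%.10g"


def write_volume(volume: ComplexVolume, path: Union[str, Path]) -> None:
    """Write a complex volume to HDF5 (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["layout"] = volume.layout
        f.attrs["magnitude_only"] = volume.magnitude_only
        if volume.magnitude_only:
            f.create_dataset("magnitude", data=volume.values)
        else:
            f.create_dataset("real", data=volume.values.real)
            f.create_dataset("imag", data=volume.values.imag)
        g = f.create_group("metadata")
        for k, v in volume.metadata.to_dict().items():
            g.attrs[k] = v


def read_volume(path: Union[str, Path]) -> ComplexVolume:
    """Read a complex (or magnitude-only) volume written by
    :func:`write_volume`; missing metadata attributes raise by name."""
    with h5py.File(path, "r") as f:
        if "metadata" not in f:
            raise ValueError(f"{path}: missing metadata group")
        attrs = f["metadata"].attrs
        missing = [k for k in _META_KEYS if k not in attrs]
        if missing:
            raise ValueError(f"{path}: missing metadata attribute(s) {missing}")
        meta = ScanMetadata.from_dict({k: attrs[k] for k in _META_KEYS})
        layout = str(f.attrs["layout"])
        magnitude_only = bool(f.attrs.get("magnitude_only", False))
        if magnitude_only:
            values = f["magnitude"][()]
        else:
            values = f["real"][()] + 1j * f["imag"][()]
    return ComplexVolume(values=values, metadata=meta, layout=layout,
                         magnitude_only=magnitude_only)


def read_magnitude_tiff(path: Union[str, Path], metadata: ScanMetadata,
                        layout: str = "zxt") -> ComplexVolume:
    """Import a legacy intensity-only TIFF stack.

    The pages are stacked along the last axis of ``layout``.  The resulting
    volume is flagged magnitude-only, which disables phase operations
    downstream.
    """
    pages = tifffile.imread(str(path))
    values = np.moveaxis(np.asarray(pages, dtype=float), 0, -1)
    return ComplexVolume(values=values, metadata=metadata, layout=layout,
                         magnitude_only=True)


def write_trace_csv(traces, path: Union[str, Path]) -> None:
    """Write one or several velocity traces to a tidy CSV."""
    if isinstance(traces, VelocityTrace):
        traces = [traces]
    frame = pd.concat([t.to_frame() for t in traces], ignore_index=True)
    frame.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def read_trace_csv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def write_mask(mask_values: np.ndarray, path: Union[str, Path],
               threshold_fraction: float, reference: float) -> None:
    """Write a binary mask to HDF5 with a JSON sidecar of its provenance."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("mask", data=np.asarray(mask_values, dtype=bool))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"threshold_fraction": threshold_fraction, "reference_value": reference},
            indent=2, sort_keys=True,
        )
        + "\n"
    )


def read_mask(path: Union[str, Path]):
    path = Path(path)
    with h5py.File(path, "r") as f:
        mask = f["mask"][()].astype(bool)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return mask, meta


def write_json(obj, path: Union[str, Path]) -> None:
    """Deterministically formatted JSON (sorted keys, fixed precision)."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n"
    )


def write_tiff_stack(values: np.ndarray, path: Union[str, Path],
                     page_axis: int = -1) -> None:
    """Export an array as a multi-page float32 TIFF (one page per B-scan)."""
    pages = np.moveaxis(np.asarray(values, dtype=np.float32), page_axis, 0)
    tifffile.imwrite(str(path), pages, photometric="minisblack")
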