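"""Complex-subtraction angiography, RPE flattening and vessel masking.

The angiogram contrast comes from differences between repeated complex
B-scans: moving blood decorrelates between repeats while static tissue
cancels.  Masks are generated by the two-filter global-threshold scheme: a
gentle 3x3 average (Angio3) for the data that is thresholded, a more
aggressive 10x10 average (Angio10) to derive a robust per-C-scan reference
value, and a single global threshold at a fraction (default 9%, alternate
12%) of that reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import median_filter, uniform_filter

from .core import ComplexVolume

__all__ = [
    "AngiogramVolume",
    "VesselMask",
    "flatten_by_rpe",
    "complex_subtraction_angiogram",
    "angiogram_volume",
    "smooth",
    "reference_value",
    "binarize",
]


@dataclass
class AngiogramVolume:
    """Non-negative angiogram data plus provenance of how it was produced."""

    values: np.ndarray
    n_repeats: int
    filter_applied: str = "none"  # none | 3x3 | 10x10

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("angiogram values must be non-negative")
        if self.filter_applied not in ("none", "3x3", "10x10"):
            raise ValueError(f"unknown filter tag {self.filter_applied!r}")


@dataclass
class VesselMask:
    """Binary vessel mask with the threshold that produced it."""

    values: np.ndarray
    threshold_fraction: float
    reference_value: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


def flatten_by_rpe(volume: ComplexVolume, min_band_fraction: float = 0.5,
                   band_tolerance_px: int = 3) -> Tuple[ComplexVolume, np.ndarray]:
    """Flatten the retina by integer axial shifts that align the RPE band.

    The brightest depth per fast-axis column (of the time/repeat-averaged
    intensity) is taken as the RPE; every column is rolled so that this row
    becomes constant.  Only integer shifts are applied, preserving the
    complex data for downstream phase analysis.

    Returns the flattened volume and the per-column shift map that was
    applied.  Raises ``ValueError`` when no consistent band exists (fewer
    than ``min_band_fraction`` of the columns peak within
    ``band_tolerance_px`` of the median peak row).
    """
    vals = volume.values
    inten = np.abs(vals) ** 2
    # average over the non-spatial axes -> (z, x[, y]) profile; smooth a few
    # columns laterally and median-filter the detected rows so that speckle
    # within the band does not jitter the per-column peak
    if volume.layout == "zxt":
        prof = inten.mean(axis=2)          # (z, x)
        prof = uniform_filter(prof, size=(1, 7), mode="nearest")
        peak = np.argmax(prof, axis=0)     # (x,)
        peak = median_filter(peak, size=5, mode="nearest")
    else:
        prof = inten.mean(axis=3)          # (z, x, y)
        prof = uniform_filter(prof, size=(1, 7, 7), mode="nearest")
        peak = np.argmax(prof, axis=0)     # (x, y)
        peak = median_filter(peak, size=(5, 5), mode="nearest")

    ref_row = int(np.median(peak))
    consistent = np.abs(peak - ref_row) <= band_tolerance_px
    if consistent.mean() < min_band_fraction:
        raise ValueError(
            "no detectable RPE band: only "
            f"{100 * consistent.mean():.0f}% of columns peak within "
            f"{band_tolerance_px} px of the median row"
        )

    # columns without a consistent band (e.g. occluded by a vessel crossing
    # the RPE) inherit the row interpolated from their consistent neighbours
    def _fill(row_1d: np.ndarray, ok_1d: np.ndarray) -> np.ndarray:
        if ok_1d.all():
            return row_1d
        idx = np.arange(row_1d.size)
        if not ok_1d.any():
            return np.full_like(row_1d, ref_row)
        filled = row_1d.astype(float)
        filled[~ok_1d] = np.interp(idx[~ok_1d], idx[ok_1d], row_1d[ok_1d])
        return np.rint(filled).astype(int)

    if peak.ndim == 1:
        peak = _fill(peak, consistent)
    else:
        for y in range(peak.shape[1]):
            peak[:, y] = _fill(peak[:, y], consistent[:, y])

    shifts = ref_row - peak
    out = vals.copy()
    if volume.layout == "zxt":
        for x in range(out.shape[1]):
            if shifts[x]:
                out[:, x] = np.roll(out[:, x], shifts[x], axis=0)
    else:
        for x in range(out.shape[1]):
            for y in range(out.shape[2]):
                if shifts[x, y]:
                    out[:, x, y] = np.roll(out[:, x, y], shifts[x, y], axis=0)
    flat = ComplexVolume(
        values=out, metadata=volume.metadata, layout=volume.layout,
        magnitude_only=volume.magnitude_only,
    )
    return flat, shifts


def complex_subtraction_angiogram(repeats: np.ndarray) -> np.ndarray:
    """Complex-subtraction OCTA signal of one stack of repeated B-scans.

    Parameters
    ----------
    repeats : ndarray, shape (R, nz, nx)
        Co-registered complex B-scan repeats, R >= 2.

    Returns
    -------
    ndarray, shape (nz, nx)
        Mean over the R-1 adjacent pairs of ``|C_{k+1} - C_k|`` after
        removal of each pair's bulk phase offset (the intensity-weighted
        mean phase difference of the whole B-scan), so that bulk motion of
        static tissue does not leak into the angiogram.
    """
    repeats = np.asarray(repeats)
    if repeats.ndim != 3 or repeats.shape[0] < 2:
        raise ValueError("need a stack of at least two complex B-scan repeats")
    if not np.iscomplexobj(repeats):
        raise ValueError("complex-valued repeats required")
    acc = np.zeros(repeats.shape[1:], dtype=float)
    n_pairs = repeats.shape[0] - 1
    for k in range(n_pairs):
        a, b = repeats[k], repeats[k + 1]
        cross = np.vdot(a, b)  # sum conj(a) * b == |a||b|-weighted phase mean
        phi = np.angle(cross) if cross != 0 else 0.0
        acc += np.abs(b * np.exp(-1j * phi) - a)
    return acc / n_pairs


def angiogram_volume(volume: ComplexVolume) -> AngiogramVolume:
    """Apply :func:`complex_subtraction_angiogram` to every slow-axis
    position of a ``(z, x, y, repeat)`` volume."""
    if volume.layout != "zxyr":
        raise ValueError("angiogram_volume expects a (z, x, y, repeat) volume")
    vals = volume.values
    ny = vals.shape[2]
    out = np.empty(vals.shape[:3], dtype=float)
    for y in range(ny):
        out[:, :, y] = complex_subtraction_angiogram(np.moveaxis(vals[:, :, y, :], 2, 0))
    return AngiogramVolume(values=out, n_repeats=vals.shape[3], filter_applied="none")


def smooth(angiogram: AngiogramVolume, kernel: int) -> AngiogramVolume:
    """Uniform-average filtering of each angiogram B-scan.

    ``kernel`` is 3 (Angio3) or 10 (Angio10).  Filtering acts within each
    B-scan only (the ``(z, x)`` plane); borders are handled by edge
    replication.  For even kernels the footprint extends one pixel further
    towards smaller indices, following the ``scipy.ndimage`` convention.
    """
    if kernel not in (3, 10):
        raise ValueError("kernel must be 3 or 10")
    v = angiogram.values
    if min(v.shape[0], v.shape[1]) < kernel:
        raise ValueError("kernel does not fit within the B-scan")
    size = (kernel, kernel) + (1,) * (v.ndim - 2)
    out = uniform_filter(v.astype(float), size=size, mode="nearest")
    return AngiogramVolume(
        values=np.maximum(out, 0.0),
        n_repeats=angiogram.n_repeats,
        filter_applied=f"{kernel}x{kernel}",
    )


def reference_value(angio10: AngiogramVolume) -> float:
    """Global threshold reference for one C-scan.

    For every B-scan of the Angio10 data, the mean across the fast axis at
    each depth yields a 1D depth profile; the maximum entry over all
    (B-scan, depth) profiles is the reference value.
    """
    v = angio10.values
    if v.size == 0:
        raise ValueError("empty angiogram volume")
    profiles = v.mean(axis=1)  # (z,) or (z, n_bscans)
    return float(profiles.max())


def binarize(angio3: AngiogramVolume, reference: float,
             fraction: float = 0.09) -> VesselMask:
    """Global binary thresholding of the Angio3 data.

    The mask is ``angio3 >= fraction * reference`` (pixels exactly at the
    threshold are included).  The default fraction is 9% of the reference;
    12% is the documented alternative for noisier volumes.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    if reference <= 0:
        raise ValueError("reference value must be positive")
    return VesselMask(
        values=angio3.values >= fraction * reference,
        threshold_fraction=fraction,
        reference_value=float(reference),
    )
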