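"""Core containers and unit helpers shared by every stage of the pipeline.

The package works on two acquisition layouts of complex-valued OCT data:

``"zxt"``
    A dynamic-contrast B-scan time series: depth ``z`` x fast axis ``x`` x
    time ``t``, where the same cross-section is resampled once per interscan
    period to follow a contrast bolus.
``"zxyr"``
    A 3D angiography volume: depth ``z`` x fast axis ``x`` x slow axis ``y``
    x repeat, with a handful of repeated B-scans at every slow-axis position.

All phase bookkeeping uses radians wrapped to ``[-pi, pi)`` and all physical
constants needed to convert phase to velocity live in :class:`ScanMetadata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ScanMetadata",
    "ComplexVolume",
    "VelocityTrace",
    "wrap_phase",
    "MM3_PER_S_TO_UL_PER_MIN",
]

#: 1 mm^3/s equals 1 uL/s; flow rates are reported in uL/min.
MM3_PER_S_TO_UL_PER_MIN = 60.0

_LAYOUT_NDIM = {"zxt": 3, "zxyr": 4}


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the half-open interval ``[-pi, pi)``."""
    return (np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class ScanMetadata:
    """Physical acquisition constants governing all velocity conversions.

    Parameters
    ----------
    wavelength_center : float
        Central wavelength of the source in metres.
    refractive_index : float
        Group refractive index of the sample (retinal tissue).
    aline_period : float
        Time between two adjacent A-scans, ``T``, in seconds.
    interscan_time : float
        Time between two B-scans of the same cross-section, in seconds.
    pixel_size_z, pixel_size_x, pixel_size_y : float
        Voxel pitch in metres along depth, fast axis and slow axis.
    n_repeats : int
        Number of repeated B-scans per slow-axis position.
    """

    wavelength_center: float = 840e-9
    refractive_index: float = 1.35
    aline_period: float = 1.0 / 83_000.0
    interscan_time: float = 7.7e-3
    pixel_size_z: float = 2.0e-6
    pixel_size_x: float = 2.0e-6   # 1 mm / 500 A-scans
    pixel_size_y: float = 2.5e-6   # 1 mm / 400 B-scan positions
    n_repeats: int = 5

    def __post_init__(self) -> None:
        for name in (
            "wavelength_center",
            "refractive_index",
            "aline_period",
            "interscan_time",
            "pixel_size_z",
            "pixel_size_x",
            "pixel_size_y",
        ):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"ScanMetadata.{name} must be positive and finite")
        if self.n_repeats < 2:
            raise ValueError("ScanMetadata.n_repeats must be >= 2")

    @property
    def phase_to_axial_velocity(self) -> float:
        """Axial velocity (m/s) per radian of inter-A-scan phase difference.

        The two-beam interferometric relation gives
        ``v_axial = lambda * dphi / (4 pi n T)``.
        """
        return self.wavelength_center / (
            4.0 * np.pi * self.refractive_index * self.aline_period
        )

    @property
    def nyquist_velocity(self) -> float:
        """Axial speed (m/s) at which ``|dphi|`` reaches pi and flow aliases."""
        return self.phase_to_axial_velocity * np.pi

    def to_dict(self) -> dict:
        return {
            "wavelength_center": self.wavelength_center,
            "refractive_index": self.refractive_index,
            "aline_period": self.aline_period,
            "interscan_time": self.interscan_time,
            "pixel_size_z": self.pixel_size_z,
            "pixel_size_x": self.pixel_size_x,
            "pixel_size_y": self.pixel_size_y,
            "n_repeats": self.n_repeats,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanMetadata":
        return cls(**{k: (int(v) if k == "n_repeats" else float(v)) for k, v in d.items()})


@dataclass
class ComplexVolume:
    """Complex OCT data plus the metadata needed to interpret it.

    ``layout`` is ``"zxt"`` for dynamic-contrast B-scan series and ``"zxyr"``
    for 3D angiography volumes.  ``magnitude_only`` marks data imported from
    intensity-only sources; phase operations reject such volumes.
    """

    values: np.ndarray
    metadata: ScanMetadata
    layout: str
    magnitude_only: bool = False

    def __post_init__(self) -> None:
        if self.layout not in _LAYOUT_NDIM:
            raise ValueError(f"unknown layout {self.layout!r}; expected 'zxt' or 'zxyr'")
        if self.values.ndim != _LAYOUT_NDIM[self.layout]:
            raise ValueError(
                f"layout {self.layout!r} requires {_LAYOUT_NDIM[self.layout]} axes, "
                f"got array with {self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ComplexVolume contains non-finite values")
        if not self.magnitude_only and not np.iscomplexobj(self.values):
            raise ValueError("complex dtype required unless magnitude_only=True")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class VelocityTrace:
    """A time-resolved velocity estimate from either velocimetry method.

    ``reliable`` flags samples whose estimate passed the method's confidence
    checks; downstream correlation analysis excludes flagged samples pairwise.
    """

    times: np.ndarray
    values: np.ndarray
    method: str
    window_frames: int = 1
    label: str = ""
    reliable: Optional[np.ndarray] = None
    confidence: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.window_frames < 1:
            raise ValueError("window_frames must be >= 1")
        if self.reliable is None:
            self.reliable = np.ones(self.values.shape, dtype=bool)
        else:
            self.reliable = np.asarray(self.reliable, dtype=bool)
            if self.reliable.shape != self.values.shape:
                raise ValueError("reliable mask shape mismatch")

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "velocity_mm_s": self.values,
                "method": self.method,
                "vessel": self.label,
                "reliable": self.reliable,
            }
        )
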