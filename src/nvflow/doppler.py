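"""Phase-resolved Doppler velocimetry with two-stage phase-bias correction.

The lag-1 (Kasai-type) autocorrelation of adjacent A-scans yields a phase
difference map; the galvo-induced bulk bias is removed per B-scan using the
intensity-weighted circular mean over the RPE band, and the residual static
background bias is removed per depth using flanking regions on either side
of the (dilated) vessel ROI.  The corrected phase converts to axial
velocity as ``V = lambda * dphi / (4 pi n T)`` and to longitudinal velocity
as ``V_D = V_axial / cos(alpha)``.

A lag-1 estimate lives on an A-scan *pair*; the estimate at fast-axis index
``x`` compares A-scans ``x`` and ``x + 1``.  The map keeps the input shape
with the last column carrying zero weight, and ROI statistics only include
pairs wholly inside the ROI (see :func:`pair_interior`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation, uniform_filter1d

from .core import ComplexVolume, ScanMetadata, VelocityTrace, wrap_phase

__all__ = [
    "PhaseDiffMap",
    "VesselROI",
    "VelocityField",
    "phase_difference",
    "bulk_correction",
    "local_background_correction",
    "average_repeats",
    "axial_velocity",
    "longitudinal_velocity",
    "roi_mean_velocity",
    "pair_interior",
    "circular_mean",
]

_STATES = ("raw", "bulk_corrected", "fully_corrected")


def circular_mean(phases: np.ndarray, weights: Optional[np.ndarray] = None,
                  axis=None) -> np.ndarray:
    """Weighted circular mean of wrapped phases, in ``[-pi, pi)``."""
    phases = np.asarray(phases, dtype=float)
    w = np.ones_like(phases) if weights is None else np.asarray(weights, dtype=float)
    s = np.sum(w * np.exp(1j * phases), axis=axis)
    return wrap_phase(np.angle(s))


@dataclass
class PhaseDiffMap:
    """Wrapped phase differences plus pair weights and correction state.

    ``values`` has the same shape as the source volume; entry ``[z, x]``
    describes the A-scan pair ``(x, x + 1)`` and the last fast-axis column
    has weight 0.  ``weights`` are the pair amplitude products
    ``|C(x)| |C(x+1)|`` and serve as intensity weights for circular means.
    """

    values: np.ndarray
    weights: np.ndarray
    layout: str
    correction_state: str = "raw"
    coherence: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.correction_state not in _STATES:
            raise ValueError(f"unknown correction_state {self.correction_state!r}")
        if np.any(self.values >= np.pi) or np.any(self.values < -np.pi):
            raise ValueError("phase values must lie in [-pi, pi)")

    def _advance(self, new_values: np.ndarray, state: str) -> "PhaseDiffMap":
        if _STATES.index(state) < _STATES.index(self.correction_state):
            raise ValueError(
                f"correction state may only advance ({self.correction_state} -> {state})"
            )
        return PhaseDiffMap(
            values=new_values, weights=self.weights, layout=self.layout,
            correction_state=state, coherence=self.coherence,
        )


@dataclass
class VesselROI:
    """Binary vessel mask (per B-scan geometry) with its dilated variant.

    ``mask`` is ``(z, x)`` for B-scan series or ``(z, x, y)`` for volumes;
    dilation uses an 8-connected 3x3 element within each B-scan, matching a
    one-pixel dilation that guarantees full peripheral coverage.
    ``alpha`` is the vessel angle from the incident beam.
    """

    mask: np.ndarray
    alpha: float = 0.0
    label: str = "vessel"
    dilated: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (0.0 <= self.alpha < np.pi / 2):
            raise ValueError("alpha must lie in [0, pi/2)")
        if self.dilated is None:
            structure = np.ones((3, 3), dtype=bool)
            if self.mask.ndim == 3:
                structure = structure[:, :, None]
            self.dilated = binary_dilation(self.mask, structure=structure)
        else:
            self.dilated = np.asarray(self.dilated, dtype=bool)
            if not np.all(self.dilated | ~self.mask):
                raise ValueError("dilated mask must contain the original mask")


def pair_interior(mask: np.ndarray) -> np.ndarray:
    """Pixels whose lag-1 A-scan pair lies wholly inside ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    out[:, :-1] &= mask[:, 1:]
    out[:, -1] = False
    return out


def phase_difference(volume: ComplexVolume) -> PhaseDiffMap:
    """Lag-1 autocorrelation phase along the fast axis, wrapped to
    ``[-pi, pi)``; correction state ``raw``."""
    if volume.magnitude_only:
        raise ValueError("phase_difference requires complex data "
                         "(volume is magnitude-only)")
    v = volume.values
    if v.shape[1] < 2:
        raise ValueError("need at least two A-scans per B-scan")
    pairs = np.conj(v[:, :-1]) * v[:, 1:]
    values = np.zeros(v.shape, dtype=float)
    weights = np.zeros(v.shape, dtype=float)
    values[:, :-1] = wrap_phase(np.angle(pairs))
    weights[:, :-1] = np.abs(pairs)
    return PhaseDiffMap(values=values, weights=weights, layout=volume.layout,
                        correction_state="raw")


def bulk_correction(pd: PhaseDiffMap, rpe_mask: np.ndarray,
                    intensities: Optional[np.ndarray] = None) -> PhaseDiffMap:
    """Remove the per-B-scan galvo bulk phase bias.

    For every B-scan, the intensity-weighted circular mean of the phase
    difference over the RPE band is subtracted.  ``intensities`` overrides
    the default pair-amplitude weights.
    """
    rpe = np.asarray(rpe_mask, dtype=bool)
    w = pd.weights if intensities is None else np.asarray(intensities, dtype=float)
    vals = pd.values
    out = np.empty_like(vals)

    def _one(v2d: np.ndarray, w2d: np.ndarray, rpe2d: np.ndarray, name: str):
        sel = rpe2d & (w2d > 0)
        if not sel.any():
            raise ValueError(f"empty RPE mask in B-scan {name}")
        mu = circular_mean(v2d[sel], w2d[sel])
        return wrap_phase(v2d - mu)

    if pd.layout == "zxt":
        rpe2 = rpe if rpe.ndim == 2 else rpe[..., 0]
        for t in range(vals.shape[2]):
            out[:, :, t] = _one(vals[:, :, t], w[:, :, t], rpe2, f"t={t}")
    else:
        for y in range(vals.shape[2]):
            rpe2 = rpe if rpe.ndim == 2 else rpe[:, :, y]
            for r in range(vals.shape[3]):
                out[:, :, y, r] = _one(vals[:, :, y, r], w[:, :, y, r], rpe2,
                                       f"y={y}, repeat={r}")
    return pd._advance(out, "bulk_corrected")


def _flank_columns(dilated_row: np.ndarray, exclude_row: np.ndarray,
                   halfwidth: int) -> np.ndarray:
    """Column indices of the two flanking bands at one depth.

    A lag-1 estimate at column ``x`` involves A-scans ``x`` and ``x + 1``,
    so a flank column is rejected when either member of its pair falls in
    the exclusion mask.
    """
    cols = np.flatnonzero(dilated_row)
    x0, x1 = cols.min(), cols.max()
    nx = dilated_row.size
    left = np.arange(max(x0 - halfwidth, 0), x0)
    right = np.arange(x1 + 1, min(x1 + 1 + halfwidth, nx))
    flank = np.concatenate([left, right])
    if flank.size == 0:
        return flank
    pair_excluded = exclude_row.copy()
    pair_excluded[:-1] |= exclude_row[1:]
    return flank[~pair_excluded[flank]]


def local_background_correction(
    pd: PhaseDiffMap,
    roi: VesselROI,
    flank_halfwidth: int = 15,
    exclude_mask: Optional[np.ndarray] = None,
) -> PhaseDiffMap:
    """Remove the residual static background bias around one vessel.

    For every depth with vessel pixels, the mean phase difference over two
    flanking bands — ``flank_halfwidth`` pixels on either side of the
    dilated ROI in the fast axis, averaged over a +/- ``flank_halfwidth``
    window in the temporal (or slow) axis — is subtracted from the
    pre-dilation mask pixels at that depth.  Pixels of ``exclude_mask``
    (default: this vessel's dilated mask; pass a union to exclude other
    vessels) never contribute to the flanks.
    """
    vals = pd.values.copy()
    w = pd.weights
    mask = roi.mask
    dil = roi.dilated
    excl = dil if exclude_mask is None else (np.asarray(exclude_mask, bool) | dil)

    if pd.layout == "zxt":
        mask2, dil2, excl2 = mask, dil, excl
        if mask2.ndim != 2:
            raise ValueError("zxt layout expects a (z, x) vessel mask")
        n_frames = vals.shape[2]
        for z in np.flatnonzero(mask2.any(axis=1)):
            flank = _flank_columns(dil2[z], excl2[z], flank_halfwidth)
            if flank.size == 0:
                raise ValueError(
                    f"flanking region at depth {z} is entirely consumed by "
                    "vessel masks"
                )
            # complex per-frame flank mean, then boxcar over +/- halfwidth frames
            s = np.sum(w[z, flank, :] * np.exp(1j * vals[z, flank, :]), axis=0)
            width = min(2 * flank_halfwidth + 1, n_frames)
            sm = uniform_filter1d(s.real, width, mode="nearest") + 1j * uniform_filter1d(
                s.imag, width, mode="nearest"
            )
            bias = np.angle(sm)
            cols = mask2[z]
            vals[z, cols, :] = wrap_phase(vals[z, cols, :] - bias[None, :])
    else:
        if mask.ndim != 3:
            raise ValueError("zxyr layout expects a (z, x, y) vessel mask")
        ny = vals.shape[2]
        for z in range(mask.shape[0]):
            if not mask[z].any():
                continue
            # flank bands per slow-axis position, then boxcar across y
            s = np.zeros((ny, vals.shape[3]), dtype=complex)
            ok = np.zeros(ny, dtype=bool)
            for y in range(ny):
                if not dil[z, :, y].any():
                    continue
                flank = _flank_columns(dil[z, :, y], excl[z, :, y], flank_halfwidth)
                if flank.size == 0:
                    raise ValueError(
                        f"flanking region at depth {z}, y={y} is entirely "
                        "consumed by vessel masks"
                    )
                s[y] = np.sum(
                    w[z, flank, y, :] * np.exp(1j * vals[z, flank, y, :]), axis=0
                )
                ok[y] = True
            ys = np.flatnonzero(ok)
            width = min(2 * flank_halfwidth + 1, ys.size)
            sm = uniform_filter1d(s[ys].real, width, axis=0, mode="nearest") + (
                1j * uniform_filter1d(s[ys].imag, width, axis=0, mode="nearest")
            )
            bias = np.angle(sm)  # (len(ys), n_rep)
            for j, y in enumerate(ys):
                cols = mask[z, :, y]
                if cols.any():
                    vals[z, cols, y, :] = wrap_phase(vals[z, cols, y, :] - bias[j][None, :])
    return pd._advance(vals, "fully_corrected")


def average_repeats(pd: PhaseDiffMap) -> PhaseDiffMap:
    """Voxelwise circular mean across the repeat axis of a ``zxyr`` map.

    The result carries layout ``"zxy"`` (one repeat-averaged map per
    slow-axis position).  A map without a repeat axis is returned unchanged
    with a warning.
    """
    if pd.layout != "zxyr":
        warnings.warn("single repeat: average_repeats is the identity",
                      RuntimeWarning, stacklevel=2)
        return pd
    s = np.sum(pd.weights * np.exp(1j * pd.values), axis=3)
    values = wrap_phase(np.angle(s))
    weights = np.abs(s) / pd.values.shape[3]
    # repeat coherence: 1 when all repeats agree in phase, ~1/sqrt(R) for
    # incoherent (phase-noise dominated) voxels such as vessel walls
    w_tot = pd.weights.sum(axis=3)
    coherence = np.abs(s) / np.maximum(w_tot, 1e-300)
    coherence[w_tot == 0] = 0.0
    return PhaseDiffMap(values=values, weights=weights, layout="zxy",
                        correction_state=pd.correction_state,
                        coherence=coherence)


@dataclass
class VelocityField:
    """Signed velocity map (mm/s) sharing the pair weights of its source."""

    values: np.ndarray
    weights: np.ndarray
    layout: str
    correction_state: str
    coherence: Optional[np.ndarray] = None


def axial_velocity(pd: PhaseDiffMap, meta: ScanMetadata,
                   require_corrected: bool = True) -> VelocityField:
    """Convert corrected phase differences to axial velocity in mm/s.

    ``V = lambda * dphi / (4 pi n T)``, positive towards increasing depth
    (into the choroid).
    """
    if require_corrected and pd.correction_state != "fully_corrected":
        raise ValueError(
            f"axial_velocity expects a fully corrected map "
            f"(state is {pd.correction_state!r})"
        )
    scale = meta.phase_to_axial_velocity * 1e3  # mm/s per radian
    return VelocityField(values=pd.values * scale, weights=pd.weights,
                         layout=pd.layout, correction_state=pd.correction_state,
                         coherence=pd.coherence)


def longitudinal_velocity(v_axial, alpha: float, margin: float = 0.1):
    """Project axial velocity onto the vessel axis: ``V_D = V_axial / cos a``.

    Rejects vessels within ``margin`` radians of perpendicular, where the
    projection blows up and Doppler velocimetry is unusable.
    """
    if not (0.0 <= alpha < np.pi / 2 - margin):
        raise ValueError(
            f"vessel angle {alpha:.3f} rad is within {margin} rad of "
            "perpendicular; longitudinal velocity undefined"
        )
    if isinstance(v_axial, VelocityField):
        return VelocityField(values=v_axial.values / np.cos(alpha),
                             weights=v_axial.weights, layout=v_axial.layout,
                             correction_state=v_axial.correction_state,
                             coherence=v_axial.coherence)
    return np.asarray(v_axial) / np.cos(alpha)


def roi_mean_velocity(field: VelocityField, roi: VesselROI, meta: ScanMetadata,
                      pairs: str = "interior",
                      weighted: bool = False) -> VelocityTrace:
    """Net (signed-mean) velocity over the vessel ROI, one value per frame.

    ``pairs="interior"`` restricts the average to pixels whose A-scan pair
    lies wholly inside the pre-dilation mask (lag-1 estimates at the ROI
    boundary mix vessel and background signal); ``pairs="all"`` uses every
    mask pixel with nonzero weight.  Frames with an empty ROI yield NaN.
    """
    if field.layout != "zxt":
        raise ValueError("roi_mean_velocity expects a (z, x, t) field")
    mask = pair_interior(roi.mask) if pairs == "interior" else roi.mask
    nt = field.values.shape[2]
    out = np.empty(nt)
    sel2 = mask
    for t in range(nt):
        w = field.weights[:, :, t]
        sel = sel2 & (w > 0)
        if not sel.any():
            out[t] = np.nan
            continue
        if weighted:
            out[t] = np.average(field.values[:, :, t][sel], weights=w[sel])
        else:
            out[t] = field.values[:, :, t][sel].mean()
    times = meta.interscan_time * np.arange(nt)
    return VelocityTrace(times=times, values=out, method="doppler",
                         window_frames=1, label=roi.label)
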