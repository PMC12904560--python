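"""En-face flowmetry and flow-directionality statistics.

Integrating the corrected axial velocity over an en-face window that
encompasses a vessel yields the volumetric flow rate through that depth
plane: ``Q = integral of v_axial dx dy``.  The integral is invariant to the
vessel angle because the axial projection of the velocity and the enlarged
en-face footprint of a tilted tube cancel.  Flow is reported in uL/min
with the convention that negative values flow from the choroid into the
retina.

Per-animal directionality aggregates signed flows across
neovascularisations (NVs) and timepoints: the directionality index is the
mean net flow divided by the mean total unsigned flow, +1 when all flow
enters the choroid and -1 when all flow leaves it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import MM3_PER_S_TO_UL_PER_MIN
from .doppler import VelocityField

__all__ = [
    "EnFaceVelocityMap",
    "NVAnnotation",
    "FlowRecord",
    "DirectionalityStats",
    "en_face_map",
    "flow_rate",
    "select_depth_plane",
    "directionality_stats",
    "detect_reversals",
    "reversal_fraction",
]


@dataclass
class EnFaceVelocityMap:
    """Axial-velocity slice (x, y) at one depth, in mm/s.

    ``coherence`` (optional) is the repeat-coherence of each phase
    estimate; :func:`flow_rate` uses it as a phase-noise mask.
    """

    values: np.ndarray
    pixel_area_mm2: float
    depth_index: int
    correction_state: str = "fully_corrected"
    coherence: Optional[np.ndarray] = None


@dataclass
class NVAnnotation:
    """Manually placed NV annotation guiding flow measurement.

    ``window`` is an axis-aligned ``(x0, x1, y0, y1)`` rectangle (half-open
    bounds) encompassing the vessel in the en-face plane; ``z_range`` is
    the half-open axial extent of the NV; ``depth_override`` forces a
    specific depth plane instead of automatic selection.
    """

    label: str
    window: Tuple[int, int, int, int]
    z_range: Tuple[int, int]
    depth_override: Optional[int] = None


@dataclass
class FlowRecord:
    """Flow rate of one NV at one timepoint (uL/min, signed)."""

    label: str
    timepoint: str
    q_ul_min: float
    depth_index: int
    window: Tuple[int, int, int, int]


@dataclass
class DirectionalityStats:
    """Per-animal flow aggregates across NVs and post-injection timepoints."""

    total_into_choroid: float       # mean over timepoints of sum(max(Q, 0))
    total_out_of_choroid: float     # mean over timepoints of sum(max(-Q, 0))
    net_into_choroid: float
    directionality: float           # net / total, NaN when total flow is zero
    n_timepoints: int
    n_vessels: int

    def __post_init__(self) -> None:
        if np.isfinite(self.directionality) and not -1.0 <= self.directionality <= 1.0 + 1e-12:
            raise ValueError("directionality index must lie in [-1, 1]")


def en_face_map(field: VelocityField, depth_index: int,
                pixel_size_x_m: float, pixel_size_y_m: float) -> EnFaceVelocityMap:
    """Extract the (x, y) axial-velocity slice at one depth of a repeat-
    averaged ``(z, x, y)`` velocity field."""
    if field.values.ndim != 3:
        raise ValueError("en_face_map expects a (z, x, y) velocity field")
    if not (0 <= depth_index < field.values.shape[0]):
        raise ValueError("depth index outside the volume")
    return EnFaceVelocityMap(
        values=field.values[depth_index],
        pixel_area_mm2=(pixel_size_x_m * 1e3) * (pixel_size_y_m * 1e3),
        depth_index=depth_index,
        correction_state=field.correction_state,
        coherence=None if field.coherence is None else field.coherence[depth_index],
    )


def flow_rate(emap: EnFaceVelocityMap, window: Tuple[int, int, int, int],
              label: str = "NV", timepoint: str = "post",
              coherence_floor: float = 0.8) -> FlowRecord:
    """Integrate signed axial velocity over the annotation window.

    ``Q = sum(v) * pixel_area`` converted to uL/min.  Background inside the
    window is included by design — the bias corrections are what null it —
    so the result is the total flow through the plane within the window.

    When the map carries repeat-coherence values, pixels below
    ``coherence_floor`` are excluded: their phase estimates are dominated
    by the incoherent mixing of static and intravascular signal at vessel
    walls and carry arbitrary, near-Nyquist velocity junk (a standard
    phase-noise mask; pass 0 to disable).
    """
    if emap.correction_state != "fully_corrected":
        raise ValueError("flow integration requires fully corrected velocities")
    x0, x1, y0, y1 = window
    nx, ny = emap.values.shape
    if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny):
        raise ValueError(
            f"window {window} is clipped by the map edge (shape {emap.values.shape})"
        )
    vals = emap.values[x0:x1, y0:y1]
    if emap.coherence is not None and coherence_floor > 0:
        vals = np.where(emap.coherence[x0:x1, y0:y1] >= coherence_floor, vals, 0.0)
    q_mm3_s = float(vals.sum()) * emap.pixel_area_mm2
    return FlowRecord(
        label=label,
        timepoint=timepoint,
        q_ul_min=q_mm3_s * MM3_PER_S_TO_UL_PER_MIN,
        depth_index=emap.depth_index,
        window=window,
    )


def flow_rate_band(field: VelocityField, annotation: NVAnnotation,
                   depth_index: int, pixel_size_x_m: float, pixel_size_y_m: float,
                   band: int = 5, timepoint: str = "post",
                   coherence_floor: float = 0.8) -> FlowRecord:
    """Flow rate averaged over a small band of depth planes.

    Every en-face plane through a tube carries the same volumetric flux,
    so averaging :func:`flow_rate` over up to ``band`` planes centred on
    ``depth_index`` (clipped to the NV's axial extent) suppresses the
    vessel-wall phase noise of any single plane without changing the
    measured quantity.  The record reports the centre depth.
    """
    z0, z1 = annotation.z_range
    half = band // 2
    lo = max(depth_index - half, z0)
    hi = min(depth_index + half + 1, z1)
    if hi <= lo:
        lo, hi = depth_index, depth_index + 1
    qs = []
    for z in range(lo, hi):
        emap = en_face_map(field, z, pixel_size_x_m, pixel_size_y_m)
        qs.append(flow_rate(emap, annotation.window, label=annotation.label,
                            timepoint=timepoint,
                            coherence_floor=coherence_floor).q_ul_min)
    return FlowRecord(
        label=annotation.label, timepoint=timepoint,
        q_ul_min=float(np.mean(qs)), depth_index=depth_index,
        window=annotation.window,
    )


def select_depth_plane(field: VelocityField, annotation: NVAnnotation,
                       flank_margin: int = 4) -> int:
    """Choose the depth plane with the clearest vessel cross-section.

    Among depths within the NV's axial extent, the plane maximising the
    contrast between mean ``|v|`` inside the annotation window and mean
    ``|v|`` in a surrounding flank ring is selected; ties break towards the
    shallower plane.  ``depth_override`` short-circuits the search.
    """
    nz, nx, ny = field.values.shape
    if annotation.depth_override is not None:
        if not (0 <= annotation.depth_override < nz):
            raise ValueError("depth override outside the volume")
        return int(annotation.depth_override)
    z0, z1 = annotation.z_range
    if not (0 <= z0 < z1 <= nz):
        raise ValueError("NV axial extent empty or outside the volume")
    x0, x1, y0, y1 = annotation.window
    if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny):
        raise ValueError("annotation window outside the volume")
    rx0, rx1 = max(x0 - flank_margin, 0), min(x1 + flank_margin, nx)
    ry0, ry1 = max(y0 - flank_margin, 0), min(y1 + flank_margin, ny)
    ring = np.ones((rx1 - rx0, ry1 - ry0), dtype=bool)
    ring[x0 - rx0: x1 - rx0, y0 - ry0: y1 - ry0] = False

    best_z, best_contrast = z0, -np.inf
    for z in range(z0, z1):
        speed = np.abs(field.values[z])
        inner = speed[x0:x1, y0:y1].mean()
        outer = speed[rx0:rx1, ry0:ry1][ring].mean() if ring.any() else 0.0
        contrast = inner - outer
        if contrast > best_contrast:  # strict: ties keep the shallower plane
            best_z, best_contrast = z, contrast
    return best_z


def _by_timepoint(records: Sequence[FlowRecord]) -> Dict[str, List[FlowRecord]]:
    out: Dict[str, List[FlowRecord]] = {}
    for r in records:
        out.setdefault(r.timepoint, []).append(r)
    return out


def directionality_stats(records: Sequence[FlowRecord]) -> DirectionalityStats:
    """Aggregate signed NV flows of one animal into directionality metrics.

    Pre-injection records (timepoint ``"pre"``) are excluded; per
    post-injection timepoint the flows into and out of the choroid are
    summed over NVs, then averaged over timepoints.  The directionality
    index is mean net flow over mean total flow, NaN (missing-value
    marker) when the total flow is zero.
    """
    post = {tp: rs for tp, rs in _by_timepoint(records).items() if tp != "pre"}
    if not post:
        raise ValueError("need at least one post-injection record")
    into, out_of = [], []
    for tp in sorted(post):
        q = np.array([r.q_ul_min for r in post[tp]])
        into.append(q[q > 0].sum())
        out_of.append(-q[q < 0].sum())
    into_m, out_m = float(np.mean(into)), float(np.mean(out_of))
    total = into_m + out_m
    directionality = (into_m - out_m) / total if total > 0 else float("nan")
    return DirectionalityStats(
        total_into_choroid=into_m,
        total_out_of_choroid=out_m,
        net_into_choroid=into_m - out_m,
        directionality=directionality,
        n_timepoints=len(post),
        n_vessels=len({r.label for r in records}),
    )


def detect_reversals(records: Sequence[FlowRecord],
                     noise_floor: float = 0.0) -> Dict[str, bool]:
    """Flag NVs whose flow direction reverses post-injection.

    An NV reverses when the sign of ``Q`` changes between two consecutive
    post-injection timepoints with ``|Q|`` above ``noise_floor`` at both.
    The default floor of 0 counts every sign change; a positive floor
    classifies persistently near-zero vessels (isolated, non-perfused NVs)
    as stable.
    """
    by_label: Dict[str, List[FlowRecord]] = {}
    for r in records:
        if r.timepoint != "pre":
            by_label.setdefault(r.label, []).append(r)
    flags: Dict[str, bool] = {}
    for label, rs in by_label.items():
        rs = sorted(rs, key=lambda r: r.timepoint)
        flag = False
        for a, b in zip(rs[:-1], rs[1:]):
            if (
                abs(a.q_ul_min) > noise_floor
                and abs(b.q_ul_min) > noise_floor
                and np.sign(a.q_ul_min) != np.sign(b.q_ul_min)
            ):
                flag = True
                break
        flags[label] = flag
    return flags


def reversal_fraction(records: Sequence[FlowRecord],
                      noise_floor: float = 0.0) -> float:
    """Fraction (in percent) of NVs exhibiting a flow reversal."""
    flags = detect_reversals(records, noise_floor=noise_floor)
    if not flags:
        raise ValueError("no post-injection records")
    return 100.0 * sum(flags.values()) / len(flags)
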