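"""Synthetic complex-OCT scenes with full ground truth.

The generator emulates the two acquisition protocols the analysis pipeline
consumes: a dynamic-contrast B-scan time series (``zxt``) and a 3D
angiography volume with repeated B-scans (``zxyr``).  Every scene consists
of

* static tissue speckle — a positive amplitude field with zero intrinsic
  phase, so that static voxels carry no inter-A-scan phase difference of
  their own;
* a bright static band standing in for the retinal pigment epithelium
  (RPE), used downstream as alignment and bulk-phase reference;
* tube-like vessels whose lumped scatterer pattern advects along the
  centerline at a configurable signed speed, producing kymograph streaks,
  inter-repeat decorrelation, and the Doppler phase shift
  ``dphi = 4 pi n T v_axial / lambda`` from a single mechanism;
* a per-B-scan galvo phase ramp (optionally depth-dependent) and additive
  complex noise.

Inside a vessel the rendered field is ``a(s - int v dt) * exp(i w T x)``
with a *real positive* amplitude pattern ``a``: interior A-scan pairs then
carry exactly the configured Doppler phase, while partial-volume voxels at
the wall (handled through a smooth coverage ramp) yield bounded,
intermediate phase values, as they do in real data.

All randomness flows from the scene's single integer seed through one
:class:`numpy.random.Generator`; identical scenes are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import ComplexVolume, ScanMetadata

__all__ = [
    "BolusCurve",
    "bolus_enhancement",
    "SyntheticVessel",
    "SyntheticScene",
    "VesselTruth",
    "GroundTruth",
    "straight_vessel",
    "simulate_dyc_series",
    "simulate_angio_volume",
]

#: m^3/s -> uL/min (1 m^3 = 1e9 uL)
_M3_S_TO_UL_MIN = 1e9 * 60.0

SpeedProfile = Union[float, Callable[[np.ndarray], np.ndarray]]


# --------------------------------------------------------------------------
# bolus kinetics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BolusCurve:
    """Intensity enhancement time course of a contrast bolus.

    A gamma-variate wash-in/wash-out rides on a smooth step towards a
    residual plateau: enhancement is 1 before ``arrival_time``, peaks near
    ``arrival_time + rise_time`` at roughly ``peak_enhancement``, and decays
    towards ``residual_plateau`` (recirculating contrast keeps the signal
    above its pre-injection baseline).
    """

    arrival_time: float = 3.0
    peak_enhancement: float = 4.0
    rise_time: float = 1.5
    decay_time: float = 8.0
    residual_plateau: float = 2.0

    def __post_init__(self) -> None:
        if self.rise_time <= 0 or self.decay_time <= 0:
            raise ValueError("rise_time and decay_time must be positive")
        if not (self.peak_enhancement >= self.residual_plateau >= 1.0):
            raise ValueError(
                "require peak_enhancement >= residual_plateau >= 1 "
                f"(got peak={self.peak_enhancement}, plateau={self.residual_plateau})"
            )

    def enhancement(self, t: Union[float, np.ndarray]) -> np.ndarray:
        return bolus_enhancement(self, t)


def bolus_enhancement(curve: BolusCurve, t: Union[float, np.ndarray]) -> np.ndarray:
    """Evaluate the bolus enhancement factor at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("bolus_enhancement requires t >= 0")
    tau = np.maximum(t - curve.arrival_time, 0.0)
    # normalised gamma-variate peaking at tau = rise_time with value 1
    a = curve.rise_time / curve.decay_time
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(
            tau > 0,
            np.exp(
                a * np.log(np.where(tau > 0, tau, 1.0) / curve.rise_time)
                + a
                - tau / curve.decay_time
            ),
            0.0,
        )
    rise = 1.0 - np.exp(-tau / curve.rise_time)
    enh = (
        1.0
        + (curve.residual_plateau - 1.0) * rise
        + (curve.peak_enhancement - curve.residual_plateau) * g
    )
    return enh if enh.ndim else float(enh)


# --------------------------------------------------------------------------
# scene description
# --------------------------------------------------------------------------

@dataclass
class SyntheticVessel:
    """A tube-like vessel with known geometry, speed and bolus response.

    ``centerline`` is given in voxel coordinates, ``(z, x)`` for B-scan
    scenes or ``(z, x, y)`` for 3D scenes.  ``speed_profile`` is the signed
    longitudinal speed (m/s) along the centerline direction (first node to
    last); with a centerline oriented towards increasing depth, negative
    speed means flow from the choroid into the retina.
    """

    centerline: np.ndarray
    radius: float
    angle_alpha: float
    speed_profile: SpeedProfile = 1e-3
    backscatter_baseline: float = 2.0
    bolus: Optional[BolusCurve] = None
    label: str = "vessel"

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[0] < 2:
            raise ValueError("centerline needs at least two nodes")
        if self.radius <= 0:
            raise ValueError("vessel radius must be positive")
        if not (0.0 <= self.angle_alpha < np.pi / 2):
            raise ValueError("angle_alpha must lie in [0, pi/2)")

    def speed(self, t: np.ndarray) -> np.ndarray:
        if callable(self.speed_profile):
            return np.asarray(self.speed_profile(np.asarray(t, dtype=float)), dtype=float)
        return np.full(np.shape(t), float(self.speed_profile))


def straight_vessel(
    *,
    metadata: ScanMetadata,
    dims: Sequence[int],
    angle_alpha: float,
    radius: float,
    center: Optional[Sequence[float]] = None,
    azimuth: float = 0.0,
    speed_profile: SpeedProfile = 1e-3,
    backscatter_baseline: float = 2.0,
    bolus: Optional[BolusCurve] = None,
    half_length: Optional[float] = None,
    label: str = "vessel",
) -> SyntheticVessel:
    """Build a straight vessel crossing the volume centre at angle ``alpha``.

    The centerline is oriented towards increasing depth ``z`` (towards the
    choroid), so positive speeds flow retina -> choroid.  ``dims`` lists the
    *spatial* extents only: ``(nz, nx)`` for B-scan scenes or
    ``(nz, nx, ny)`` for 3D scenes.  For 3D scenes ``azimuth`` rotates the
    transverse component from the ``x`` axis towards ``y``.  The line is
    clipped to the volume extent; ``half_length`` (metres) additionally
    limits the centerline to that distance either side of ``center``.
    """

    nd = len(dims)
    if nd not in (2, 3):
        raise ValueError("dims must list 2 or 3 spatial extents")
    pitches = np.array(
        [metadata.pixel_size_z, metadata.pixel_size_x, metadata.pixel_size_y][:nd]
    )
    shape = np.asarray(dims[:nd], dtype=float)
    if center is None:
        center = shape / 2.0
    center = np.asarray(center, dtype=float)
    if nd == 2:
        direction = np.array([np.cos(angle_alpha), np.sin(angle_alpha)])
    else:
        direction = np.array(
            [
                np.cos(angle_alpha),
                np.sin(angle_alpha) * np.cos(azimuth),
                np.sin(angle_alpha) * np.sin(azimuth),
            ]
        )
    # march in physical space, convert back to voxel coordinates
    c_phys = center * pitches
    extent = shape * pitches
    # find parameter range keeping the line inside the volume
    tmin, tmax = -np.inf, np.inf
    for ax in range(nd):
        if abs(direction[ax]) < 1e-12:
            continue
        lo = (0.0 - c_phys[ax]) / direction[ax]
        hi = (extent[ax] - pitches[ax] - c_phys[ax]) / direction[ax]
        lo, hi = min(lo, hi), max(lo, hi)
        tmin, tmax = max(tmin, lo), min(tmax, hi)
    if not np.isfinite(tmin) or not np.isfinite(tmax) or tmax <= tmin:
        raise ValueError("straight vessel does not intersect the volume")
    if half_length is not None:
        tmin, tmax = max(tmin, -half_length), min(tmax, half_length)
        if tmax <= tmin:
            raise ValueError("half_length leaves no centerline inside the volume")
    p0 = np.clip((c_phys + tmin * direction) / pitches, 0.0, shape - 1.0)
    p1 = np.clip((c_phys + tmax * direction) / pitches, 0.0, shape - 1.0)
    return SyntheticVessel(
        centerline=np.stack([p0, p1]),
        radius=radius,
        angle_alpha=angle_alpha,
        speed_profile=speed_profile,
        backscatter_baseline=backscatter_baseline,
        bolus=bolus,
        label=label,
    )


@dataclass
class SyntheticScene:
    """Full description of a synthetic acquisition.

    ``dims`` is ``(nz, nx, nt)`` for dynamic-contrast series and
    ``(nz, nx, ny)`` for 3D angiography scenes (repeats come from the
    metadata).  ``galvo_ramp`` is the per-A-scan phase bias in radians that
    the scanning galvo imprints linearly across each B-scan;
    ``depth_phase_bias`` optionally adds a depth-dependent component
    (radians per A-scan, indexed by ``z``).
    """

    metadata: ScanMetadata = field(default_factory=ScanMetadata)
    dims: Sequence[int] = (64, 96, 128)
    rpe_depth_index: int = 48
    vessels: List[SyntheticVessel] = field(default_factory=list)
    galvo_ramp: float = 0.0
    depth_phase_bias: Optional[np.ndarray] = None
    noise_sigma: float = 0.0
    seed: int = 0
    tissue_mean: float = 1.0
    rpe_gain: float = 12.0
    rpe_halfwidth: int = 0
    rpe_tilt_px: float = 0.0
    acquisition_start_time: float = 0.0
    edge_width_px: float = 1.5
    #: amplitude of the fully decorrelating choroid band below the RPE
    #: (0 disables it).  The perfused choroid re-randomises between frames
    #: and repeats, dominating the angiogram's depth profile and thereby
    #: setting a realistic global-threshold reference value.
    choroid_amp: float = 0.0
    choroid_gap_px: int = 3

    def __post_init__(self) -> None:
        nz = int(self.dims[0])
        if not (0 <= self.rpe_depth_index < nz):
            raise ValueError("rpe_depth_index outside the depth extent")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def choroid_rows(self) -> np.ndarray:
        nz = int(self.dims[0])
        start = self.rpe_depth_index + self.rpe_halfwidth + self.choroid_gap_px
        if self.choroid_amp <= 0 or start >= nz:
            return np.arange(0)
        return np.arange(start, nz)

    def depth_bias_array(self) -> np.ndarray:
        nz = int(self.dims[0])
        if self.depth_phase_bias is None:
            return np.zeros(nz)
        b = np.asarray(self.depth_phase_bias, dtype=float)
        if b.shape != (nz,):
            raise ValueError("depth_phase_bias must have shape (nz,)")
        return b


@dataclass
class VesselTruth:
    """Ground truth for one vessel: geometry, kinematics and flow."""

    label: str
    coverage: np.ndarray          # partial-volume fraction in [0, 1]
    occupancy: np.ndarray         # coverage >= 0.5
    core: np.ndarray              # fully interior voxels (coverage == 1)
    tangent_z: np.ndarray         # signed axial direction cosine per voxel
    alpha: float
    times: np.ndarray             # frame times (s)
    v_long: np.ndarray            # signed longitudinal speed (m/s) per frame
    v_axial: np.ndarray           # signed axial velocity (m/s) per frame
    q_ul_min: np.ndarray          # volumetric flow (uL/min) per frame

    @property
    def v_axial_mm_s(self) -> np.ndarray:
        return self.v_axial * 1e3


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the pipeline."""

    vessels: List[VesselTruth]
    rpe_mask: np.ndarray
    galvo_ramp: float
    depth_bias: np.ndarray
    frame_times: np.ndarray
    rpe_tilt_shifts: Optional[np.ndarray] = None
    choroid_mask: Optional[np.ndarray] = None

    def vessel(self, label: str) -> VesselTruth:
        for v in self.vessels:
            if v.label == label:
                return v
        raise KeyError(label)


# --------------------------------------------------------------------------
# speckle and geometry helpers
# --------------------------------------------------------------------------

def _speckle_amplitude(rng: np.random.Generator, shape, corr_px: float = 1.2,
                       floor: float = 0.25) -> np.ndarray:
    """Positive spatially-correlated amplitude field with unit mean."""
    g = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    amp = np.abs(gaussian_filter(g.real, corr_px) + 1j * gaussian_filter(g.imag, corr_px))
    amp /= amp.mean()
    return floor + (1.0 - floor) * amp


def _project_to_polyline(points_phys: np.ndarray, coords_phys: np.ndarray):
    """Distance, arclength and local tangent of voxels w.r.t. a polyline.

    Returns ``(dist, s, tangent)`` for every row of ``coords_phys``;
    ``tangent`` is the unit direction of the nearest polyline segment.
    """
    n_seg = points_phys.shape[0] - 1
    npts = coords_phys.shape[0]
    best_d = np.full(npts, np.inf)
    best_s = np.zeros(npts)
    best_t = np.zeros((npts, coords_phys.shape[1]))
    s0 = 0.0
    for k in range(n_seg):
        a, b = points_phys[k], points_phys[k + 1]
        ab = b - a
        seg_len = np.linalg.norm(ab)
        if seg_len == 0:
            continue
        u = np.clip((coords_phys - a) @ ab / seg_len**2, 0.0, 1.0)
        proj = a + u[:, None] * ab
        d = np.linalg.norm(coords_phys - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_s[better] = s0 + u[better] * seg_len
        best_t[better] = ab / seg_len
        s0 += seg_len
    return best_d, best_s, best_t


def _vessel_geometry(vessel: SyntheticVessel, meta: ScanMetadata, shape, edge_width_px: float):
    """Coverage, occupancy, core masks plus per-voxel arclength and tangent."""
    nd = len(shape)
    pitches = np.array([meta.pixel_size_z, meta.pixel_size_x, meta.pixel_size_y][:nd])
    if vessel.centerline.shape[1] != nd:
        raise ValueError(
            f"vessel {vessel.label!r}: centerline has {vessel.centerline.shape[1]} "
            f"coordinates but the scene has {nd} spatial axes"
        )
    if np.any(vessel.centerline < -0.5) or np.any(
        vessel.centerline > np.asarray(shape) - 0.5
    ):
        raise ValueError(
            f"vessel {vessel.label!r}: centerline leaves the volume "
            f"(shape {tuple(shape)})"
        )
    pts_phys = vessel.centerline * pitches
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = np.stack([g.ravel() * p for g, p in zip(grids, pitches)], axis=1)

    # restrict the expensive projection to a bounding box around the line
    lo = pts_phys.min(axis=0) - vessel.radius - 2 * edge_width_px * pitches
    hi = pts_phys.max(axis=0) + vessel.radius + 2 * edge_width_px * pitches
    inside_box = np.all((coords >= lo) & (coords <= hi), axis=1)
    idx_box = np.flatnonzero(inside_box)
    dist, s, tang = _project_to_polyline(pts_phys, coords[idx_box])

    w_edge = edge_width_px * pitches[:2].min()
    m_box = np.clip(0.5 + (vessel.radius - dist) / w_edge, 0.0, 1.0)
    coverage = np.zeros(int(np.prod(shape)))
    coverage[idx_box] = m_box
    coverage = coverage.reshape(shape)
    occupancy = coverage >= 0.5
    core = coverage >= 1.0
    if not occupancy.any():
        raise ValueError(f"vessel {vessel.label!r} does not occupy any voxel")

    sel = np.flatnonzero(coverage.ravel() > 0.0)
    # map the selected voxels back to their projection results
    pos_in_box = np.searchsorted(idx_box, sel)
    return {
        "coverage": coverage,
        "occupancy": occupancy,
        "core": core,
        "flat_index": sel,
        "m": coverage.ravel()[sel],
        "s": s[pos_in_box],
        "tangent_z": tang[pos_in_box, 0],
        "x_index": grids[1].ravel()[sel],
        "y_index": grids[2].ravel()[sel] if nd == 3 else None,
    }


def _vessel_pattern(rng: np.random.Generator, s_values: np.ndarray,
                    disp: np.ndarray, corr_lens: Sequence[float] = (12e-6, 40e-6),
                    ds: float = 1e-6, floor: float = 0.3):
    """Real positive scatterer pattern along the vessel.

    The pattern mixes two correlation scales emulating the multi-scale
    intensity structure of flowing blood: short-range speckle from red-cell
    clusters and longer plasma-gap / aggregate features tens of microns
    long (the latter are what make kymograph streaks trackable at high
    speeds, where fine structure aliases between frames).  The domain
    carries margins for the whole displacement history.
    """
    c_max = max(corr_lens)
    lo = s_values.min() - max(disp.max(), 0.0) - 10 * c_max
    hi = s_values.max() - min(disp.min(), 0.0) + 10 * c_max
    n = max(int(np.ceil((hi - lo) / ds)) + 2, 16)
    grid = lo + ds * np.arange(n)
    amp = np.zeros(n)
    for corr in corr_lens:
        g = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        sig = corr / ds
        a = np.abs(gaussian_filter1d(g.real, sig) + 1j * gaussian_filter1d(g.imag, sig))
        amp += a / (a.mean() * len(corr_lens))
    return grid, floor + (1.0 - floor) * amp


def _doppler_rate(meta: ScanMetadata) -> float:
    """Phase (rad) accumulated per second per m/s of axial velocity."""
    return 4.0 * np.pi * meta.refractive_index / meta.wavelength_center


# --------------------------------------------------------------------------
# simulators
# --------------------------------------------------------------------------

def _check_aliasing(v_axial_max: float, meta: ScanMetadata, label: str) -> None:
    dphi = _doppler_rate(meta) * meta.aline_period * abs(v_axial_max)
    if dphi >= np.pi:
        warnings.warn(
            f"vessel {label!r}: |dphi| = {dphi:.2f} rad >= pi at the requested "
            "speed; Doppler estimates will alias",
            RuntimeWarning,
            stacklevel=3,
        )


def simulate_dyc_series(scene: SyntheticScene):
    """Render a dynamic-contrast B-scan time series.

    Returns
    -------
    (ComplexVolume, GroundTruth)
        The volume has layout ``(z, x, t)``; static voxels change between
        A-scans only through the galvo/depth phase bias (plus noise), while
        vessel voxels carry the configured Doppler phase shift, a speckle
        pattern translating along the vessel, and the bolus enhancement.
    """
    meta = scene.metadata
    nz, nx, nt = (int(d) for d in scene.dims)
    rng = np.random.default_rng(scene.seed)

    amp = scene.tissue_mean * _speckle_amplitude(rng, (nz, nx))
    rpe_rows = np.arange(
        max(scene.rpe_depth_index - scene.rpe_halfwidth, 0),
        min(scene.rpe_depth_index + scene.rpe_halfwidth + 1, nz),
    )
    amp[rpe_rows] *= scene.rpe_gain

    bias = scene.galvo_ramp + scene.depth_bias_array()  # rad per A-scan, per depth
    static_phase = bias[:, None] * np.arange(nx)[None, :]
    static_field = amp * np.exp(1j * static_phase)

    times = scene.acquisition_start_time + meta.interscan_time * np.arange(nt)
    volume = np.repeat(static_field[:, :, None], nt, axis=2)

    ch_rows = scene.choroid_rows()
    if ch_rows.size:
        c = scene.choroid_amp / np.sqrt(2.0)
        for k in range(nt):
            volume[ch_rows, :, k] = c * (
                rng.standard_normal((ch_rows.size, nx))
                + 1j * rng.standard_normal((ch_rows.size, nx))
            )

    rate = _doppler_rate(meta)
    truths: List[VesselTruth] = []
    for vessel in scene.vessels:
        geo = _vessel_geometry(vessel, meta, (nz, nx), scene.edge_width_px)
        v_long = vessel.speed(times)
        disp = cumulative_trapezoid(v_long, times, initial=0.0)
        enh = (
            vessel.bolus.enhancement(times)
            if vessel.bolus is not None
            else np.ones(nt)
        )
        tz_core = geo["tangent_z"][geo["m"] >= 1.0]
        tz_mean = float(tz_core.mean()) if tz_core.size else float(geo["tangent_z"].mean())
        _check_aliasing(np.max(np.abs(v_long)) * np.max(np.abs(geo["tangent_z"])),
                        meta, vessel.label)

        grid, pattern = _vessel_pattern(rng, geo["s"], disp)
        # intravascular speckle phase decorrelates between B-scans: one
        # random bulk phase per frame (cancels within a frame, so lag-1
        # phase differences are unaffected)
        psi = rng.uniform(0.0, 2.0 * np.pi, nt)
        zf, xf = np.unravel_index(geo["flat_index"], (nz, nx))
        m = geo["m"]
        phase_static = static_phase[zf, xf]
        for k in range(nt):
            pat = np.interp(geo["s"] - disp[k], grid, pattern)
            omega = rate * v_long[k] * geo["tangent_z"]
            phase = phase_static + omega * meta.aline_period * xf + psi[k]
            val = vessel.backscatter_baseline * enh[k] * pat
            volume[zf, xf, k] = (1.0 - m) * volume[zf, xf, k] + m * val * np.exp(
                1j * phase
            )

        truths.append(
            VesselTruth(
                label=vessel.label,
                coverage=geo["coverage"],
                occupancy=geo["occupancy"],
                core=geo["core"],
                tangent_z=_scatter_map((nz, nx), geo["flat_index"], geo["tangent_z"]),
                alpha=vessel.angle_alpha,
                times=times,
                v_long=v_long,
                v_axial=v_long * tz_mean,
                q_ul_min=v_long * np.pi * vessel.radius**2 * _M3_S_TO_UL_MIN,
            )
        )

    if scene.noise_sigma > 0:
        s = scene.noise_sigma / np.sqrt(2.0)
        for k in range(nt):
            volume[:, :, k] += s * (
                rng.standard_normal((nz, nx)) + 1j * rng.standard_normal((nz, nx))
            )

    rpe_mask = np.zeros((nz, nx), dtype=bool)
    rpe_mask[rpe_rows] = True
    rpe_mask &= ~_vessel_shadow(truths, (nz, nx))
    truth = GroundTruth(
        vessels=truths,
        rpe_mask=rpe_mask,
        galvo_ramp=scene.galvo_ramp,
        depth_bias=scene.depth_bias_array(),
        frame_times=times,
    )
    if ch_rows.size:
        ch = np.zeros((nz, nx), dtype=bool)
        ch[ch_rows] = True
        truth.choroid_mask = ch
    if scene.rpe_tilt_px:
        shifts = np.rint(np.linspace(0.0, scene.rpe_tilt_px, nx)).astype(int)
        for x in range(nx):
            if shifts[x]:
                volume[:, x] = np.roll(volume[:, x], shifts[x], axis=0)
                rpe_mask[:, x] = np.roll(rpe_mask[:, x], shifts[x])
                for vt in truths:
                    vt.coverage[:, x] = np.roll(vt.coverage[:, x], shifts[x])
                    vt.occupancy[:, x] = np.roll(vt.occupancy[:, x], shifts[x])
                    vt.core[:, x] = np.roll(vt.core[:, x], shifts[x])
                    vt.tangent_z[:, x] = np.roll(vt.tangent_z[:, x], shifts[x])
        truth.rpe_tilt_shifts = shifts

    return ComplexVolume(values=volume, metadata=meta, layout="zxt"), truth


def _scatter_map(shape, flat_index, values) -> np.ndarray:
    out = np.zeros(shape)
    out.ravel()[flat_index] = values
    return out


def _vessel_shadow(truths: Sequence[VesselTruth], shape) -> np.ndarray:
    """Voxels touched by any vessel, widened by one fast-axis pixel so that
    no lag-1 A-scan pair straddles tissue and vessel signal.

    The ground-truth RPE mask excludes these voxels: a reference built from
    the cross-polarised RPE channel would likewise not include pixels
    dominated by intravascular signal.
    """
    bad = np.zeros(shape, dtype=bool)
    for vt in truths:
        bad |= vt.coverage > 0
    widened = bad.copy()
    widened[:, :-1] |= bad[:, 1:]
    widened[:, 1:] |= bad[:, :-1]
    return widened


def simulate_angio_volume(scene: SyntheticScene):
    """Render a 3D angiography volume with repeated B-scans.

    Returns a ``(z, x, y, repeat)`` :class:`ComplexVolume` plus ground
    truth.  Repeats at one slow-axis position are re-realisations in which
    only vessel voxels decorrelate (the scatterer pattern advects and the
    Doppler phase accumulates between repeats); static tissue is identical
    across repeats up to noise.
    """
    meta = scene.metadata
    nz, nx, ny = (int(d) for d in scene.dims)
    n_rep = meta.n_repeats
    rng = np.random.default_rng(scene.seed)

    amp = scene.tissue_mean * _speckle_amplitude(rng, (nz, nx, ny))
    rpe_rows = np.arange(
        max(scene.rpe_depth_index - scene.rpe_halfwidth, 0),
        min(scene.rpe_depth_index + scene.rpe_halfwidth + 1, nz),
    )
    amp[rpe_rows] *= scene.rpe_gain

    bias = scene.galvo_ramp + scene.depth_bias_array()
    static_phase = bias[:, None] * np.arange(nx)[None, :]  # (nz, nx), same for every y
    static_field = amp * np.exp(1j * static_phase[:, :, None])

    # acquisition clock: B-scan (y, r) starts at (y * n_rep + r) * interscan
    frame_times = (
        scene.acquisition_start_time
        + meta.interscan_time * (np.arange(ny)[:, None] * n_rep + np.arange(n_rep))
    )  # (ny, n_rep)

    volume = np.repeat(static_field[:, :, :, None], n_rep, axis=3)

    ch_rows = scene.choroid_rows()
    if ch_rows.size:
        c = scene.choroid_amp / np.sqrt(2.0)
        for y in range(ny):
            volume[ch_rows, :, y, :] = c * (
                rng.standard_normal((ch_rows.size, nx, n_rep))
                + 1j * rng.standard_normal((ch_rows.size, nx, n_rep))
            )

    rate = _doppler_rate(meta)
    truths: List[VesselTruth] = []
    for vessel in scene.vessels:
        geo = _vessel_geometry(vessel, meta, (nz, nx, ny), scene.edge_width_px)
        t_flat = frame_times.ravel()
        v_long = vessel.speed(t_flat)
        disp_flat = cumulative_trapezoid(v_long, t_flat, initial=0.0)
        enh = (
            vessel.bolus.enhancement(t_flat)
            if vessel.bolus is not None
            else np.ones(t_flat.size)
        )
        tz_core = geo["tangent_z"][geo["m"] >= 1.0]
        tz_mean = float(tz_core.mean()) if tz_core.size else float(geo["tangent_z"].mean())
        _check_aliasing(np.max(np.abs(v_long)) * np.max(np.abs(geo["tangent_z"])),
                        meta, vessel.label)

        grid, pattern = _vessel_pattern(rng, geo["s"], disp_flat)
        # intravascular speckle phase decorrelates between repeats
        psi = rng.uniform(0.0, 2.0 * np.pi, ny * n_rep)
        zf, xf, yf = np.unravel_index(geo["flat_index"], (nz, nx, ny))
        m = geo["m"]
        phase_static = static_phase[zf, xf]
        order = np.argsort(yf, kind="stable")
        for y in np.unique(yf):
            sel = order[np.searchsorted(yf[order], y): np.searchsorted(yf[order], y + 1)]
            for r in range(n_rep):
                fi = y * n_rep + r
                pat = np.interp(geo["s"][sel] - disp_flat[fi], grid, pattern)
                omega = rate * v_long[fi] * geo["tangent_z"][sel]
                phase = phase_static[sel] + omega * meta.aline_period * xf[sel] + psi[fi]
                val = vessel.backscatter_baseline * enh[fi] * pat
                volume[zf[sel], xf[sel], y, r] = (1.0 - m[sel]) * volume[
                    zf[sel], xf[sel], y, r
                ] + m[sel] * val * np.exp(1j * phase)

        truths.append(
            VesselTruth(
                label=vessel.label,
                coverage=geo["coverage"],
                occupancy=geo["occupancy"],
                core=geo["core"],
                tangent_z=_scatter_map((nz, nx, ny), geo["flat_index"], geo["tangent_z"]),
                alpha=vessel.angle_alpha,
                times=t_flat,
                v_long=v_long,
                v_axial=v_long * tz_mean,
                q_ul_min=v_long * np.pi * vessel.radius**2 * _M3_S_TO_UL_MIN,
            )
        )

    if scene.noise_sigma > 0:
        s = scene.noise_sigma / np.sqrt(2.0)
        for y in range(ny):
            volume[:, :, y, :] += s * (
                rng.standard_normal((nz, nx, n_rep))
                + 1j * rng.standard_normal((nz, nx, n_rep))
            )

    rpe_mask = np.zeros((nz, nx, ny), dtype=bool)
    rpe_mask[rpe_rows] = True
    rpe_mask &= ~_vessel_shadow(truths, (nz, nx, ny))
    truth = GroundTruth(
        vessels=truths,
        rpe_mask=rpe_mask,
        galvo_ramp=scene.galvo_ramp,
        depth_bias=scene.depth_bias_array(),
        frame_times=frame_times,
    )
    if ch_rows.size:
        ch = np.zeros((nz, nx, ny), dtype=bool)
        ch[ch_rows] = True
        truth.choroid_mask = ch
    return ComplexVolume(values=volume, metadata=meta, layout="zxyr"), truth
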