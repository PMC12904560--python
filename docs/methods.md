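# Methods

This note documents the models, estimators and numerical choices behind
`nvflow`, and what the synthetic validation does and does not demonstrate
about real data.

## Acquisition model and units

All velocity conversions are governed by `ScanMetadata`: central wavelength
λ = 840 nm, tissue refractive index n = 1.35, A-scan period T = 1/83000 s,
interscan (B-scan) time 7.7 ms, pixel pitches 2 µm (z), 2 µm (x, 1 mm /
500 A-scans) and 2.5 µm (y, 1 mm / 400 positions), 5 repeated B-scans per
slow-axis position.  Two layouts are supported: dynamic-contrast B-scan
time series `(z, x, t)` and 3D angiography volumes `(z, x, y, repeat)`.
Phases are wrapped to [−π, π); the axial Nyquist speed λ/(4nT) evaluates to
12.91 mm/s.  Depth increases towards the choroid and positive axial
velocity means flow into the choroid; captions and outputs use the
convention that negative flow goes from the choroid into the retina.
Flow rates convert as mm/s × mm² = µL/s, reported in µL/min.

## Synthetic scenes

The generator is designed so that every downstream estimator can be scored
by parameter recovery, while reproducing the failure modes that matter
(vessel-wall phase noise, temporal aliasing of fine speckle, bolus
dynamics).

**Static tissue** is a positive amplitude speckle field (magnitude of a
spatially low-passed complex Gaussian, correlation ≈ 1.2 px, floor 0.25,
mean 1) with zero intrinsic phase, so static voxels carry no inter-A-scan
phase of their own.  The **RPE** is a single bright row (12× tissue mean);
a one-row band makes the per-column intensity peak an unambiguous
alignment reference.  An optional **choroid** band below the RPE is fully
decorrelating speckle (fresh complex Gaussian per frame/repeat): it
dominates the angiogram's depth profile and thereby sets a realistic
global-threshold reference value, exactly as the perfused choroid does in
vivo.

**Vessels** are tubes around a (poly)line centerline with radius r and
angle α from the beam.  Partial-volume coverage m ∈ [0, 1] falls off
linearly over 1.5 px at the wall; voxels mix `(1−m)·background +
m·vessel`.  The intravascular field is

    a(s − ∫v dt) · bolus(t) · exp(i[ω T x + ψ_frame + galvo ramp terms]),

with a *real positive* scatterer pattern `a` along the arclength s and
ω = 4πn·v·cosα/λ.  Consequences:

- interior A-scan pairs carry exactly the configured Doppler phase ωT
  (machine precision), which is what makes sub-0.1% zero-noise recovery
  testable;
- the translating pattern produces kymograph streaks and inter-repeat
  decorrelation from the same speed parameter;
- `ψ_frame`, a per-frame random bulk phase of the intravascular speckle,
  reproduces the fact that moving blood decorrelates in phase between
  B-scans.  It cancels inside lag-1 phase differences but randomises the
  tissue/vessel cross-terms at the wall between repeats, which is what lets
  repeat averaging suppress wall phase noise (without it the junk has a
  fixed phase and never averages out).

The scatterer pattern mixes two correlation scales, 12 µm and 40 µm.  The
long scale is essential physics, not cosmetic: at the 7.7 ms interscan
time, features finer than v·Δt (≈ 15 µm at 2 mm/s, 38 µm at 5 mm/s)
alias between frames, and no streak-angle method can track them.  Real
kymographs are trackable at such speeds because red-cell aggregates and
plasma gaps form features tens of micrometres long; the generator models
exactly that.

The bolus enhancement is a normalised gamma-variate wash-in/wash-out on
top of a smooth step to a residual plateau ≥ 1 (recirculating contrast
keeps the signal above its pre-injection baseline).  All randomness flows
from one integer seed through a single generator; identical scenes are
bit-reproducible.

## Angiography

Complex subtraction averages |C_{k+1} − C_k| over adjacent repeat pairs
after removing each pair's bulk phase offset, estimated as the argument of
Σ conj(C_k)·C_{k+1} over the whole B-scan (an |C_k||C_{k+1}|-weighted
circular mean); without this, bulk phase jitter leaks static tissue into
the angiogram.  Averaging filters use edge replication; for the even 10×10
kernel the footprint extends one pixel further towards smaller indices
(the `scipy.ndimage` convention, mirrored exactly by the test oracles).
Thresholding is inclusive (≥).  Flattening applies integer shifts only,
preserving phases; per-column RPE detection uses a laterally smoothed
profile with a median-filtered row map, and columns without a consistent
band (e.g. occluded by a vessel crossing the RPE) inherit shifts
interpolated from their neighbours.

## Doppler velocimetry

The phase estimator is the lag-1 Kasai autocorrelation along the fast
axis.  A lag-1 estimate lives on an A-scan *pair*: the map entry at column
x describes pair (x, x+1), the last column carries zero weight, and ROI
statistics by default include only pairs wholly interior to the mask —
boundary pairs mix static and intravascular signal and carry near-arbitrary
phases.  The same pair logic excludes flank columns whose pair touches a
vessel.

Corrections are applied in the published order: (1) per B-scan, subtract
the intensity-weighted circular mean phase over the RPE band (galvo bulk
bias); (2) per depth, subtract the mean phase of two 15-pixel flanking
bands beside the dilated (3×3, 8-connected) vessel ROI, averaged over a
±15-frame (or ±15-position) boxcar in the temporal/slow axis, from the
pre-dilation mask pixels.  Circular statistics are used wherever phases
are averaged.  With a galvo ramp plus an arbitrary depth-dependent phase
bias, this chain recovers interior phases to machine precision at zero
noise, and ROI-mean longitudinal velocities to ≪ 1% at 20 dB SNR across
|Δφ| ∈ [0.1π, 0.8π] and α ∈ {0, 0.67, 1.07} rad.

`roi_mean_velocity` uses the arithmetic mean of signed velocities
(intensity weighting available as an option); the longitudinal projection
V_D = V_axial/cosα refuses angles within 0.1 rad of perpendicular.

## Particle tracking

Kymographs sample intensity along the segment by bilinear interpolation at
arclength steps ds ≤ min(pixel pitch).  Windows are mean-subtracted per
row (removing static structure), then projected along candidate streak
orientations; the response of an orientation is the count-weighted
variance of the per-bin projection *means*, restricted to bins with at
least half the maximal support.  Both normalisations matter: plain
zero-padded sums bias the argmax towards shallow slopes (steep shears lose
support), and unrestricted bins let short partial traversals that catch a
single bright feature win.

Because V = cotθ is only meaningful for a declared axis scaling, the angle
grid is uniform (0.25° steps) in a frame where a streak at `v_scale`
(default 1 mm/s) lies at 45°, giving near-uniform *relative* velocity
resolution over 0.2–5 mm/s.  Sliding windows use a 2° coarse scan refined
at 0.25° and then 0.05°.  Guard bands of 1° around the degenerate
orientations are flagged, not extrapolated; samples faster than 10 mm/s
are additionally flagged unreliable (such streaks cross the tracked
segment within a couple of interscan periods and are indistinguishable
from chance alignments).  Confidence is the peak response over the
incoherent expectation at the same support (pixel variance / samples per
bin): ≈ 1 for noise, approaching the window length for clean streaks;
samples below 3 are flagged.

Known limitations, visible in the tests: windows occasionally lock onto
partially aliased fine speckle (errors of tens of percent in a few percent
of windows — the medians stay well under 5%), and textured streaks carry a
sub-degree estimator bias (≲ 3% in velocity).  Short segments (≲ 100
sampling steps) amplify both effects; the published vessel-selection
criterion — a sufficient in-plane length — applies to the synthetic
scenarios too.

## Flowmetry

Q integrates the fully corrected, repeat-averaged axial velocity over an
axis-aligned window encompassing the NV; background inside the window is
included, relying on the bias corrections to null it.  The depth plane is
chosen automatically as the maximum-contrast plane (mean |v| inside the
window minus a surrounding ring, ties towards the shallower plane), with a
manual override.

Two robustness extensions go beyond the literal single-plane unmasked
integral (both can be disabled):

- a **repeat-coherence mask** (floor 0.8) excludes pixels whose phase
  estimates are incoherent across the 5 repeats — these are the
  vessel-wall pixels whose tissue/vessel cross-terms carry near-Nyquist
  velocity junk.  The floor trades a small negative bias (over-gating
  genuine partial-volume flow, dominant at 0.95) against residual wall
  noise (dominant below 0.5); 0.8 sits at the crossover on the generator.
- **`flow_rate_band`** averages the integral over a small band of depth
  planes (default 5–7) centred on the selected plane; every plane through
  a tube carries the same flux, so this suppresses single-plane wall noise
  without changing the measured quantity.

With both, the en-face flow of a synthetic tube at 2 mm/s recovers the
configured volumetric flow within ~2–4% and is invariant under tilt
between 0 and 0.6 rad to the same level.  Note the window integral remains
sensitive to any depth-structured background phase bias that the
corrections do not touch outside the NV mask; the method presumes the bulk
(RPE) correction leaves none, which holds for galvo-type biases.

Directionality statistics are computed per post-injection timepoint
(total into = Σ max(Q, 0), total out = Σ max(−Q, 0), net = their
difference, summed over NVs), then averaged over timepoints; the index is
mean net / mean total, in [−1, 1].  Reversal detection flags a sign change
between consecutive post-injection timepoints with |Q| above a noise floor
(default 0, matching simple sign counting; a positive floor classifies
persistently near-zero, isolated vessels as non-perfused rather than
reversing).

## Method comparison

The Doppler trace is boxcar-averaged over the particle-tracking window
(100 frames ≈ 0.77 s) so both traces share timestamps sample-for-sample;
Pearson r (and r² = r², enforced to machine precision) is computed per
injection phase with pairwise exclusion of flagged samples.  The phase
split comes from the bolus-arrival detector: earliest time the smoothed
(25-frame) mean ROI intensity exceeds the baseline mean + 5 SD, baseline =
first 10% of frames.  The correlation uses the angle-corrected
longitudinal Doppler velocity, so both traces live on the same axis
(configurable).

The standard comparison scenario is deliberately a *fixed-seed* study: a
2000-frame series (the published protocol length) with one long in-plane
vessel (α = 1.07 rad) at −1.6 mm/s modulated ±30% at 0.45 Hz, pre-injection
amplitude barely above the noise floor, bolus arriving at 6 s.  Two choices
deserve emphasis.  The modulation frequency must stay well below 1.3 Hz:
a 1.3 Hz modulation has the period of the 0.77 s window and is annihilated
by the boxcar.  And with 99% window overlap, a trace of N samples carries
only ~N/100 independent ones; correlations over short phases scatter
wildly, which is why the scenario fixes its seed and uses a long record.

## Validation battery and problem sizes

The study battery (`nvflow.studies`, reported by `scripts/acceptance.py`)
uses desk-scale volumes chosen so the whole battery runs in a few minutes:
64×96×40 series for the 24-cell Doppler sweep; 64×110×260 series for the
six-speed particle-tracking sweep and the mid-series reversal; 48×96×64×5
volumes, three speckle replicates per angle, for flow-angle invariance;
the full 2000-frame protocol for the method comparison.  The demo pipeline
analyses a 72×110×500 series and four 48×96×64×5 volumes.

Passing these tests shows the estimators recover known kinematics from
data containing the modelled artefacts (speckle, partial volume, galvo and
depth phase biases, bolus dynamics, complex noise, temporal aliasing).  It
does not exercise eye motion, cataract-induced signal loss, cardiac
pulsatility, vessel tortuosity or out-of-plane flow, polarisation effects,
or segmentation error (ROIs come from ground truth); conclusions about
real acquisitions should be drawn accordingly.
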