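# Methods

`lightsweep` simulates a fast volume-scanning light-sheet microscope and
analyses the calcium-imaging movies it produces. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic tests do and do not establish about real data.

## Optical forward model

The instrument being modelled sweeps a thin illumination sheet along the
detection (Z) axis with a galvo mirror while an electrically tunable lens
(ETL) sweeps the detection focal plane in synchrony. Both are driven by
50 Hz sine signals:

    z(t) = center_z + A · sin(2π f t + φ)

with the sweep depth given peak-to-peak (20 µm by default, so A = 10 µm).
The camera exposure is locked to exactly one drive period (20 ms at 50 Hz),
so every frame integrates one complete Z sweep — an average intensity
projection of the volume. The acquisition API enforces the lock and rejects
exposure/period mismatches beyond 10⁻⁶ relative; partial-cycle exposures
are not modelled.

Axial profiles are Gaussian, not diffraction-rigorous: the sheet has an
excitation profile `exp(−(z−z_sheet)²/2σ_s²)` (σ_s = 2 µm default) and the
detection arm an axial acceptance `exp(−(z−z_focus)²/2σ_d²)` (σ_d = 1.5 µm
default). These defaults are model parameters chosen so that single-plane
imaging visibly truncates a dendrite meandering over tens of µm in Z; they
are not measured point-spread functions. A sheet/focus mismatch
additionally blurs the image laterally at `defocus_blur_rate` (0.25 µm of
Gaussian blur sigma per µm of mismatch) on top of the in-focus lateral
blur (0.4 µm). ETL magnification change is neglected (it is small for a
20 µm scan range).

A frame is rendered as the mean of K instantaneous sub-frames at midpoint
times across the exposure (K = 32 by default; K ≥ 8 enforced). Each
sub-frame integrates emission density × excitation × detection weight over
a Z quadrature grid (midpoint rule, dz = 0.5 µm default; the Gaussian
integrand makes the rule converge far below the tolerances used anywhere).
Convergence in K is testable by doubling K. Noise is applied per frame in
physical order: Poisson shot noise on `photon_scale × signal`, camera bias
offset, additive Gaussian read noise, rounding to integer counts, clipping
at zero. `photon_scale=None` disables noise and yields float frames, which
is what the conservation and linearity tests rely on.

Three acquisition modes share this core: `volume_scan` (both waveforms
swept), `single_plane` (sheet and focus static at one plane), and
`structural_z` (stage-stepped stack, one rendered plane per step — the
standard 320 × 0.5 µm stack spans 160 µm).

### Effective sheet thickness

Time-averaging the excitation of a sine-swept sheet over one period gives
an arcsine-shaped profile: flat-ish in the middle with integrable maxima
near the turning points, smoothed by the sheet thickness. Measured as the
Z range above 5% of the profile's peak, the support of a σ_s = 0.2 µm
sheet swept 20 µm peak-to-peak is 20.8 µm: the 5% crossing sits about two
sheet sigmas beyond each turning point, so the measured extent is the
sweep depth plus ~4 σ_s, not sweep ± σ_s. This is a property of the
measurement definition, not a numerical artefact; it persists as the grid
and substep count are refined.

## Dendrite phantom

The phantom is a circular tube (radius 1 µm default) around a Catmull-Rom
smoothed random-walk centerline. The walk's heading meanders in XY with a
configurable control-point spacing ("smoothness", 10 µm default); the Z
profile is an independent smoothed walk rescaled so the realised Z span
exactly matches the requested value — coverage experiments need phantoms
whose Z extent (e.g. 40 µm) exceeds the 20 µm sweep. Spines,
indicator-buffering kinetics and diffusion are out of scope; the tube
carries two uniform dyes: a structural channel of constant density and an
indicator channel equal to `baseline × (1 + ΔF/F(s, t))`, where s is
arclength.

For rendering, the tube is voxelised sparsely (only tube voxels are
stored) with a linear partial-volume edge one voxel wide; each voxel
carries the arclength of its nearest centerline point so the indicator
channel can be updated per substep from a 0.5 µm arclength table. The
point-evaluation API uses the exact (hard-edged) tube.

## Ground-truth events

A transient at origin s₀ follows the rise/decay kernel

    ΔF/F(t) = b · (t − t_on) · exp(−c · (t − t_on)),   t ≥ t_on

which peaks b/(c·e) above zero at 1/c after onset. Events are stored by
their peak ΔF/F; b is derived (b = peak · c · e) and any explicitly
supplied b is checked for consistency. Spatially, the amplitude decays as
`exp(−d/spread_length)` with arclength distance d from the origin and the
onset is delayed by `propagation_delay · d`. Both are the simplest
monotone forms consistent with the observed phenomenology (reduced,
delayed transients a few µm from the initiation site); the true spatial
profile of propagating dendritic Ca²⁺ is not claimed. Defaults:
spread 6 µm, delay 5 ms/µm, peak ΔF/F drawn from 0.3–1.2, c from
4–10 s⁻¹ (time-to-peak 100–250 ms, appropriate for a slow synthetic
indicator). Overlapping events add linearly in ΔF/F; a double-peaked
transient is represented as two events.

## Phase calibration

The ETL responds to its drive with a lag, modelled as a pure phase delay
of the focus waveform. Calibration mimics the bench procedure: image a
field of 0.5 µm Gaussian beads at a grid of candidate phase offsets
(grid search, ≥ 8 points over one period — matching the manual tuning it
emulates, not a continuous optimiser) and keep the offset maximising mean
frame sharpness, scored by normalised variance (var/mean², scale
invariant).

Two subtleties surfaced here. First, because the Gaussian detection
weight *rejects* out-of-focus light rather than spreading it, badly
synchronised phases produce dim, sparse frames whose normalised variance
is spuriously high; including the camera's bias offset (20 counts in the
calibration defaults) anchors the denominator and restores the correct
ranking. Second, the two sine waves coincide twice per cycle at *any*
phase error, momentarily refocusing the system; the quality-vs-phase
curve therefore has a dominant lobe at the compensating offset plus
secondary structure (≈ 25% of peak) rather than being strictly unimodal.
With a 24-point grid, injected lags of 0–5 ms at 50 Hz are recovered
within one grid step.

## Trace extraction and ΔF/F

ROIs are labelled pixel sets (polygons rasterised via scikit-image's
`polygon2mask`, or explicit pixel lists), 0-based, origin top-left. The
raw trace is the mean pixel value per frame at frame mid-exposure times.
A designated background ROI is fitted with `p + q·exp(−r·t)` (nonlinear
least squares with an offset term, since a pure decay cannot represent
the ambient floor; internally normalised by the trace mean so the fit is
exactly equivariant under global intensity rescaling; constant traces
short-circuit; non-convergence falls back to a flagged log-linear fit).
The fitted background model is evaluated per frame and subtracted from
each signal ROI's raw trace (a divide-by-fit detrending mode is available
as a config option), F₀ is the mean of the corrected trace over a
baseline window (first 1 s by default — a declared convention, since the
field has no single standard), and ΔF/F = (corrected − F₀)/F₀. F₀ ≤ 0
is an error: the ROI is indistinguishable from background.

## Event detection and acceptance

Candidate nomination is deliberately simple and fully parameterised:
boxcar-smooth the ΔF/F trace (3 frames), open a window where it exceeds
median + 2.5 × robust σ (1.4826 × MAD of the whole trace), close on
return below, merge windows closer than 0.3 s, and pad (0.25 s before,
0.5 s after) for fitting context.

Each window is fitted with `a + b·(t−t_on)·exp(−c·(t−t_on))` (zero rise
before onset; the offset a absorbs residual baseline error). The onset is
grid-searched over sample times within 0.4 s of the window start — the
window opens at a threshold crossing, so the physical onset is near the
start; a free onset would chase the largest noise excursion — and then
all four parameters are refined continuously with t_on confined to ±1
frame of the grid winner. The refinement matters: an onset fixed at frame
resolution biases b and c by ~10% when the true onset falls between
samples. The decay rate is bounded to c ∈ [0.5, 12.5] s⁻¹ (time-to-peak
80 ms–2 s), a physiological prior for slow Ca²⁺ indicators that also
prevents the model from fitting single-sample noise spikes.

Acceptance follows the amplitude-versus-noise rule: the fitted amplitude
b/(c·e) — the curve's peak above its offset — must *strictly* exceed the
RMS of the mean-subtracted ΔF/F over the 1 s preceding the onset
(truncated to the available span, minimum 0.25 s; events with less
baseline are unscorable and never accepted). Mean subtraction is a
declared interpretation: an uncentered RMS would conflate offset with
noise. On pure-noise windows this rule rejects ≈ 93% of fits at the
default settings (a smooth rise/decay regressed onto white noise retains
~0.5–0.9 σ of amplitude, so a tail always passes); in the full pipeline,
where fitting is gated by candidate nomination, the accepted
false-positive rate on event-free 10 s traces is far below 0.1 per trace.

Recovery scoring matches detected events to ground truth greedily by
onset proximity (one-to-one, 0.2 s tolerance by default) and reports
precision, recall, and per-match amplitude and time-to-peak errors.
Precision is defined as 1 when nothing was detected.

## Problem sizes and determinism

Default study conditions follow the instrument's operating point: 50 Hz,
20 ms exposure, 20 µm sweep, 10 s functional acquisitions, 320 × 0.5 µm
structural stacks. Test and demo scenes use reduced frames (tens of
pixels across), K = 8–32 substeps and 2–6 s durations; recovery and
false-positive statistics use 100–500 seeded trace-level simulations.
Every random draw descends from a single run seed; with the seed fixed,
acquisitions are bit-reproducible and repeated pipeline runs produce
byte-identical TIFFs and CSVs.

## What the synthetic tests do not show

The phantom has uniform dye density, no spines, no motion, no scattering
or stripe artefacts, Gaussian optics, and events whose shape exactly
matches the fitted model. Passing recovery tests therefore demonstrates
the internal consistency of the pipeline (geometry → optics → noise →
detection) and its statistical behaviour under the stated noise model —
not performance on real tissue, where model mismatch (non-exponential
bleaching, compound events, motion) dominates.
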