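# Methods

## The measurement problem

Targeted two-photon photostimulation aims to activate one neuron and not
its neighbours above or below. The limiting width is axial: the focus of
a high-NA objective is far more elongated along z than laterally, and a
spatial light modulator (SLM) that repositions the focus in depth can also
be used to deliberately change its axial extent. This package quantifies
the two widths involved — the optical point spread function (OPSF) of the
stimulation beam and the physiological point spread function (PPSF) of the
neuronal response — and models their relationship.

## OPSF estimation (`ppsfkit.opsf`)

Sub-diffraction (0.2 μm) fluorescent beads imaged with the stimulation
beam sample the OPSF directly. The estimator:

1. registers the stack slice-to-slice (sub-pixel cross-correlation against
   the brightest slice, classic — unnormalized — correlation, because
   phase-normalized correlation is unreliable on smooth noise-free blobs);
2. detects beads as local maxima above an intensity quantile (default
   0.999) with non-maximum suppression, refined to sub-voxel precision by
   center of mass in a background-subtracted 7-voxel window;
3. extracts 1D profiles along the axial and two lateral axes through each
   centroid, averaging over a 3-voxel perpendicular aperture to reduce
   noise;
4. fits offset + amplitude·exp(−(x−μ)²/(2σ²)) by least squares.
   Initialization is moment-based (μ at the argmax, σ from the
   intensity-weighted second moment); σ is bounded to (0.1 × sample
   spacing, 2 × window range). The lower bound is a fraction of the
   spacing, not of the range: a bound proportional to the window range
   would exclude physically plausible σ whenever the extraction window is
   generous relative to the focus.
5. flags a fit unusable when R² < 0.9 (configurable) — an automated
   surrogate for inspecting each curve by eye — and summarizes usable fits
   per axis as mean FWHM ± 1.96·SE. FWHM = 2√(2 ln 2)·σ throughout.

The summary reports the mean of per-bead FWHMs (not the FWHM of a mean
curve); both constructions agree for the synthetic beads used in testing.

## PPSF measurement (`ppsfkit.ppsf`)

Inputs are a movie (T×Y×X), a synchronization record (frame clock +
stimulation gate) and ROI masks. Per trial:

* frame indices come from counting frame-clock rising edges; any frame
  overlapping the stimulation gate is an artifact frame (the stimulation
  laser bleeds into the imaging channel) and belongs to no analysis
  window;
* ΔF/F = (F − F₀)/F₀ with F₀ the mean ROI fluorescence over the 1.5 s of
  frames before stimulation onset; the trial response is the mean ΔF/F
  over the 1.5 s of frames after stimulation end.

Trial responses are averaged over the repeats (default 3) at each of the
9 z offsets (−60…+60 μm, 15 μm apart). Curve-level processing follows the
field's conventions:

* **inclusion filter** — a neuron counts as successfully stimulated only
  if its mean response reaches ≥ 0.35 ΔF/F at some offset; others are
  excluded and logged;
* **peak alignment** — because the soma's true depth relative to the
  imaging plane is uncertain by roughly one cell body, each curve is
  relabeled so its maximum sits at z = 0. Ties break toward the
  smallest-magnitude shift, then toward the negative shift; a shift larger
  than one 15 μm step warns but does not fail;
* **sweep flipping** — curves acquired with the descending ("reverse")
  offset order are mirrored in z so all curves share the ascending
  convention before combination;
* **group curve** — per-neuron curves are normalized to their own maximum
  and averaged pointwise with a normal-approximation 95% CI
  (mean ± 1.96·SE);
* **width** — the group FWHM is the width of the curve at half the
  prominence of its highest peak (curve boundaries count as bases),
  computed with `scipy.signal.find_peaks`/`peak_widths` and linear
  interpolation at the crossings. Flat or monotone curves return NaN. The
  group FWHM is measured on the combined normalized mean curve, not as a
  mean of per-neuron FWHMs;
* **condition comparison** — Welch two-sample t-tests per offset, with no
  multiple-testing correction across the 9 offsets (flagged in the output
  metadata). Offsets where both groups are degenerate (zero variance)
  report NaN.

Optional symmetrization of the two curve halves about the peak is not
performed; the halves are kept as measured.

## Convolution model (`ppsfkit.model`)

The cell is a binary square wave of width *d*: for a sphere with opsin in
the membrane this is exact, because the membrane area inside an axial slab
of thickness dz is 2πR·dz wherever the slab cuts the sphere
(`ppsfkit.synth.membrane_area_profile` also provides the parabolic
uniform-volume alternative). The OPSF is a Gaussian with
σ = FWHM/(2√(2 ln 2)), sampled deterministically rather than built from a
histogram of random draws — the stochastic construction converges to the
density, and determinism removes a nuisance source of variance.

The model PPSF is the discrete linear convolution of the two profiles,
peak-normalized, optionally followed by a 5-sample centered moving
average (normalize-then-smooth order). Because the smoothing window is
expressed in grid samples, its physical width depends on the grid spacing;
FWHM reporting therefore defaults to the unsmoothed profile, and smoothing
is exposed for plot reproduction only. The default grid spans ±80 μm at
0.1 μm spacing (acceptance checks use 0.05 μm).

An independent closed-form oracle validates the pipeline: the convolution
of a unit top hat with a Gaussian density is
C(z) = Φ((z + d/2)/σ) − Φ((z − d/2)/σ), and the FWHM is obtained by
bisection on C(z) = C(0)/2 to 10⁻⁶ μm. The discrete route and the oracle
agree to < 0.1 μm over both measured OPSF conditions and cell diameters
0–50 μm. The convergence diameter — the smallest cell size beyond which
the two OPSF conditions' model FWHMs stay within a tolerance (2 μm
default) of each other — lands at 26 μm for the 8.3 / 18.6 μm pair,
i.e. cells in the tens of micrometres erase the optical difference.

## Synthetic data (`ppsfkit.synth`)

The generator emulates the acquisition geometry of the experiments:
30 Hz movies, 512×512 px at 1.25 μm/px (defaults; tests render smaller
frames), 9 stimulation offsets from −60 to +60 μm in 15 μm steps, 3 trials
per offset repeated every 10 s, 250 ms spiral stimulation (10 μm diameter,
5 revolutions), and bead stacks at 0.1 μm lateral / 1 μm axial sampling
with 256×256-px-class fields.

Forward model, in order:

* **dose** — the excitation delivered to a cell at focus offset z is the
  1D axial convolution of the cell's opsin-weighted profile
  (peak-normalized) with the axial OPSF density, evaluated by midpoint
  quadrature on a grid symmetric about the cell center (the top-hat edges
  fall between nodes, keeping the discontinuity error at O(step²)). The
  lateral dimension drops out because the spiral tiles the soma; the
  lateral OPSF width enters only bead rendering. Dose lies in (0, 1].
* **response law** — ΔF/F amplitude follows a Hill curve
  A = A_max·doseⁿ/(doseⁿ + hⁿ) with defaults A_max = 2.0 ΔF/F (within the
  0–3 ΔF/F range typical of strong GCaMP6s responses), h = 0.3 on the
  normalized dose scale, n = 2. Saturation is the experimentally motivated
  feature; the specific functional form is a modeling choice, and n is
  exposed to make the law threshold-like when desired.
* **kinetics** — transients follow (1 − e^(−t/τ_rise))·e^(−t/τ_decay),
  peak-normalized, with τ_rise = 0.2 s and τ_decay = 1.5 s (GCaMP6s-like).
* **rendering** — somata are uniform disks at 100 a.u. baseline over a
  10 a.u. background; stimulation frames add a constant artifact in the
  target pixels (excluded from analysis windows by construction); noise is
  Gaussian with variance proportional to signal (Poisson surrogate) plus
  additive read noise. Synchronization traces (10 kHz) carry one clock
  rising edge per frame and a gate pulse per stimulation.
* **ground truth** — the per-trial table stores dose, amplitude, artifact
  frame indices (derived from the generated sync record via the same
  onset detector the analysis uses) and the exact window-mean ΔF/F the
  pipeline recovers on a noiseless movie, including the small baseline
  bias from residual decay of earlier transients.

A fast path (`simulate_response_curves`) skips rendering and draws trial
responses as amplitude + i.i.d. Gaussian noise, for cohort-scale
statistical tests.

Coordinate convention: z increases downward into tissue, so "+60 μm"
places the focus 60 μm below the imaging plane; the sweep direction labels
("standard" = ascending z) order the acquisition timeline only.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: brain motion within an acquisition,
neuropil contamination and ROI cross-talk, opsin desensitization over
repeated trials, spiking nonlinearity between photocurrent and calcium,
indicator saturation dynamics beyond the static Hill law, and non-spherical
or perisomatically labeled cells. The experimental group widths measured
in vivo (tens of μm with substantial neuron-to-neuron spread) reflect
those factors on top of the geometry modeled here, so synthetic cohort
widths are expected to be narrower than in vivo ones; the package's
claims on real data are limited to the correctness of the measurement
procedure itself.

## Problem sizes and numerical choices

Test and acceptance runs use reduced sizes chosen to exercise every code
path at full fidelity: 48×48 px frames for rendered movies (one soma plus
background), bead stacks of 48×48 lateral voxels, cohorts of 15 neurons
per condition via the fast path, and 20 seeded bead stacks per condition
for recovery statistics. Noiseless movie tests shorten the repeat interval
to 4 s where trial independence is not at stake (the minimum compatible
with the 1.5 s + 0.25 s + 1.5 s windows) and keep the 10 s default where
it is. Seeds are explicit function arguments everywhere; no global RNG
state is used. Degenerate inputs (flat profiles, empty gates, zero-area
ROIs, non-positive baselines) raise or return NaN failure values rather
than propagating silently.

## Known limitations

* The OPSF is assumed independent of the SLM z offset; measuring its
  offset dependence requires remote-focusing hardware and is out of scope.
* Registration across acquisitions is integer-pixel translation of mean
  images — adequate for drift, not for rotation or non-rigid motion.
* The per-offset t-tests are reported uncorrected by design; consumers
  needing family-wise control should apply their own correction.
* The half-prominence width is undefined (NaN) for curves whose maximum
  sits on the sweep boundary; such curves indicate an incompletely sampled
  response and should be re-acquired with a wider sweep.
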