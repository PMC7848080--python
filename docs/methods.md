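# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations behind `synapsekit`. Units are micrometers and
seconds throughout; a particle at the center of pixel `(i, j)` has
coordinates `x = (j + 0.5) * pixel_size`, `y = (i + 0.5) * pixel_size`
(0-based indices).

## Synthetic data

The simulator exists so that every analysis stage can be checked against
known ground truth. It emulates TIRF imaging of T cell synapses on
supported lipid bilayers at desk scale; its defaults are the package's
study conditions and are not adjusted per experiment.

**Geometry.** A synapse is a set of concentric zones: cSMAC disc
(default radius 1.5 um), pSMAC annulus (to 3.5 um), dSMAC annulus (to the
5.0 um contact edge), centered in a 12.8 um (128 px at 0.1 um/px) field.
These radii and the 0.1 um pixel are typical of mature primary-T-cell
synapses imaged at high magnification.

**Channels.** Per-channel radial intensity functions are sampled at each
pixel-center radius. The default set places the TCR-ligand (UCHT1) signal
in the cSMAC, ICAM1 in the pSMAC, a dSMAC-biased receptor ring, and an IRM
channel that is dark inside the contact and bright outside — the IRM
convention used throughout (close membrane apposition reflects darkly).
Optional noise replaces each pixel by a scaled Poisson draw with the clean
value as mean.

**Trajectories.** Three modes, one label per track:

- *normal*: 2D random walk, per-axis step variance `2 D dt`, so the
  ensemble MSD is `4 D tau`. Default D = 0.1 um^2/s, in the range reported
  for membrane receptors in live T cells.
- *active*: the same walk plus a constant-speed drift (default
  v = 0.5 um/s) pointed at the contact center each frame (clamped so it
  never overshoots), modeling centripetal transport; a fixed drift
  direction can be supplied instead.
- *confined*: the walk reflected off a circular corral (default radius
  R = 0.15 um) centered on the start; the reflection is a radial fold, so
  tracks provably never leave the corral.

Frame interval defaults to 0.05 s and track length is capped at 300 frames
(15 s), mirroring standard acquisition (50 ms/frame for 15 s). Mode counts
in a simulated cell follow deterministic largest-remainder rounding of
`n_tracks * proportions` (ties to the lower index), so tests can assert
exact counts; per-track random draws are available behind `random_modes`.
Start positions are uniform over the contact disc — an assumption, since
the true spatial distribution of receptor start positions is not known.

**Movies.** Each detected position contributes a pixel-integrated isotropic
Gaussian (error-function differences across pixel edges; default
sigma = 0.15 um, 500 photons/spot) on a constant background, optionally
Poisson-corrupted. No EM-gain noise, 3D PSF, or evanescent-depth model.
Out-of-frame positions are clip-rendered with a warning and a metadata
flag.

**Screens.** Fraction-positive responses are
`baseline + 4PL(c) + N(0, noise_sd)` clipped to [0, 1], over a 9-point
titration (0 plus 1e-4..1e3 ng/ml) and 6 donors with noise_sd = 0.02 —
dose range matching superantigen stimulation protocols, noise matching
typical donor scatter on the fraction scale.

All randomness flows from one integer seed per call (`numpy` Generator);
identical seeds give bit-identical outputs.

What the simulator does *not* emulate: photobleaching and blinking,
receptor clustering (multiple molecules per diffraction-limited spot),
kinapse (broken-symmetry) geometries, time-evolving partitions, chromatic
offsets, and uneven illumination. Passing tests therefore demonstrate
correctness of the *analysis* under the stated model, not robustness to
every artifact of real data.

## Segmentation

The contact mask is pixels below an automatic global threshold of the IRM
channel (Otsu), morphologically closed with a 3-px-radius disc, hole-filled,
largest connected component kept; components below 5 um^2 raise
`NoContactError`. The closing radius stabilizes boundaries on Poisson-noisy
input. cSMAC = largest connected UCHT1-enriched component within the
contact (threshold computed over in-contact pixels only; the
largest-component rule keeps peripheral TCR microclusters out of the cSMAC
label); pSMAC = ICAM1-enriched remainder; dSMAC = the rest. The three
labels partition the contact exactly, by construction. A channel with no
in-contact contrast yields an empty (flagged) cSMAC or pSMAC rather than an
arbitrary split. Otsu on raw values makes all labels invariant to positive
affine rescaling of each channel; absolute threshold overrides are
available. The contact center is the mask's area centroid (an
intensity-weighted centroid is available behind a flag).

## Radial profiles, enrichment, colocalization

The reference radial average rotates the image about the center through
every integer angle 1-359 deg (bilinear interpolation) and mean-projects the
stack with the original. This is mathematically annular averaging up to
interpolation, so an annular-binning fast path (1-px annuli, values
interpolated back to each pixel's radius) is provided; the two agree to
well under 1% on realistic images over the disc inscribed about the center.
Outside that disc the rotation stack averages in out-of-field zeros, so
comparisons and conservation statements are made within it. Bilinear
resampling conserves total intensity to <0.1% on smooth images; its worst
case — a single-pixel delta — loses about 2%, while the binned annular
profile conserves mass exactly.

Cross-section profiles are annular means versus radius; min-max
normalization maps them to [0, 1], and a flat profile is returned as zeros
with a degenerate-normalization flag rather than NaN. Multi-cell averaging
resamples normalized profiles onto the union radius grid restricted to the
common radial range (no per-cell radius rescaling by default, matching
direct image averaging; a normalized-radius mode would be a deliberate,
non-default choice).

The enrichment index of region r is its in-contact intensity fraction over
its area fraction; the area-weighted mean of the indices is exactly 1 for
any image, which the tests assert. Raw in-contact intensities are used;
an optional constant background subtraction is exposed because whether the
original percentages were background-subtracted is not knowable from the
outputs alone.

Thresholded Pearson correlation includes pixels above an automatic (Otsu)
threshold in *either* channel — excluding the joint background that
inflates correlations — and requires at least 3 included pixels and
nonzero variance. The one-sample two-tailed t-test (against 1 for
enrichment, 0 for correlation) is the standard n-1 df statistic.

## Tracking

Detection: difference-of-Gaussians bandpass with
`sigma1 = diameter / (2*sqrt(2)*1.1)`, `sigma2 = 1.6 * sigma1` (standard
blob-detection convention; only the 0.5 um diameter is prescribed), local
maxima at >= half a diameter separation, sub-pixel refinement by
intensity-weighted centroid of the positive DoG response in a window of
half-width `ceil(0.6 * diameter_px)`. The window covers the full positive
core of the DoG response; a window of only one spot diameter truncates the
core asymmetrically and biases off-center positions by ~0.2 px, whereas
the chosen window measures <0.01 px worst-case on noise-free spots.
Quality is the DoG response at the maximum. The automatic quality gate is
an Otsu cut over the per-frame quality distribution, applied only when the
cut separates two genuinely distinct populations (low-group mean below
half the high-group mean); otherwise all maxima are kept, so homogeneous
populations of real spots are never split.

Linking is the two-pass LAP scheme: frame-to-frame assignment with squared
displacement costs, links forbidden beyond 1 um and the non-link
alternative costed at `max_link^2`; then a gap-closing pass bridging a
track end to a later start within 1 missing frame and 1 um, costed the
same way. Assignments are solved exactly (Jonker-Volgenant via
`scipy.optimize.linear_sum_assignment` on the augmented square matrix), and
the tests verify equality with exhaustive minimum-cost matching on small
instances. Bridged frames are stored as missing; no merge/split events are
modeled. The default length filter keeps tracks with >= 30 detected frames
(1.5 s of observation at 50 ms/frame); gap frames do not count.

## Diffusion classification

The per-track time-averaged MSD at lag `k dt` averages squared
displacements over gap-free frame pairs exactly k apart (a pair whose
intermediate frames were undetected is excluded, as is any gap-spanning
step in the mean speed). Lags run to one third of the track span; the
anomalous exponent alpha is the OLS slope of log MSD vs log lag over the
first 10 usable lags (time-averaged MSD is unreliable at long lags), and
D = MSD(tau_1) / (4 tau_1). Classification is a transparent threshold rule:
alpha < 0.7 confined, alpha > 1.3 active, else normal — standard SPT
practice; a stationary (all-zero MSD) track is classified confined and
flagged. Classification is invariant to rigid motions of the track.

**Known limitation — slow directed transport.** With drift v and diffusion
D, the MSD is `4 D tau + (v tau)^2`; directed motion dominates only beyond
the crossover lag `4D / v^2`. At D = 0.1 um^2/s and v = 0.5 um/s that
crossover is 1.6 s — beyond the fitted lag range of a 5 s track — so the
expected exponent of such a track is ~1.1 and the alpha rule files it under
normal diffusion. This is not specific to the rule: for Brownian motion
with constant drift the net displacement is a sufficient statistic, and
the optimal per-track test (Rice vs Rayleigh on the net displacement
magnitude) still has an ~19% equal-error rate at these parameters over
100 frames. Per-track classification of slow directed transport is
information-limited; category frequencies for the active class are
therefore comparable across conditions only qualitatively. Confined and
normal tracks at the default parameters are recovered with >= 0.98
per-class accuracy.

## Region dynamics

Track positions are assigned the label of the containing pixel (floor
indexing; positions outside the image are `outside`), against a single
static partition per cell — matching analyses that segment a snapshot
taken immediately before the video. Occupancy counts a track for a region
when it spends >= 3 frames there, totaled across the track by default
("minimum of three frames" read as total, not consecutive; a consecutive
mode is behind a flag). Transition summaries collapse each label sequence
to runs and count boundaries between distinct consecutive runs, so they
are invariant to run-preserving resampling; gap frames carry no label and
break a run only when the post-gap label differs.

Normalized distance divides each track's distance-to-center series by its
starting distance (first value exactly 1); the reported statistic is the
per-track OLS slope versus time, plus a pooled fit (whether the original
regression was per-track or pooled is ambiguous, so both are emitted).
Tracks starting within 0.1 um of the center are excluded — the
normalization divides by the starting distance. Note a genuine property of
this statistic: the radial distance of planar Brownian motion drifts
outward (`d<r>/dt = D/r`), so a Brownian ensemble's mean normalized slope
has positive expectation ~E[D/d0^2], heavy-tailed when small starting
distances are admitted. The robust null for "no centripetal transport" is
therefore one-sided (no *inward* trend), and that is what the test suite
asserts at module level; the two-sided "within +-2 SE of 0" reading is
marginal at realistic ensemble sizes and fails at large ones.

## Intensity ratios

Distal/basal: mean intensity per z-plane inside a 3 x 3 um box at the
synapse center; basal is the peak over the lower half of the z-range,
distal over the upper half (the halves share the middle plane for odd
counts, making the ratio of a z-mirrored stack exactly the reciprocal).
The ratio is reported distal-over-basal; take the reciprocal for the
basal-relative reading. Contour extraction for vesicle-contact profiles is
out of scope — the operation consumes an already-sampled profile (0.5 um
spacing, flanks out to one contact width on each side; shorter flanks are
flagged as truncated) and returns mean(outside)/mean(inside). Both ratios
are invariant to positive intensity scaling.

## Screen statistics

Responses are `100 * (frac_pos - frac_baseline) / reference_max`, where the
baseline is the zero-dose row of the same target/donor/marker and
`reference_max` is the maximum mean baseline-subtracted response of the
CD19-targeted control (per marker) — so the control's own maximum is
exactly 100. Baseline rows are consumed by the subtraction and excluded
from fitting: a zero concentration cannot enter the log-domain 4PL model.

The 4PL fit runs in log10 concentration with bounds Bottom >= 0 and
0 < Hill <= 10 (identifiability with 7-point titrations), initialized from
the response range and the median log-dose; noise-free data are recovered
to ~1e-16 relative error. Emax is the fitted curve at the highest tested
dose. The extra sum-of-squares F test compares a shared 4PL fit of two
pooled datasets against separate fits (all four parameters free per
curve — a whole-curve comparison; per-parameter tests are out of scope):
`F = ((RSS_sh - RSS_sep)/(df_sh - df_sep)) / (RSS_sep/df_sep)`. Raw
p-values are reported; Benjamini-Hochberg adjustment is available behind a
flag and never applied by default. The functional family is recorded in
the output (`model = "4PL"`) since the exact family used by point-and-click
fitting software is ambiguous.

## Problem sizes

The test and acceptance runs use desk-scale sizes chosen to make the
statistical assertions sharp while completing in seconds: 96-128 px
images, 9-track movies for recovery, 500 tracks x 100 frames for mode
recovery, 120-track ensembles x 40 frames for directional dynamics, 50
random geometries for the segmentation round trip, 200 random instances
for the assignment oracle, and 50 replicate screens for F-test power.
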