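# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `pdmotor`. Nothing here reports an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

The camera ("skeleton space") frame is right-handed with +Y vertical (up) and
+Z out of the sensor toward the subject; joint positions are meters,
timestamps seconds, nominal sampling 30 Hz. Gait analysis runs in a *subject
frame* (x forward, y to the subject's left, z up) obtained by a rigid
transform: the vertical is taken from gravity (camera −Y), the forward axis
from the net horizontal displacement of SpineBase between the initial
quasi-static calibration interval (first 1.0 s, a T-pose stand) and the end
of the walk. Less than 0.5 m of net displacement is an error — the walking
direction cannot be estimated from a stationary subject. Because the
transform is rigid, inter-joint distances are preserved to machine precision,
and all 16 gait features are invariant to rotating the walk about the
vertical.

Skeleton sequences are stored as long-format CSV (one row per frame/joint,
1-based frame index, `repr`-precision floats) so a write/read round trip is
bit-exact. Depth is stored as 16-bit PNG with a `depth_scale` (meters per
unit) in the intrinsics JSON.

### Missing joints

Frames in which a joint needed downstream is untracked are linearly
interpolated across gaps of at most 3 frames (100 ms at 30 Hz); longer gaps
split the usable interval and any cycle touching one is excluded. The SDK's
actual behaviour for untracked joints during walking is unknown; bounding the
interpolation avoids fabricating motion.

## Gait

### Event detection

Heel strike (HS) and toe off (TO) are detected from the ankle-minus-pelvis
forward coordinate: the ankle is maximally ahead of the pelvis at HS and
maximally behind at TO (the standard Zeni-style kinematic proxy). Rough
extrema come from `scipy.signal.find_peaks` on a zero-phase 4th-order
Butterworth low-pass at 6 Hz (prominence 25% of the signal excursion, minimum
separation 0.4 s). Foot contact is a slope break, not a smooth parabola, so
each event time is refined on the unfiltered trace as the intersection of a
straight-line fit on the stance side (where the coordinate recedes linearly
at the gait speed) and a local quadratic on the swing side. Two HS candidates
within 0.2 s are resolved in favour of the lower ankle. On noise-free
synthetic gait the refined events land within a couple of milliseconds of
truth; the suite asserts ±1 frame.

### Cycles and phases

A cycle spans consecutive ipsilateral heel strikes and must contain exactly
one ipsilateral TO, one contralateral HS and one contralateral TO in the
expected order; otherwise it is discarded with a warning. The seven
conventional phases are reported with LR ending at the contralateral TO and
PSW starting at the contralateral HS (both event-fixed); the MST/TST split is
placed at 30% of the cycle and the swing is divided into equal thirds. No
feature depends on those inner boundaries, so a documented convention
suffices.

### Features

Temporal features are ratios of mean durations over the side's cycles, which
makes two identities exact by construction: STp + SWp = 100 and
STDc · STDt = 60. Total double support per cycle is the initial segment
(ipsi HS → contra TO) plus the terminal one (contra HS → ipsi TO); note that
for any alternating biped this sums structurally to
(stance%_left + stance%_right − 100) of the cycle.

Spatial features interpolate ankle trajectories at event times: STDl is the
forward ankle travel between the cycle's heel strikes, SPl the forward
inter-ankle distance at the contralateral HS, SPw the mediolateral distance
between the two heel-strike placements, STDv = STDl/STDt, and SWv the mean
forward ankle speed during swing. Raw units (cm, m/s) are canonical;
`normalize=True` adds dimensionless copies (lengths by subject height, width
by lower-limb length).

Angular features measure segment inclinations against the vertical: trunk
(SpineBase→SpineShoulder) and neck (Neck→Head) sagittal means (TFlex, NFlex),
the signed frontal-plane trunk mean (PS, positive toward the analysed side —
the lateral-lean sign convention is otherwise arbitrary), and the arm-swing
range of motion (ASrom) of the sagittal shoulder→elbow angle
(the upper-arm segment; whether the forearm should be included is left open
by the protocols this follows). ASrom is computed per cycle as twice the
amplitude of a least-squares sinusoid at the stride frequency: for sinusoidal
swing this equals the max−min excursion exactly, and unlike a raw max−min it
is unbiased under additive joint noise (a per-cycle extreme of a noisy trace
is inflated by roughly the noise SD in angle units, ~1° at 3 mm jitter, which
would exceed the generator's 0.3° angular bias budget).

## Tapping

### Vision stage

Marker blobs are segmented per infrared frame by: global threshold at 80% of
the frame maximum (retroreflective markers saturate the IR image, so a
relative threshold also makes detection invariant to uniform gain), a
Gaussian blur (σ=1, ~5×5) re-thresholded to suppress isolated hot pixels,
binary opening then closing with a 3×3 disk, connected-component extraction,
an area filter against the expected marker size, and the binary center of
mass as centroid (blobs returned largest-first). A frame with more than half
its pixels above threshold is rejected as uninformative. Centroids are
back-projected with the pinhole model X=(u−cx)z/fx, Y=(v−cy)z/fy,
Z = depth·depth_scale; invalid depth at the centroid falls back to the median
of the valid 3×3 neighbourhood, else the frame is a gap. Marker identity is
assigned by area at first detection (the thumb thimble is assumed larger) and
nearest-neighbour tracking afterwards; d1 is symmetric in the two markers, so
an identity swap is harmless.

### Signals and trials

d1(t) is the Euclidean inter-marker distance; d2(t) is the distance of the
toe marker from its rest reference, the median position over the
lowest-decile-height frames (at least 0.3 s of rest is required). Gaps of at
most 3 frames are interpolated; both signals are min–max normalised to
[0, 1], and a dynamic range under 1 mm is an error (a static marker cannot be
normalised meaningfully). Trials are delimited around the dominant peaks
(prominence ≥ 0.3 normalised units, separation ≥ 0.15 s): interior boundaries
sit at the centre of the minimum run between adjacent peaks, edge boundaries
mirror the adjacent half-interval so the first and last trials carry full
valley-to-valley durations. Only the first 10 peaks are kept (the protocol
prescribes ten taps); fewer than 10 warns and proceeds.

### Features

meanTime/varTime and meanAmplitude/varAmplitude are the mean/population
variance of trial durations and peak amplitudes. `tremors` counts *all*
local maxima of d(t) with prominence ≥ 0.02 over the acquisition (so it is
at least the trial count; group comparisons rely only on its monotonicity in
added bumps). `hesitations` counts local maxima of |d′(t)| — central
differences after a zero-phase 5 Hz low-pass, since 30 Hz samples are too
noisy to count speed peaks raw — with prominence ≥ 5% of the peak speed.
`periodicity` is the height of the first non-zero-lag peak of the unbiased
normalised autocorrelation of d(t) (lags restricted to half the record),
computed over the span from the first to the last trial: the rest before and
after the exercise is protocol dead time, not part of the rhythm. The value
is clipped to [0, 1]; a pure sinusoid scores 1. This autocorrelation form is
a documented stand-in — the literature formula it replaces is not public —
so no test depends on its absolute value away from the analytic sine limit.
AxF averages peak amplitude over trial duration across trials.

## Classification

Instances are (subject, side) pairs: sides are treated as independent, so 30
subjects yield 60 Case A instances and the 16 PD subjects 32 Case B
instances. The positive class is PD in Case A and *mild* in Case B (with
56.3% mild prevalence an always-mild classifier then shows the
characteristic sensitivity 100 / specificity 0 pattern).

CFS scores a subset S of k features by M(S) = k·r̄_cf /
√(k + k(k−1)·r̄_ff), with r̄_cf the mean |point-biserial| feature–class
correlation and r̄_ff the mean |Pearson| feature–feature correlation
(constant features get correlation 0 and are never selected). Search is
best-first forward expansion with a stale limit of 5 non-improving
expansions; for ≤ 8 features it provably matches exhaustive enumeration (and
the suite checks this).

SVMs run on z-scored features with C=1: linear, inhomogeneous polynomial of
degree 2/3 (quadratic/cubic), and RBF with bandwidth from the median
pairwise distance of the standardised training fold (γ = 1/(2·d_med²)) — the
usual heuristics, since no hyperparameters are prescribed. The ANN is a
1–2-hidden-layer logistic-activation perceptron trained with a fixed
iteration budget (L-BFGS, 500 iterations). Its topology is picked by a small
genetic algorithm (population 20, 15 generations, tournament selection,
one-point crossover 0.7, per-gene mutation 0.2, elitism, hidden sizes 2–16):
the fitness of a topology is its mean held-out accuracy over 3 random
stratified 70/30 permutations of the instances. Fitness values are cached
per topology and the whole search is a deterministic function of its seed.

Evaluation is stratified 5-fold cross-validation (stratification is a
deliberate choice — with 32 instances unstratified folds can be
single-class); instances are put in a canonical lexicographic order before
fold assignment so the metrics depend only on the data content and the seed,
never on row order. Metrics are accuracy, sensitivity and specificity in
percent, mean ± population SD across folds. Feature selection runs once on
the full table by default, mirroring how selected subsets are reported
globally; `cfs_in_cv=True` moves it inside each training fold to avoid
selection bias. An optional subject-grouped CV keeps both sides of a subject
in the same fold; it is off by default because sides are defined as
independent instances.

## Synthetic generator

The generator is *feature-level*: walks are constructed directly from target
feature values, so extraction has an exact ground truth to recover — the
artifact validates the measurement pipeline, not a biomechanical model.

A walk consists of a 1.0 s standing calibration interval followed by
`n_strides` strides toward the camera (placed 0.75 m high, 3.5 m away).
The pelvis advances at stride_length/stride_time; each ankle alternates
stance (anchored at its foot placement) with a smooth swing whose phase rate
stays strictly positive (0.55–1.45 of the mean), so the ankle decelerates
into contact and accelerates out of toe off abruptly — as a real foot does —
and the relative-forward extrema coincide exactly with the contact events.
Arms swing sinusoidally at the stride frequency, anti-phase to the
ipsilateral leg, with amplitude ASrom/2; constant trunk/neck sagittal tilts
and a frontal trunk tilt are injected exactly (the trunk direction vector is
built from the tangents of the target angles, so the extracted angles match
by construction). Gaussian jitter of 3 mm SD (a typical consumer depth-camera
joint noise magnitude) is added to every joint; it is configurable.

Per-group parameter distributions default to the published cohort statistics
for healthy / mild / moderate gait. Deterministic identities are respected
rather than drawn: STp, STDt, STDl, SPl (as a step phase), SPw, TFlex,
NFlex, PS and ASrom are independent truncated-normal draws, while SWp, DSp,
STt, SWt, STDc, STDv and SWv follow from them. Two consequences are worth
stating plainly. First, cadence is 60/STDt per walk, so the cohort-mean
cadence is E[60/STDt] ≈ 46.3 strides/min under the healthy stride-time
distribution — slightly above the table value of 45.0, which was measured on
real data where the two quantities were estimated separately; a generator
honouring the identity cannot match both marginals at once, and stride time
is the primary draw. Second, double support is structurally
2·STp − 100 of the cycle (≈ 20.2% for STp = 60.1%), so the published DSp
marginal (18.6%) is not independently injectable either. The step phase
SPl/STDl is clipped to the interval the stance fraction admits, mildly
narrowing the realised SPl marginal. Recovery tests therefore compare
extracted values against *injected* truth for all features, and against the
published marginals for the unconstrained draws only.

Tapping signals are trains of raised-cosine pulses occupying 70% of each
period (taps dwell briefly between repetitions), with per-trial period and
amplitude jitter. Tremor bumps are small Gaussians (6% of the mean
amplitude, σ = 45 ms) placed in inter-trial rest dwells, where they create
countable local maxima. Hesitations are mid-rise dwells implemented by a
monotone time warp whose rate dips to 3% for ~0.3 s, extending the trial and
splitting its rise-phase speed peak. No published group statistics exist for
the tapping features, so the per-group tapping profiles (periods slowing and
amplitudes shrinking from healthy → mild → moderate, with Poisson-distributed
tremor/hesitation counts) are free parameters of the generator chosen to
separate the groups moderately; conclusions about tapping classification
accuracy describe these synthetic conditions only.

Infrared frames render each marker as a saturated (flat-top) Gaussian blob —
retroreflectors saturate real IR sensors — with matched depth inside the blob
disk, a far background, and optional salt noise; projection is the exact
inverse of the back-projection used in extraction.

Cohorts draw one gait parameter set per subject (both sides extracted from
the same walk, giving the natural within-subject correlation) and one
finger + one foot tapping profile per side, with subject-level variation
around the group means. Default layouts are 14 healthy + 9 mild + 7 moderate
subjects (Case A, 60 instances) and 9 + 7 (Case B, 32 instances). Every
level — walk, signal, frames, cohort — is a deterministic function of its
seed via spawned child generators.

### What the generator does not emulate

Soft-tissue and skeleton-estimation artifacts (systematic joint mislocation,
depth-dependent noise, tracking dropouts under self-occlusion), turning or
non-straight walking, stride-to-stride autocorrelation, tremor spectra beyond
countable bumps, and any correlation structure between gait and tapping
impairment within a subject. Passing recovery tests therefore demonstrates
that the pipeline measures what it claims under the stated noise model — not
that clinical accuracy figures would transfer to real recordings.

## Problem sizes and runtimes

Recovery tests use 200 walks of 5 strides each (~10 s of simulated walking
per walk), which puts the standard error of cohort feature means well below
the published between-subject SDs; the full Case A study grid runs on the
default 60-instance cohort with the default GA budget (20 × 15 topologies,
3 permutations each, cached). The whole suite completes in well under a
minute on one CPU, the study grid itself in seconds.

## Known limitations

* Event detection is validated against the generator's kinematics only; the
  original segmentation method it stands in for is not reproduced in public
  sources.
* The periodicity formula is an autocorrelation stand-in (see above).
* The GA is a generic topology search; the "improved" variant it replaces is
  unspecified in public sources beyond its fitness definition.
* PS is a single whole-body quantity per walk; the per-side sign convention
  means left and right instances of the same subject carry opposite signs.
* Real-cohort accuracy figures are out of scope: the cohorts here are
  synthetic and the classification numbers describe them alone.
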