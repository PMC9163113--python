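# Methods

## Kinetic model

A myocardial voxel's activity concentration is modelled with the
single-tissue-compartment model for freely diffusible water, extended with
arterial blood volume and right-ventricular spill-over terms:

    C(t) = MBF·PTF · [C_A ⊗ e^{−(MBF/V_D)·t}](t) + V_A·C_A(t) + V_RV·C_RV(t)

* **MBF** — blood flow in perfusable tissue, mL·g⁻¹·min⁻¹. Appears in both
  the uptake amplitude and the washout exponent; the fit identifies it from
  the washout.
* **PTF** — perfusable tissue fraction, g/mL: the part of the voxel that
  exchanges water with blood.
* **V_A, V_RV** — unitless arterial and right-ventricular blood/spill-over
  fractions, constrained to `V_A, V_RV ≥ 0`, `V_A + V_RV ≤ 1`.
* **V_D** — distribution volume of water, fixed at 0.91 mL/g.
* **MBFt** = MBF·PTF/(1 − V_A) — transmural flow derived from the uptake
  rate, the quantity all retained-tracer methods measure.

Times are seconds internally; flows are per-minute at the interface, so the
washout rate is λ = MBF/(60·V_D) s⁻¹ and the uptake coefficient
k₁ = MBF·PTF/60 s⁻¹. Decay correction is assumed already applied, as in
reconstructed clinical data; no ¹⁵O decay term appears.

## Basis-function fit

The washout rate is profiled over a fixed grid: 100 log-spaced MBF values
on [0.2, 6.0] mL·g⁻¹·min⁻¹ (≈3.5% spacing), covering the clinical stress
range with margin. For each grid rate the convolution is precomputed
(exact recursion for piecewise-linear inputs, evaluated as a first-order
IIR filter) and frame-averaged, leaving a 3-coefficient non-negative
weighted linear least-squares problem per curve. Weights are frame
durations, a standard proxy for count statistics. The constrained optimum
is found by exact enumeration of the active sets of
{A ≥ 0, V_A ≥ 0, V_RV ≥ 0, V_A+V_RV ≤ 1} — at most 13 reduced solves, all
sharing one design matrix, so an entire image is fitted as a sequence of
dense matrix products (seconds for ~10⁴ voxels). The grid node with
minimal weighted RSS wins; ties within 10⁻¹² relative go to the smallest
rate, making output deterministic. Degenerate curves (all-zero) return
zero parameters with a flag; a fit whose amplitude vanishes reports
PTF = 0 and flags the grid-edge selection.

**Amplitude invariance.** Scaling a curve by k scales all linear
coefficients by k and the RSS profile by k² uniformly over the grid, so
the selected washout rate — hence MBF — is *bit-identical* under amplitude
changes. This is exactly why washout-based MBF resists
attenuation-correction errors that uptake-based MBFt cannot. One caveat
found during development: the physical bound V_A + V_RV ≤ 1 is not
scale-invariant, so for blood-rich curves a large upscale can activate the
constraint and perturb the selected rate. For myocardial voxels
(V_A ≲ 0.3, V_RV ≲ 0.1) the bound stays inactive across any realistic
amplitude error and the invariance is exact; the tests draw truths from
that regime.

Against a continuous-rate nonlinear least-squares oracle the grid fit
agrees in MBF to within one grid step by construction; PTF inherits the
grid quantisation through the profile ridge (bounded by about two steps),
while at a *fixed* rate the linear coefficients agree with an independent
NNLS route to 10⁻³.

## Input functions

Clinically the input functions are image-derived. Here they come from
eroded cavity VOIs: the mean cavity curve per frame is interpolated onto a
0.1 s grid and iteratively corrected until its frame averages reproduce the
measured frame values (which are themselves frame means) to 10⁻⁴ relative,
with the curve pinned to zero before the arrival frame. Plain
midpoint-linear interpolation was found to miss peak-frame means by up to
12% and was replaced by this mean-preserving scheme.

## Phantom

A voxelised thick-walled half-ellipsoidal LV (outer semiaxes 30×30×40 mm,
10 mm wall, open basally) with an adjacent RV pool, on a 64³ grid of 2 mm
voxels by default (the cohort experiment uses 40³ at 3 mm to keep a
12-analysis-per-subject study in minutes; the wall stays >3 voxels thick).
Axis convention: +X patient-left, +Y anterior, +Z caudal; the long axis is
Z with the apex caudal. The arterial input is a gamma-variate bolus
(shape α = 2, peak 60 kBq/mL at 25 s) plus an exponential recirculation
tail; the RV curve leads it by 4 s and is dispersed with a 6 s exponential
kernel. Wall voxels carry forward-model curves of their territory's truth
(default MBF 2.4/2.0/2.8 for LAD/RCA/LCX, PTF 0.70, V_A 0.15, V_RV 0.08
septal / 0.02 lateral); cavity voxels carry the frame-averaged input
curves. Territories are fixed 120° circumferential sectors about the long
axis (LCX lateral, LAD anterior+anteroseptal, RCA inferior+inferoseptal),
the three-territory reduction of the standard coronary map.

Frame noise is zero-mean Gaussian with SD = noise_scale·√(max(value,
floor)/duration) — variance proportional to activity and inverse to frame
duration, the behaviour of reconstructed-image noise. The default
noise_scale 0.4 was calibrated once to ≈5% relative noise on late wall
frames, at which the fitter's median |MBF| error is ≈2.3% over the
0.5–4 mL/g/min range. The phantom deliberately omits scanner resolution
(no PSF: cavity and wall voxels are pure), sinogram-level effects
(scatter, randoms, reconstruction), and intra-scan motion — so passing
tests demonstrate correctness of the estimation chain and the *mechanism*
of misalignment bias, not absolute clinical error magnitudes.

## Misalignment model

Attenuation-correction errors from PET–CT misalignment change the
amplitude of tissue curves, not their shape. The model is therefore a
static multiplicative field rather than re-projected attenuation physics:

    factor(v) = 1 − ε · Σ_axis d_axis · max(0, n_axis(v))

with d the shift (mm), n(v) the outward wall normal, and the lung-adjacent
reference directions +X (lateral wall), +Y (anterior), +Z (caudal apex).
A shift toward a lung-adjacent wall depresses that wall; the reverse shift
inflates it symmetrically; cavities and background are untouched (an
option extends the field to cavity voxels, which then also biases the
image-derived inputs — off by default). The field is exactly linear in
amplitude, so 20 mm doubles the 10 mm effect. ε defaults to 0.01/mm,
chosen once so a 20 mm lateral shift attenuates the most-lateral wall by
~20%, the order of the strongest clinically observed uptake-flow effects.
Factors are floored at 0.05 to stay positive under extreme settings.

A consequence worth stating plainly: with tissue-only bias at default
strength, washout MBF deviations in the cohort experiment are *exactly
zero* — per-voxel amplitude scaling provably cannot move the basis-fit
MBF, and segmentation membership does not change at these bias levels.
Small nonzero MBF deviations seen clinically arise from mechanisms outside
this model (biased input functions, nonlinear attenuation artifacts,
segmentation shifts); the model reproduces the washout-vs-uptake
robustness ordering in its purest form.

## Segmentation

ATF = 1 − V_A − V_RV (clipped to [0, 1]) gates the wall: with the ATF rule
on, PTF is zeroed where ATF < 0.25, and the wall mask is the largest
26-connected component of PTF > 0.25 g/mL. Both thresholds are
config-exposed; the defaults segment the noiseless default phantom
perfectly. The connected-component step suppresses noise islands. An empty
result raises a segmentation error that the study driver records as an
exclusion for that subject-condition, mirroring the clinical failure mode
under severe lateral misalignment. In this model, amplitude-*reducing*
shifts delete wall through the PTF floor (scaling down also lowers fitted
blood fractions, which raises ATF), whereas the ATF rule bites when
amplitudes are inflated.

## Study design and statistics

Eleven conditions in six directions: X±10, X±20 (lateral), Y+10
(anterior), Z±10, Z±20 (caudal/cranial), and two combined
anterior-cranial shifts. The combined conditions are labelled
"Y+10Z+10" / "Y+10Z+20" after the conventional table rows while shifting
anterior *and cranially* (dz = −10/−20); the label/sign tension in the
source conventions is resolved in favour of the described directions.

Each synthetic subject draws a global MBF uniformly from 1.0–4.2
mL·g⁻¹·min⁻¹ (the observed stress range), scaling the territory pattern.
Per subject the aligned noisy image is analysed once, then each condition
biases the *same* image and the full analysis (input extraction, voxel
fit, segmentation, territories, regional means) repeats. Deviations are
percent changes against that subject's aligned value. Per condition and
region: mean ± SD of deviations, ICC(A,1) (two-way ANOVA mean squares,
McGraw–Wong absolute agreement), and the two-sided Wilcoxon signed-rank
p-value — exact by enumeration of all 2ⁿ sign assignments for n ≤ 15
(valid under midranked ties), normal approximation with tie-aware variance
and continuity correction above. No multiple-testing correction is
applied, matching the per-cell presentation convention. Ischemia
reclassification uses strict-inequality thresholds (2.3 MBF / 1.8 MBFt
mL/g/min; boundary values non-ischemic) and counts false positives and
false negatives per condition, region and flow kind. Failed analyses are
recorded as exclusions and drop out of that condition's statistics.

## Numerical and I/O choices

* Fine simulation/fit grid: 0.1 s; frame values are means over frame
  intervals (reconstruction integrates counts), with the half-open
  convention start ≤ t < end.
* Convolution recursion is exact for piecewise-linear inputs and switches
  to its series limit for λ·dt < 10⁻⁸.
* All randomness flows from explicit integer seeds; identical seeds give
  bit-identical images and tables.
* Images as NIfTI-1 with a JSON sidecar (frame starts/durations, axis
  tag); NIfTI lacks a standard frame-timing field. CSV numbers use 12
  significant digits for reproducible diffs.

## Limitations

No resolution modelling or partial-volume blur; no sinogram-level physics
or reconstruction; the amplitude-bias field is a first-order surrogate for
attenuation error, so absolute bias magnitudes depend on the chosen ε and
only the directional structure (signs, amplitude ordering, washout-vs-
uptake robustness) is meaningful; inputs are phantom-geometry VOIs rather
than a clustering-based extraction; coronary flow reserve and rest/stress
comparisons are out of scope; observer-variability statistics require
human readers and are not simulated.
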