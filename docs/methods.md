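# Methods

This note documents the models, parameter choices and numerical decisions
behind `bowelperf`, and what the synthetic-data validation does and does
not establish.

## Data model and conventions

Hyperspectral cubes are reflectance-calibrated arrays indexed
(row, col, band) on an ascending wavelength grid; the nominal grid is
500–995 nm at 5 nm (100 bands), but any uniform grid covering 750–850 nm is
accepted. Pixels are 0-based with x = column and y = row; a circular ROI
contains every pixel centre with `dx² + dy² ≤ r²` (a radius-1 disc is the
centre plus its 4-neighbours). Reflectance above 1 is accepted — specular
glare exceeds the white-reference calibration — but negative values are
rejected at read time. ENVI header/binary pairs are the interchange format
(BSQ/BIL/BIP, float32/float64, bit-exact round trip); a configurable raw
float32 reader covers vendor layouts whose byte order and interleave are
not otherwise published.

## ICG reconstruction

The pipeline is: 1-D Gaussian smoothing along the band axis (σ = 4.44 in
band-index units ≈ 22 nm on the nominal grid; kernel truncated at radius
⌈4σ⌉, reflect padding) → central-difference second derivative with respect
to wavelength (per nm²; edge bands replicate their nearest interior value)
→ arithmetic mean over bands centred in [790, 810] nm (five bands
nominally; on other grids the 1/5 constant generalises to one over the
window band count) → negative curvature clipped to zero → 7 × 7 median
filter (reflect padding) → division by the 99th percentile of the filtered
map → clip to [0, 1]. If the 99th percentile is ≤ 1e−12 the image is all
zeros.

Decisions worth stating:

- σ is interpreted in band-index units because no unit accompanies the
  published value; it is configurable.
- The derivative's absolute scale cancels in the percentile normalisation,
  so the nm² unit is a readability choice only; the output is invariant
  under global multiplicative rescaling of the cube.
- Negative curvature is clipped before median filtering: an absorption dip
  produces positive curvature at its minimum; negative values come from
  noise and other chromophores. Flat (saturated glare) spectra contribute
  zero curvature, and the median filter removes isolated glare residue.
- The percentile is computed over the whole image, per image (not per
  acquisition series).

## Tissue indices

Clinical HSI devices derive StO2, NIR PI, OHI and TWI from reflectance
ratios within selected spectral ranges, on a 0–100 scale; the exact
formulas are proprietary. The engine is therefore fully configuration
driven: each index is a ratio of window means (in reflectance or absorbance
−log R), mapped affinely to 0–100 and clipped. The shipped defaults
(StO2 570–590/740–780 nm, NIR_PI 655–735/825–925 nm, OHI 530–590/785–825 nm,
TWI 880–900/955–980 nm, all absorbance) are **non-authoritative
approximations** chosen so that plausible tissue spectra land mid-scale;
they exercise the pipeline but must not be read as validated clinical
formulas. Denominator means with magnitude ≤ 1e−12 yield 0 with a logged
warning count.

## Inflow quantification

The analysis object is the laser-normalised, smoothed ROI curve. The
moving-average window is 3 s, converted to an odd frame count and applied
with a symmetric window that shrinks at the record ends. Background noise
`B` is the maximum of that curve 3–6 s after administration (capture starts
with the bolus, so the stack clock is the administration clock by default);
`T0` is the earliest sample at or after the end of that window from which
the curve exceeds `B` at every later sample.

The smoothing window trades onset bias for noise suppression: on a
noiseless ramp the smoothed curve starts rising half a window early, so
`T0` would read ~1.4 s early; with noise present, `B` rises with the noise
level and the crossing moves later, and the two effects largely cancel (the
recovery grid shows a median error of ~0.4 s at SNR 10). The noiseless
exactness test therefore runs with the window reduced to a single frame
(smoothing disabled), which isolates the estimator definitions from the
smoothing bias; both the window and the curve stage used for `T0` are
configurable.

The slope is an ordinary least-squares fit over the contiguous segment of
highest local slopes: local slopes are central differences of the smoothed
curve taken at a stencil of half the smoothing window (one sample when
smoothing is off), the segment is the maximal run containing the global
maximum where the local slope stays ≥ 50 % of it (fraction configurable),
and a degenerate one-or-two-sample run (an isolated noise spike) falls back
to the minimal three-sample window. The wide stencil matters: one-sample
central differences use only four raw frames regardless of frame rate,
which at realistic noise makes the segment selection latch onto spikes.
Slopes are reported on the laser-normalised intensity scale.

The laser level per frame is the best normalized-cross-correlation match
against a template bank of indicator renderings, ties resolved to the
higher level; scores below 0.2 mark the frame unreadable and its level is
linearly interpolated from readable neighbours. Time to peak is the onset
of the laser plateau: the earliest time at which the laser has already
dropped below its running maximum and does not fall further for more than
1 s (the intraoperative trigger for the intra-cube acquisition). A series
that never stabilises yields "not found" and callers treat the metric as
missing.

## Border localisation

Profiles are sampled by bilinear interpolation at 0.5 px steps from a
proximal origin to a distal endpoint. The inflection estimator smooths the
profile (5-sample moving average), normalises both axes to [0, 1] — hence
exact invariance under affine intensity maps — and builds the chord from
first to last sample. For a falling sigmoid the signed distance to the
chord peaks above it on the proximal shoulder and below it on the distal
shoulder; these two extrema bracket the falling limb. Within the bracket
the inflection is the median crossing of the half-range level between the
two plateau medians (computed outside the bracket), snapped to the sample
grid. For any symmetric sigmoid the half-range crossing is exactly the
inflection abscissa; the construction is our interpretation of a
chord-based geometric method and is validated purely by parameter recovery
on synthetic profiles (noiseless logistic and step edge within one sample;
5 %-of-range noise: median error 1 sample over 100 seeds). Profiles whose
range does not exceed 5× the smoothing-residual noise, or whose chord
distances all vanish (linear profiles), are rejected as degenerate.

Per modality, the three profile inflections are aggregated by the median of
their projections on the mean proximal→distal axis (robust to one bad
profile; degenerate profiles are dropped with a warning). The signed
distance to the clinical marker uses the ruler calibration
(cm = known length / pixel distance); negative is proximal. Modalities are
assumed co-registered through shared annotations; no automatic registration
is attempted.

## Parameter shift and cohort statistics

Parameter shifts are computed on ROI means (matching the ROI-centric
workflow), summarised per perfusion class by median and IQR of the
intra−pre and post−pre differences. The output is deliberately descriptive:
with one acquisition per time point, temporal drift and ICG presence are
confounded, so no test is attached.

The Wilcoxon signed-rank test uses the exact null distribution (dynamic
programming over rank sums) for n ≤ 25 without ties or zeros, and a
tie-corrected normal approximation otherwise; zero differences are dropped
by default (Pratt's policy is available). Retrospective power is computed
for a two-sided paired t-test via the noncentral t distribution with effect
size Δ/σ_d (Δ = 0.5 cm, α = 0.05 defaults); the paired comparison itself is
nonparametric, so a Wilcoxon mode rescales the effective sample size by the
asymptotic relative efficiency 0.955. No multiple-testing correction is
applied (per-comparison α). scipy's noncentral-t CDF underflows to NaN deep
in the opposite tail; that negligible term is replaced by 0.

## Synthetic data

The generator emulates the acquisition protocol it tests against:

- **Cubes**: flat baseline reflectance 0.6 modulated by a falling sigmoid
  along x (the perfusion border; distal floor 0.7), an ICG absorption dip
  modelled as a Gaussian in wavelength (centre 805 nm, σ 25 nm, depth 0.2)
  scaled by a proximal-high concentration map, an extra haemoglobin-band
  dip (560 nm) on the distal side so oxygenation-sensitive ratios also see
  the border, 0.5 % multiplicative Gaussian noise (an integrating HSI
  camera after white/dark calibration), and optional glare discs fixed at
  reflectance 1.5. The Gaussian dip shape is a modelling choice: the
  reconstruction responds to curvature near 805 nm, not to the exact wings.
- **Inflow videos**: ROI fluorescence is background plus a ramp from the
  true onset at the true slope up to a plateau (rise duration 8 s), times a
  laser level that falls linearly during the rise and settles at 0.5; the
  level is quantised to the template bank and rendered into the indicator
  region. Pixel noise is scaled so the ROI-mean curve has sd = plateau/10
  (SNR 10). Test-scale stacks run at 5 Hz, 60 s, 48 × 48 px.
- **Border images**: falling logistic along x with configurable width
  (0 = step edge) and noise in units of the plateau range.
- **Cohorts**: per-case signed distances per modality = true offset +
  Gaussian noise with sd 0.2/√2 cm per modality, so paired differences have
  sd 0.2 cm.

Everything is deterministic under its seed. Default sizes (160 × 120 cubes,
5 Hz videos) keep the full validation suite fast; they are smaller than the
clinical 640 × 480 cubes and ~25 fps videos, which only scales the pixel
counts, not the estimator definitions.

What passing the synthetic suite shows: the implementations agree with
independent brute-force oracles, the estimators recover known parameters at
realistic noise, and the statistics have the advertised size and power.
What it does not show: that the default tissue-index formulas reproduce any
vendor's values, that the reconstruction succeeds on real surgical scenes
(motion, heterogeneous chromophores, uncontrolled glare), or that the
inflow model captures real pharmacokinetics (recirculation, washout, bolus
dispersion are not modelled).

## Known limitations

- The index formulas are placeholders; only the band-ratio engine, not its
  defaults, is meant for real use.
- Co-registration is assumed given; annotation errors propagate directly
  into border distances.
- The inflow model excludes maximum-fluorescence amplitude and washout
  analysis by design.
- T0 on the default smoothed curve carries the bias/cancellation behaviour
  described above; for very clean signals, reduce the window.
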