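# bowelperf

Multimodal quantification of intestinal perfusion from hyperspectral imaging
(HSI) and indocyanine green fluorescence angiography (ICG-FA).

Sufficient blood perfusion at the anastomotic site is a key determinant of
healing after colorectal resection; insufficient perfusion predisposes to
anastomotic leakage. Two intraoperative imaging modalities address this:
ICG-FA shows dynamic blood inflow after an intravenous fluorophore bolus,
while HSI provides static, contact-free tissue parameters (oxygenation,
haemoglobin and water indices) from per-pixel reflectance spectra
(500–995 nm at 5 nm). `bowelperf` implements the quantitative analysis that
links the two: it reconstructs an ICG-mimicking absorption image directly
from hyperspectral cubes acquired while ICG circulates, quantifies the
fluorescence inflow per region of interest, localises the perfusion
transection border in any modality, measures how ICG presence shifts the
HSI tissue indices, and runs the paired cohort statistics. Because no
patient data ships with the package, a first-class synthetic-data module
generates every input with known ground truth, and all validation is
recovery-based.

Intended users: researchers in surgical imaging and biomedical image
analysis who want a reproducible, testable reference implementation of
these methods.

## The core methods

**ICG reconstruction from reflectance.** ICG has its absorption maximum
near 805 nm, so a perfused region imaged during circulation shows a
reflectance dip there. The dip is isolated as positive spectral curvature:

```
recICG(x, y) = (1/5) · Σ_{λi = 790 nm}^{810 nm}  d²R_S(x, y, λi) / dλ²
```

where `R_S` is the spectrally smoothed reflectance (Gaussian, σ = 4.44 band
indices). The curvature map is clipped at zero, median filtered (7 × 7),
normalised to its 99th percentile and clipped to [0, 1].

**Inflow quantification.** Per circular ROI, the mean fluorescence
intensity per video frame is divided by the laser excitation level (read
from the rendered intensity indicator by template matching), smoothed with
a 3 s moving average, and summarised by the background-noise maximum `B`
(3–6 s after administration), the objective time to first fluorescence `T0`
(first time from which the curve stays above `B`), the inflow slope
(ordinary least squares over the segment of highest local slopes, in
normalised units/s), and the time to peak (onset of the laser plateau).
Literature risk thresholds (slope < 2.1 units/s; T0 > 60 s / > 40 s) can be
evaluated against the metrics.

**Border localisation.** The perfusion border is the inflection point of
intensity line profiles drawn proximal → distal across the transition zone,
estimated with a chord-based geometric method robust to profile noise;
three profiles per image are aggregated by their median, and the signed
distance to the surgeon's clinical marker is reported in centimetres
(negative = proximal) via a ruler calibration.

**Statistics.** Shapiro–Wilk normality screening, exact Wilcoxon
signed-rank comparison of paired border distances, Spearman rank
correlation, and retrospective power from the noncentral t distribution
with effect size Δ/σ_d (Δ = 0.5 cm by default).

## Worked example

Generate one complete synthetic case (pre/intra cubes, fluorescence video,
annotations) and run every stage:

```python
from bowelperf.pipeline import CaseBundle, run_case
from bowelperf.synthetic import CaseScenario, simulate_case

simulate_case("demo_case", CaseScenario(seed=5, case_id="demo"))
report = run_case(CaseBundle.from_dir("demo_case"), out_dir="demo_out")
print(report["inflow"][["label", "class", "t0_s", "slope_units_per_s", "ttp_s"]].round(2))
print(report["border"][["modality", "distance_cm"]])
```

prints

```
   label      class  t0_s  slope_units_per_s  ttp_s
proximal   perfused  19.0              24.16   27.6
  border transition  18.8              12.14   27.6
  distal   ischemic  17.2               0.50   27.6

modality  distance_cm
     icg       -0.005
  recicg      -0.025
    sto2      -0.040
```

The generator's ground truth for this case is T0 = 20 s and slope =
25 units/s in the perfused region: the proximal ROI recovers both (the
transition ROI sees roughly half the slope, the ischemic ROI essentially
none, and its slope of 0.5 units/s would trip the < 2.1 units/s risk
threshold). All three modality images — the ICG video, the ICG image
reconstructed from the hyperspectral intra-cube, and the StO2 map — place
the perfusion border within 0.04 cm of the clinical marker, which the
scenario put exactly on the true border.

The same stages are available from the shell via the `perfusion` command
(`perfusion simulate cube`, `perfusion reconstruct`, `perfusion inflow`,
`perfusion border`, `perfusion shift`, `perfusion stats`,
`perfusion run-case`, `perfusion run-cohort`).

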