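# watermbf

Quantification of myocardial blood flow from dynamic oxygen-15-water
cardiac PET, and a simulation framework for how PET–CT attenuation
misalignment biases the two flow estimates the tracer offers.

## The problem

Cardiac PET/CT quantifies myocardial blood flow (MBF) from a 4-minute
dynamic scan after a ¹⁵O-water bolus. Attenuation correction uses a CT
acquired separately, and the two scans are frequently misaligned by
5–20 mm (respiration, body motion). Misalignment corrupts the *amplitude*
of tissue time-activity curves but not their *shape* — which matters
because ¹⁵O-water is unique among perfusion tracers: flow can be estimated
from the tracer's **washout rate** (shape) rather than its **uptake rate**
(amplitude). This package implements the full analysis chain needed to
study that difference quantitatively on synthetic data:

* a digital cardiac phantom with known per-territory kinetics and a
  clinical 20-frame / 240 s dynamic schedule;
* basis-function fitting of the single-tissue-compartment model

  `C(t) = MBF·PTF · C_A(t) ⊗ exp(−(MBF/V_D)·t) + V_A·C_A(t) + V_RV·C_RV(t)`

  with V_D = 0.91 mL/g, yielding washout-based MBF, the perfusable tissue
  fraction PTF, blood/spill-over fractions V_A and V_RV, and the
  uptake-based transmural flow `MBFt = MBF·PTF/(1 − V_A)` (all flows in
  mL·g⁻¹·min⁻¹);
* PTF-image segmentation with the anatomical-tissue-fraction (ATF) rule
  and circumferential LAD/RCA/LCX territory assignment;
* a misalignment model — a multiplicative amplitude-bias field, linear in
  the shift and localised to walls facing the lung-adjacent directions —
  applied over the standard eleven conditions (six directions, 10 and
  20 mm);
* the agreement-statistics battery: relative deviation, Bland–Altman,
  ICC(A,1) for absolute agreement, exact Wilcoxon signed-rank, and
  ischemia reclassification against the clinical thresholds
  (2.3 mL/g/min for MBF, 1.8 for MBFt).

It is intended for physicists and methodologists working on cardiac PET
quantification who need a reproducible, fully synthetic test bed for
attenuation-robustness questions.

## Worked example

`examples/04_misalignment_bias.py` builds a 48³ phantom, quantifies it
once aligned and once under a 20 mm left-lateral misalignment (condition
X+20), and prints:

```
bias field on the wall: factors 0.80 .. 1.00

region   MBF dev %   MBFt dev %
LV           0.00       -7.22
LAD          0.00       -1.30
RCA          0.00       -1.30
LCX          0.00      -16.58
```

The attenuation error removes up to 20% of the signal from the lateral
wall. Washout-based MBF is unchanged — per-voxel amplitude scaling cannot
move the best-fitting washout rate — while uptake-based MBFt drops 17% in
the lateral (LCX) territory facing the shift. The other examples cover
phantom construction, kinetic fitting, segmentation, and the full
11-condition cohort experiment (`examples/05_misalignment_study.py`),
which also reports ICC and diagnosis-change counts.

A thin CLI exposes the same stages (`watermbf simulate | fit | segment |
study | stats`); images travel as NIfTI-1 with a JSON frame-timing
sidecar, curves and tables as CSV.

## Layout

```
src/watermbf/    frames, synth, misalign, kinetics, regions, stats, study, io, cli
examples/        one narrative script per capability
tests/           pytest suite with independent oracles (tests/oracles.py)
docs/methods.md  model, parameters, design choices, limitations
```
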