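# btbquant

Quantification of antibody permeability across the blood-brain barrier
(BBB) and the blood-tumor barrier (BTB), for researchers studying how
well therapeutic antibodies such as trastuzumab reach brain metastases.
The package implements the three quantification arms of a typical
preclinical permeability study — an in-vitro microfluidic barrier chip,
in-vivo brain-section autoradiography with lesion classification, and
whole-body radiotracer biodistribution — together with seeded synthetic
generators that produce all three input families with known ground
truth, so every stage is testable end-to-end without animal or device
data.

## The models

**Chip uptake kinetics.** Fluorescent antibody is perfused through the
outer (vascular) compartment of a microfluidic chip while both
compartments are imaged every 2 min for 90 min. Writing C_PF and C_CC
for the ROI sum intensities of the outer and central compartments, the
unidirectional-uptake law is

    (C_CC + C_PF) / C_PF = k_in · t + O_C

with t the time in minutes from steady-state onset (the device needs a
pre-steady-state delay, 22 min by default, before the outer compartment
concentration is constant). k_in — the unidirectional uptake transfer
constant, in 1/min on the ratio scale — and the intercept O_C are
estimated by ordinary least squares on the trimmed ratio series; the
one-sided t-test on the slope tests whether any transport occurs at
all. Groups of devices (BBB vs BTB vs unrestricted diffusion) are
compared with Welch's t-test and a variance-ratio F-test.

**Lesion permeability classification.** Metastases are segmented from a
tumor-marker channel, measured on a co-registered tracer channel (Texas
Red, or an autoradiograph calibrated to co-exposed activity standards),
and expressed as fold increase of per-area signal over normal brain.
Each lesion is classed as low (fold below "mean brain + 3 SD",
i.e. 1 + 3·CV in fold units), intermediate (up to 2-fold), medium
(2–4 fold), or high (above 4-fold); class summaries, and the correlation
of fold with lesion size, reproduce the standard heterogeneity analysis.

**QAR calibration and biodistribution.** Autoradiograph intensity is
mapped to tissue activity (nCi/g) through a monotone calibration fit —
linear with a fitted film background, or a saturating exponential
approach. Gamma-counter organ tables are converted through
cpm → nCi → nCi/g → %ID/g (percent of injected dose per gram) and
tissue/blood ratios, including the tumor-to-brain accumulation fold.

## Worked example

```python
from btbquant import (ChipSimConfig, simulate_chip_stack,
                      extract_roi_traces, UptakeKinetics,
                      tumor_to_brain_fold)

cfg = ChipSimConfig(true_kin=0.18, noise_sd=40.0, seed=1)   # BBB-scale slope
sim = simulate_chip_stack(cfg)                               # 46 frames, 64x64
trace = extract_roi_traces(sim.stack, sim.mask, sim.times,
                           device_id="bbb-1", model_label="BBB")
print(UptakeKinetics.from_trace(trace, delay=22.0).fit().summary())
print("tumor-to-brain fold:", round(tumor_to_brain_fold(0.46, 0.30), 1))
```

prints

```
Uptake kinetics (OLS on uptake ratio vs steady-state time)
==========================================================
device: bbb-1    model: BBB
n frames used: 35    R^2: 0.9996
k_in  = 0.180807 1/min  (SE 0.000621, 95% CI [0.179544, 0.18207])
O_C   = 1.19233  (SE 0.0245)
P(slope > 0): 3.71e-58
tumor-to-brain fold: 1.5
```

The fitted slope recovers the generator's true 0.18/min within its
standard error from the 35 steady-state frames, the intercept recovers
the configured outer-compartment volume term 1.2, and the one-sided
slope test overwhelmingly rejects "no transport". The final line is the
tumor-over-normal-brain accumulation ratio computed from mean %ID/g
values of 0.46 (tumor-bearing brain) and 0.30 (normal brain): antibody
reaches tumor at 1.5× the level of intact brain — measurable, but far
below the uptake of peripheral organs.

A full seeded run of all three arms, writing CSV tables and a
parameter-recovery log:

```bash
btbquant run-all --seed 1 --outdir run1 --figures
```

Individual stages (`btbquant simulate`, `chip-fit`, `lesion-quant`,
`qar-calibrate`, `biodist`) consume each other's files directly; see
`btbquant --help`.

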