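# Methods

## Chip uptake model

The in-vitro arm models unidirectional tracer movement from a perfused
outer (vascular) compartment into a central (tissue) compartment. With
C_PF and C_CC the ROI *sum* intensities of the two compartments (sum,
not mean — the "sum intensity" convention), the working quantity is the
ratio (C_CC + C_PF)/C_PF, which is ≥ 1 whenever the central compartment
carries non-negative signal and is invariant to any common gain applied
to both ROIs. Under constant outer-compartment concentration (steady
state) and unidirectional uptake the ratio is affine in time:

    ratio(t) = O_C + k_in · t,   t measured from steady-state onset.

`fit_kin` estimates k_in and O_C by ordinary least squares
(statsmodels OLS behind the `UptakeKinetics` model/results pair),
reporting the slope's standard error, R², and a one-sided t-test
p-value for k_in > 0 with n − 2 degrees of freedom. Group contrasts use
Welch's unequal-variance t-test (scipy) and a variance-ratio F-test
with the larger sample variance in the numerator and a two-sided p
obtained by doubling the upper tail — the convention of the common
interactive statistics packages this analysis is usually run in.

Parameters that matter:

- `steady_state_delay` (min, default 22): dead time before the outer
  compartment reaches constant concentration. It is a parameter, not a
  constant, because it is a property of the device and pump rate; an
  optional changepoint estimator (`estimate_steady_state_delay`,
  best-RSS hinge fit over candidate breakpoints) recovers it from data
  when a device differs.
- `frame_interval` / `total_duration` (min, defaults 2 and 90): the
  acquisition cadence; 46 frames at the defaults, 35 of them in the
  steady-state window.
- k_in is reported in 1/min on the ratio scale. Display conventions in
  µL/min/µm² require a chamber-geometry factor that cannot be derived
  from the ratio law alone; `KinEstimate.to_display_units` applies a
  user-supplied factor and no factor is built in.

Degenerate inputs: fewer than 3 frames, or a time axis without
variance, raise; duplicate timestamps are rejected rather than
averaged, to surface acquisition faults. A numerically perfect fit
(residuals at floating-point noise) reports p = 0 for a positive slope,
0.5 for a zero slope, and R² = 1, avoiding 0/0 in the t statistic.

## Lesion analysis

Lesions are segmented on the tumor-marker channel by thresholding
(Otsu by default, overridable) and 4-connected component labelling,
with an optional minimum-area filter; area is pixel count × pixel
area. Manual ROI tracing in the original workflow is replaced by this
deterministic rule because the marker channel is effectively a
segmentation oracle — tumors are the only bright objects in it.

Fold increase is (lesion sum intensity / lesion area) divided by the
same per-area quantity for a normal-brain reference — equivalently a
ratio of mean pixel intensities, hence gain-invariant. The reference is
either explicit `NormalBrainStats` or a labelled reference mask; a
reference that intersects a lesion falls back to a designated
alternate-slice mask and errors if both are tumor-involved.

Permeability classes follow the fold-space reading of
"mean brain + 3×SD": since fold is already normalised by the
normal-brain mean, that threshold is 1 + 3·CV of the reference signal.
Intervals are half-open with the upper class claiming each boundary —
low (0, cutoff), intermediate [cutoff, 2), medium [2, 4),
high [4, ∞) — a documented convention because the verbal rule is
ambiguous at exactly 2- and 4-fold. The classifier is exhaustive and
mutually exclusive over all positive folds by construction; if a
user-supplied cutoff exceeds 2 the intermediate class is empty and
folds below 2 are low. Single-member classes report SD 0 with an
explicit `sd_defined = False` flag so summary tables stay well-formed.

The in-vivo transfer constant uses the single-time-point constant-
plasma approximation k_in = (tissue/blood)/t (mL/sec/g); with ≥ 3 time
points `invivo_kin_patlak` regresses the apparent distribution volume
on time instead, which additionally yields the initial distribution
volume V0.

## QAR calibration and biodistribution

Calibration fits intensity on activity for the co-exposed standards:
linear with fitted intercept by default (phosphor/film backgrounds are
not zero; a forced-zero flag exists), or a saturating exponential
approach offset + I_max(1 − exp(−a/scale)) for screens driven toward
saturation. The fitted map must be monotone over the standards' range
or the fit errors. Inversion is closed-form in both cases; intensities
outside the calibrated range raise unless extrapolation is requested,
and the saturating form refuses intensities at or above its asymptote.

The counting chain is centralised in one units module: 1 nCi = 2220
dpm, a counter efficiency in cpm/nCi, %ID/g = 100·(cpm/efficiency/
weight)/dose. Physical-decay correction for ¹²⁵I (59.4-day half-life)
is available but off by default, matching common practice for a
24-hour circulation window. Counter efficiency and injected dose are
required inputs of the accounting stage — they are facility numbers,
not inferable from the data — and carry defaults only inside the
synthetic generator.

## Synthetic-data generators

The generators exist so that every downstream statistic can be checked
against known truth; they emulate structure, not optics.

**Chip stacks**: the outer ROI holds constant per-pixel intensity; the
central ROI per-pixel value is set so the ROI sums realise the ratio
law exactly (pre-delay ratio equals O_C, slope k_in afterwards);
additive per-pixel Gaussian noise models the detector. Defaults place
the device in the BBB regime: true slope 0.18/min, O_C 1.2, 22-min
delay, 2-min cadence over 90 min, 64×64 frames.

**Section triplets**: lesions are uniform-intensity disks — the
analysis only consumes ROI sums, so internal texture would add nothing
— placed without overlap by rejection sampling (bounded retries, then a
generation error). Each lesion's tracer activity is normal_mean × fold,
fold drawn from a four-group mixture whose per-group means and SDs
default to (1.30, 0.34), (1.88, 0.07), (2.79, 0.61) and (7.40, 4.66)
for low/intermediate/medium/high; draws are truncated normals
restricted to each class's fold interval so the drawn group always
equals the rule-derived class. Group weights default to
(0.45, 0.15, 0.25, 0.15) — a "limited and heterogeneous" profile in
which most metastases are near-impermeable — because per-group counts
are a free choice of the mixture, not a derived quantity. The
autoradiograph channel applies the configured intensity-response map
(linear-with-offset or saturating) to the activity field, so the fold
round-trip genuinely passes through calibration; the Texas Red channel
is proportional to activity with zero offset, so folds are read
directly from intensity there. `normal_sd` is a declared population
parameter consumed by the classification cutoff (default CV 0.1,
cutoff 1.3); it is not rendered as pixel noise, which keeps the
zero-noise round trip exact.

**Biodistribution tables**: the %ID/g chain run backwards, with
multiplicative log-normal count noise (mean-one parameterisation).
Default organ profile: spleen 5.04, lungs 4.45, liver 3.54, kidney
3.12, heart 3.08, normal brain 0.30, tumor brain 0.46 %ID/g, a typical
radio-iodinated antibody distribution at 24 h; injected dose 10⁵ nCi,
counter efficiency 1665 cpm/nCi (75% of 2220 dpm/nCi), blood at
15 %ID/g — realistic facility numbers chosen once, since they are
inputs rather than outputs of the method. Mouse-scale organ weights
keep the zero-noise whole-body recovery below 100% of dose.

Noise models are stated choices (Gaussian additive on images,
log-normal on counts), the simplest forms that support parameter-
recovery testing; they make no claim about the original instruments.
What passing tests show is that the analysis chain inverts its own
forward models exactly and remains stable under moderate noise — not
that it handles optical artefacts, registration error, partial-volume
effects or non-uniform illumination, none of which are simulated.

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng(seed)`;
  identical configs are bit-identical, and the orchestrated run writes
  a log with seed, config hash and per-stage recovery deltas.
- The 95% CI coverage property for k_in is asserted under iid Gaussian
  noise on the ratio series — the regime in which the OLS interval is
  exact (empirically ≈ 96–97% over 500 replicates). Pixel-level image
  noise induces ratio noise whose SD grows with the accumulated signal;
  under that heteroscedasticity the plain-OLS interval is mildly
  anticonservative (empirically ≈ 92%). This is a known limitation of
  the plain-OLS convention the analysis follows, flagged rather than
  silently patched with robust errors.
- Monte-Carlo tests run at reduced problem sizes (16×16 chip frames,
  a few hundred replicates, 60–100 resampling draws), sizes at which
  the asserted tolerances are already decisive.
- A printed in-vivo normal-brain transfer constant on the order of
  10⁷ mL/sec/g is dimensionally implausible for brain uptake and is
  used nowhere as a default or target.
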