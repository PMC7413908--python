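# Methods

This note records the measurement model behind the simulator, the
statistical conventions behind the validation metrics, and the design
choices made where more than one defensible reading existed.

## Measurement model

A *sample* is a reconstituted SPE extract injected onto a chiral SFC
column with targeted MS/MS detection; each analyte channel (one MRM
transition, or one enantiomer of a chiral analyte) produces one peak.
The simulator composes three physically distinct effects:

1. **Extraction recovery** r ∈ [0, 1.6] acts on the *amount* of a compound
   reaching the final vial, and therefore only on material present before
   extraction (pre-extraction spikes, matrix background, the
   internal-standard spike). Values above 1 model apparent
   over-recovery.
2. **Signal suppression** SS (%) acts multiplicatively on the *instrument
   response* of whatever is in the vial, whether it was extracted or
   spiked post-extraction. Negative SS is enhancement.
3. **The concentration factor** CF maps sample concentration to vial
   concentration. The default workflow extracts 50 mL of water and
   reconstitutes in 0.5 mL, CF = 100.

The expected peak area of a channel is
`response_factor × vial_concentration × (1 − SS/100)`. This separation
reproduces the two classical experiment designs: post-extraction spikes
isolate SS (recovery cancels), pre-extraction spikes confound
recovery × response and are disentangled by the mobile-phase QC and the
calibration curve.

Internal standards are spiked at 1 µg/L into every 50-mL sample (50 ng)
before extraction and at 100 µg/L into every calibrant vial. With full IS
recovery these coincide after SPE (1 µg/L × 100 = 100 µg/L), which is what
makes a single calibration curve serve both mobile-phase standards and
matrix extracts.

### Peak shape and trace rendering

Peaks are pure Gaussians (SD `peak_sigma`, default 0.02 min — ≈ 6-s base
widths typical of sub-2-µm chiral SFC); no tailing model is included
because none of the downstream statistics depends on asymmetry, and an
exponentially-modified Gaussian would add a parameter the validation
pipeline cannot identify. Rendered traces add white baseline noise
N(0, `noise_sd`); the base width at the 5%-height boundary of a Gaussian
is 2σ√(2 ln 20) ≈ 4.895σ, the closed form used as an oracle in the tests.

### Noise model

Peak-table noise is mean-one log-normal, parameterised by CV, in two
components:

- a **shared per-injection factor** (`injection_cv`) multiplying every
  peak of a sample — injection-volume and source variability. This is the
  component internal-standard normalisation exists to cancel, and
  omitting it would make IS normalisation *increase* response-ratio
  noise, inverting the method's logic.
- an **independent per-peak residual** (`area_cv`) — integration and
  detector noise that survives normalisation.

The pipeline default is injection CV 4.6% + residual 2% ≈ 5% total area
CV; `emit_peak_table` itself defaults to independent noise only, so the
CV of raw areas equals the parameter given. Rendered traces instead carry
additive baseline noise, which produces the S/N-limited behaviour at the
bottom of the calibration.

### What the simulator does not emulate

Retention-time drift, peak tailing and co-elution, carry-over,
heteroscedastic detector saturation at the top of the range,
between-batch drift, and real matrix chemistry (it applies fixed
per-compound recovery/suppression/background numbers). Passing tests
therefore demonstrate that the *computations* are correct under the
stated measurement model, not that any instrument will achieve these
figures.

## Calibration and quantification

Curves regress the response ratio (analyte area / assigned IS area) on
vial concentration, replicate-level points, blank excluded. The library
default is unweighted ordinary least squares; the pipeline fits
**1/x-weighted** curves. Over a range spanning five orders of magnitude
(0.005–1000 µg/L) the unweighted intercept is determined by the top
levels and wanders on a scale (∼µg/L in the vial) that swamps the lowest
matrix spikes (0.05 µg/L × CF × recovery ≈ 2 µg/L in the vial), so the
low end cannot quantify without weighting. R² is always the squared
Pearson correlation of observed and fitted ratios. Linearity classes:
R² > 0.997 full; 0.990 ≤ R² ≤ 0.997 semi (the boundary value is semi,
matching the strict inequality for full); below 0.990 fail.

Back-calculated concentrations below zero are censored to 0 and flagged;
values outside the fitted range are returned with an out-of-range flag.

Instrument limits use the S/N rule only (no calibration-slope/σ
formulas): iLOD and iLOQ are the lowest calibrant levels whose mean S/N
over replicate injections reaches 3 and 10. S/N is baseline-corrected
apex height over the robust baseline SD (1.4826 × MAD); the convention
matters because any S/N-gated result is convention-dependent, so it is
fixed and documented here. A 3σ apex threshold admits occasional noise
maxima by construction (~1 per ~700 baseline points); callers screening
noisy traces should raise the multiplier.

## Validation statistics

Sample standard deviations use the n−1 denominator throughout (triplicate
bioanalytical convention). Accuracy is nominal/mean × 100, so values
above 100% indicate under-reading. Signal suppression is computed as the
exact floating-point complement of absolute recovery (both share the
blank-corrected area ratio), making SS + recovery ≡ 100 identically.

**Recovery correction.** Relative recovery is measured from
IS-corrected, *uncorrected-for-recovery* concentrations — it is the
quantity being estimated. Method accuracy, method precision and
environmental concentrations are then computed from concentrations
divided by Rec_average/100 (and CF). This is the same correction
structure as the method-limit formula mLOD = iLOD·100/(Rec·CF), and it is
what makes method accuracy a check of the *corrected* reported value:
a compound with reproducible 58% recovery still reports ≈ 100% method
accuracy, as a practitioner would expect from a recovery-corrected
result. Rec_average aggregates the spike levels by unweighted mean; its
SD is the across-level SD of level means. Negative blank-subtracted means
yield flagged undefined (NaN) accuracy, never sign-flipped percentages.

## Chiral metrics and censoring

E1/E2 are positional labels by elution order; the package never assigns
absolute configuration. EF is computed from quantified concentrations
when a calibration exists (enantiomers can differ in recovery and
suppression in matrix); raw-area EF is used for mobile-phase standards.
Censoring: an enantiomer below the quantification limit contributes 0 to
the EF denominator, so one-sided detections give EF 1.0/0.0 with a flag
and doubly-censored pairs are undefined ("–"). Rs requires both peaks
*detected* but not necessarily quantifiable, so a pair can report Rs
while EF is censored. Coincident apexes (unresolved pair) are legal and
give Rs = 0.

## Internal-standard assignment

Priority: (1) the analyte's own deuterated analog; (2) the IS with t_rel
closest to 1, with candidates within 0.01 of the best treated as tied and
ranked by mean |SS_analyte − SS_IS| over the available matrices; (3)
lexicographic IS name. Both the 0.01 tolerance and the pooling of
matrices for the SS distance are config knobs, chosen because a priority
order without tolerances is not computable on continuous inputs. The
mapping is total, deterministic and independent of input order. When a
chiral analyte is assigned a chiral IS, enantiomer channels pair E1–E1 /
E2–E2; a chiral IS normalising an achiral analyte contributes the sum of
its enantiomer areas.

## Classification

Thresholds (all config knobs, percent scale): accuracy band 80–120,
precision limit 20% RSD, recovery band 80–120 with SD limit 20, recovery
hard band 40–160. Fully quantitative requires full linearity, all
accuracies in band, all precisions under the limit, and recovery either
in band or reproducibly out of band (SD < 20) inside the hard band —
the latter keeps compounds like a reproducible 58%-recovery analyte
quantitative. Any tolerated relaxation (semi linearity, an accuracy band
violation, a precision exceedance, an irreproducible out-of-band
recovery) gives semi-quantitative; undefined required metrics, failed
linearity or recovery outside the hard band give qualitative. The
decision is monotone: improving any one metric never demotes. The hard
band is the one genuinely open choice — "extreme" recovery is not a
sharp concept — and it is exposed in `ClassificationRules` so alternative
readings are expressible in configuration.

## Environmental reporting

Per matrix, concentrations are averaged over all replicate injections of
all samples (the default design, 2 samples × 3 injections, gives n = 6);
means below the compound's mLOQ are rendered "<LOQ", numeric means are
reported in ng/L with %RSD, and compounds without a defined mLOQ are
reported qualitative-only. Chiral analytes carry EF and Rs columns with
the censoring rules above.

## Problem sizes and numerical choices

The test suite and the acceptance script run the campaign on a 3-analyte
panel (one chiral → 4 channels) with the full calibrant series in
triplicate, QCs on 2 days, and spikes at {0, 0.05, 0.5, 2} µg/L in
triplicate — the smallest design that exercises every code path
(multi-day precision, chiral pairing, censoring, recovery correction)
while leaving the statistics interpretable; Monte-Carlo checks use
10³–10⁴ draws. Degenerate inputs are contracts, not crashes: empty peak
lists are valid (no detections), missing metrics demote a compound's
status rather than raising, and zero baseline noise propagates as
infinite S/N ("above any threshold"). Floating-point ties at
classification boundaries follow the stated inequalities exactly
(R² = 0.997 is semi; S/N = 3.0 detects).
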