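# Methods

`hemovalid` implements the statistical validation of a continuous
non-invasive hemodynamic monitor against invasive references (arterial line
for SBP/DBP/HR, pulmonary-artery thermodilution for CO), in the setting of a
three-phase controlled hemorrhagic-shock experiment in swine. The pipeline is

    ingest / simulate  →  outlier screening  →  static agreement  →  trending

with every stage exposed both as plain functions and through model/results
objects (`AgreementAnalysis().fit() → AgreementResults`, etc.).

## Data model

One observation is a timestamped pair (reference value, device value) for one
animal, one variable ∈ {SBP, DBP, HR, CO} and one protocol phase ∈
{pre_bleeding, bleeding, post_bleeding}. Values are strictly positive and
finite; times are minutes since protocol start; phases must be
non-overlapping in time within an animal. Phase is an explicit column rather
than inferred from time because phase boundaries differ per animal (bleeding
lasts 20–60 min). CSV round-trips are exact: writes use shortest-repr float
serialization and reads use round-trip float parsing.

## Outlier screening

The screen targets single-point artifacts in the invasively measured series
(catheter flushes, mis-timed thermodilution runs). For each interior point
`x_i` of an animal × variable series the two signed percentage differences

    Δ⁻ᵢ = 100·(xᵢ − xᵢ₋₁)/xᵢ₋₁     Δ⁺ᵢ = 100·(xᵢ − xᵢ₊₁)/xᵢ₊₁

are computed on the reference channel. Per variable, pooled across animals,
the SD of all these signed differences defines a band ±k·SD (k = 2 by
default); a point is eliminated iff **both** |Δ⁻| and |Δ⁺| exceed the band.
A genuine spike sticks out against both neighbours; a step change or steady
decline does not, so trends survive. Screening is single-pass, endpoints are
never removed, and the paired device value is removed together with the
reference value so downstream pairs stay aligned.

Design choice: the band is computed from the *signed* differences, not their
absolute values. For noise-like series the signed differences are roughly
mean-zero Gaussian, so ±2·SD excludes ≈ 5% per side and the conjunctive
two-sided rule removes well under 1% of points — the regime a screen that
reportedly discarded < 0.5% of points must operate in. An absolute-value SD
is systematically smaller (≈ 0.6σ for half-normal data), which would push
~10% of ordinary noise points over the threshold and turn the screen into a
mass filter. On the default simulated cohort the realised removal fraction
is ≈ 0.4%.

## Static agreement

Per variable and stratum (each phase, plus all phases pooled; pairs pooled
across animals):

- **Pearson r** and the device-on-reference OLS line with two-sided tests of
  slope = 0 and intercept = 0 (scipy / statsmodels).
- **ICC(A,1)** — two-way random effects, absolute agreement, single
  measurement — from the two-way ANOVA mean squares with n pairs × k = 2
  methods:

      ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

  Absolute agreement penalises systematic offsets (the MSC term), which is
  the right notion for asking whether the device can replace the reference.
  Negative estimates are clamped to 0 and flagged. The **standard error of
  measurement** SEM = pooled SD of all 2n measurements × √(1 − ICC) gives
  the unit-carrying companion of ICC.
- **Bland–Altman**: differences d = device − reference, bias = mean(d),
  SD with n−1 denominator, 95% limits of agreement bias ± 1.96·SD. The
  z-multiplier 1.96 (not a t quantile) is the standard convention and the
  strata here are large.
- **Percentage error** (CO only): 100·1.96·SD(d)/mean(reference CO);
  ≤ 30% is the conventional acceptability bound for CO monitors. Invariant
  under common unit rescaling.
- **BP error bins**: share of pairs within ±5/±10/±15 mmHg (inclusive
  boundaries), the binning used by cuff-device validation protocols.
- **Normality** of the differences via Shapiro–Wilk and the
  Lilliefors-corrected Kolmogorov–Smirnov test (the KS variant statistics
  packages apply when mean and SD are estimated). Reported, never used as a
  gate; constant differences are flagged degenerate instead of producing
  spurious p-values.

No within-animal clustering adjustment is applied to the pooled strata; this
matches how such validation studies conventionally report pooled N, and is a
known limitation (repeated-measures LOA would widen the limits somewhat).

## Trending (four-quadrant concordance)

For each animal's series the change between every pair of consecutive
surviving observations is computed on both channels over the same interval;
changes chain across phase boundaries, and after screening intervals may be
unequal. Pairs inside the central exclusion square (|Δref| ≤ zone AND
|Δdev| ≤ zone, inclusive; zone = 2 mmHg for the pressures, 0.5 l/min for CO)
carry no directional information and are excluded. Among retained pairs a
pair is concordant iff the two changes have the same strict sign — axes
belong to no quadrant, so a zero change is never concordant but stays in the
denominator. Concordance rate = 100·concordant/retained (a switch restores
the literal all-points denominator); the Pearson correlation of the retained
change pairs is reported alongside. The panel covers SBP, DBP and CO;
heart-rate trending is not part of the standard four-quadrant panel.

## Synthetic cohort generator

The generator exists so the full pipeline can be exercised and calibrated
without access to animal data. It emulates the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_animals | 11 | cohort size |
| pre_bleeding | 25–35 min, 5-min cadence | baseline |
| bleeding | 20–60 min, 5-min cadence | controlled 35% blood-volume withdrawal |
| post_bleeding | 420 min, 20-min cadence | untreated follow-up |
| phase level_mean/level_sd | SBP 79±14 / 51±20 / 58±12; DBP 57±18 / 32±12 / 30±18; HR 96±20 / 99±20 / 125±25; CO 3.8±1.0 / 2.4±1.1 / 2.2±0.5 | reference-channel marginal targets per phase |
| map_floor | 30 mmHg | bleeding rate-control floor on MAP = (SBP+2·DBP)/3 |
| dropout_prob | 0.18 | ≈ 2/11 animals die early in follow-up (uniform death time) |
| co_missing_prob | 0.18 | CO thinning during/after bleeding (thermodilution logistics) |
| spike_prob / spike_magnitude | 0.004 / 0.5 | rare +50% single-point artifacts, either channel |
| calibration_offset_sd | 4 / 4 / 2 / 0.4 (SBP/DBP/HR/CO) | one-time per-animal device calibration offset |
| noise_sd | 5 / 5 / 3 / 0.35 | AR(1) device observation noise, ρ = 0.3 |

Reference trajectories are latent per-animal paths: a phase-mean curve, plus
a persistent animal level, plus a smooth AR(1) path (ρ = 0.6), with the
marginal variance per phase split evenly between the animal level and the
path after subtracting the phase-mean curve's own time-variance. The
bleeding curve declines (cosine-eased) over the first 40% of the phase to a
trough and then holds — emulating rapid withdrawal followed by pauses to
respect the MAP floor — with the trough solved so the phase time-average
equals the configured bleeding mean. Post-bleeding drifts over the first 30%
of the phase toward a level solved the same way (HR rises, pressures and CO
stay depressed). DBP is a phase-specific fraction of SBP (fraction =
μ_DBP/μ_SBP) plus independent variation sized to hit the DBP marginal SD,
so MAP is well defined; bleeding rows whose MAP falls below the floor have
both pressures scaled up onto it, as the rate-controlled protocol would.
The device channel is reference·(1+slope) + per-animal offset + AR(1) noise;
with all error parameters zero the device equals the reference bit-for-bit,
which downstream must (and does) turn into exactly perfect statistics.

A single root seed drives one `SeedSequence`; per-animal substreams are
spawned deterministically, so cohorts are reproducible and per-animal output
is stable under config edits.

Where the MAP floor binds, realised bleeding BP means sit slightly above the
configured targets; HR and CO are unconstrained. Hand-built test fixtures
(`make_fixture`) are < 200-row deterministic datasets — smooth eased paths
with a small bounded oscillation — with known ground truth: identity device,
+4 mmHg BP offset, known-SD noise, or +50% reference spikes at recorded
points.

What the generator does **not** emulate: PPG waveforms and the device's
internal pulse-wave algorithm, drug/anesthesia effects, resuscitation,
blood-volume bookkeeping, circadian structure, or any mechanistic link
between CO missingness and clinical state (thinning is independent). Passing
tests therefore demonstrate that the *statistics* are computed correctly and
recover known truth under realistic marginal levels, autocorrelation and
artifact structure — not that the device itself is valid on real animals.

One consequence of following the phase-level CO targets: the pooled CO mean
is ≈ 2.6 l/min, so a device error of SD ≈ 0.5 l/min — clinically modest in
absolute terms — yields a percentage error near 45–50%, and the CO
acceptability flag fails on the default cohort. The percentage error divides
by the mean reference CO, so the same absolute error passes at a normal CO
of 4 l/min and fails in a deeply shocked cohort; the flag is reported as
computed.

## Numerical choices

- Reference values are floored at physiological minima (SBP 15, DBP 5,
  HR 25 mmHg/bpm, CO 0.3 l/min) and device values at 10⁻³ so extreme noise
  draws cannot violate positivity; the floors essentially never bind at
  default parameters.
- MAP-floor scaling multiplies by (1 + 10⁻¹²) so rounding cannot leave MAP
  an ulp below the floor.
- Zone and error-bin boundaries are inclusive; quadrant membership uses
  strict signs.
- Thresholds with zero SD (constant series) remove nothing (strict `>`).
- All-excluded trending strata and zero-variance inputs return flagged
  results or raise `DegenerateInputError` rather than NaN-poisoning reports.
- Reports serialize to JSON with sorted keys; identical seeds give
  byte-identical reports.

## Problem sizes used in the test suite

Unit and property tests run on the < 200-row fixtures and on single default
cohorts (11 animals, ≈ 1 400 paired observations). Parameter-recovery checks
use 2 000–20 000 simulated pairs/changes, sized so Monte-Carlo error is a
small fraction of the asserted tolerance. The generator-calibration check
pools 10 independent cohorts (110 animals) and compares the pooled baseline
SBP mean/SD to the configured 79/14 within twice the animal-level bootstrap
standard error — a single 11-animal cohort mean has a cluster SE of ≈ 3 mmHg,
so pooling tests the same property with the sampling noise reduced below the
tolerance. The whole suite runs in well under a minute.

## Known limitations

- No repeated-measures (clustered) Bland–Altman correction and no
  confidence intervals on ICC; strata pool animals.
- The screen is exactly the two-sided percentage-difference rule; it is not
  a general artifact detector (no Hampel/median filtering) and will miss
  multi-point artifacts.
- The trending exclusion region is the central square; polar-plot trending
  analysis is out of scope.
- Simulator realism is limited to marginal phase structure, within-series
  autocorrelation, paired device error and simple artifact/censoring
  mechanisms.
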