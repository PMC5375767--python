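# Methods

## Signal model and pipeline

The detector operates on the vector magnitude of 3-axis wrist acceleration
(the ACM series), assumed uniformly sampled at 100 Hz within ±8 g. Each
analysis window holds N = 100 samples (1 s), tapered with a symmetric
Hamming window `0.54 − 0.46·cos(2πn/(N−1))`, advanced by 50 samples (50%
overlap), so scores are emitted every 0.5 s. With N equal to the sample
rate the DFT bins fall exactly on integer frequencies; bins 0…50 Hz are
kept, including DC and the Nyquist bin. Windows are stamped at their start
time (0-based, half-open spans) and a trailing stretch shorter than one
window is discarded so that all spectra are comparable.

Spectra enter all downstream sums as magnitudes `|X[ω]|` by default. The
underlying quantity is described ambiguously in the field as "spectral
power", so `spectrum_mode="power"` (squared magnitude) is available and the
whole pipeline — templates, GDF, SCR — is well defined under either choice;
the invariant suite passes under both. DC is included in all sums by
default (`exclude_dc` exists): gravity puts ~1 g at DC, which drags the
ictal-to-interictal DC ratio toward 1 and makes quiet wear score near
GDF[0] < 1, comfortably below any calibrated threshold.

Templates are unit-sum by construction: the per-seizure template averages
the ictal windows' spectra and divides by the grand sum; the ictal template
is the unweighted mean over per-seizure templates (equal weight regardless
of seizure duration); the interictal template pools all windows of all
training recordings that do not intersect any seizure interval — including
rest — with boundary-straddling windows excluded from both classes to avoid
label contamination. The GDF divides the two templates bin-wise with both
numerator and denominator floored at `eps_floor = 1e-12` (relative to
unit-sum templates): no infinities, strictly positive weights, and a
template divided by itself is exactly 1 everywhere, including bins that are
zero on both sides.

The SCR of a window is the GDF-weighted average of its spectrum,
normalized by the spectrum's total — a convex combination of GDF weights,
bounded by the smallest and largest weight and exactly invariant to
positive amplitude scaling. All-zero windows score 0 by convention.
Detection uses the trailing (causal) mean of 10 SCRs — causal because an
alerting device cannot look ahead — emitted once the 5-s buffer fills, and
a strictly-greater threshold comparison. The temporal baseline is the
population standard deviation (divisor N) over 500-sample windows hopped by
50 samples; the hop is chosen so both methods share one score clock, one
event detector and one evaluator. Supra-threshold runs separated by at most
`merge_gap_s = 30 s` merge into one event, so a single clinical event with
brief sub-threshold dips is counted once.

## Evaluation protocol

Matching is event-level: a seizure counts as detected if any event overlaps
its interval; an event overlapping no seizure is one false positive.
Sensitivity = detected/total seizures; FPR = false positives × 24/recorded
hours; PPV = true detections/all detections. Specificity needs negatives,
so non-seizure time is tiled into 5-s epochs (the decision cadence); an
epoch overlapping a false detection counts against specificity. Printed
tables truncate FPR to one decimal and round percentages half-up to
integers — the combination that reproduces the published mean-row
presentation (e.g. a fold FPR of 1.95 prints as 1.9 while a mean PPV of
60.9 prints as 61); full-precision values are always carried alongside.

Cross-validation is leave-one-fold-out over explicitly given fold
boundaries (no random splitting): per fold, the GDF is rebuilt from the
k−1 training folds and the threshold is calibrated on training data only as
the minimum over training seizures of the maximum smoothed score inside the
seizure interval, shaved by a relative margin of 1e-6 — the largest
threshold that keeps 100% training sensitivity, hence the most
false-positive-rejecting one. Both detectors run the identical protocol on
identical folds, so the comparison is paired by construction.

A consequence worth stating plainly: with continuously distributed scores
this threshold rule cannot reach 100% *test* sensitivity. Among k folds,
exactly one holds the globally weakest seizure (lowest in-ictal peak
score); when that fold is held out, the threshold — pinned to the minimum
of the other k−1 peaks — sits above the test seizure's peak, and a 1e-6
margin is orders of magnitude smaller than the natural seizure-to-seizure
spread of peak scores (~percents). On the synthetic benchmark both methods
therefore plateau at 90% (9/10) at every seed examined, while the false-
positive ordering (spectral ≪ temporal) is robust. Reaching 100% in
practice requires threshold slack beyond perfect training sensitivity,
which the protocol deliberately does not take.

## The synthetic cohort

The simulator emulates the statistical contrast the method exploits, not
limb biomechanics. Defaults (the benchmark's study conditions):

| parameter | default | rationale |
|---|---|---|
| fold duration | 1.5 h | desk-scale fold length retaining ≥1 h interictal context |
| folds (k) | 10, one GTCS each | one-seizure-per-fold cross-validation design |
| seizure duration | U(89, 256) s | observed clinical GTCS duration range |
| clonic sweep | 9 → 4 Hz linear, 2nd harmonic 0.3 | declining jerk rate; broadband 4–25 Hz signature |
| seizure amplitude | 2 g, enveloped, ±30% slow jitter | vigorous but not range-limited wrist motion |
| interictal motion | 0.3 g low-pass noise, dominant < 0.8 Hz, weaker < 4 Hz | normal movement concentrates below 0.8 Hz |
| distractors | 2/h daytime, 1–3 Hz, 3 g, 8–20 s | rhythmic daily activity (brushing, shaking) that out-amplitudes seizures |
| activity profile | 24 hourly multipliers, 0.15 night / 1.0 day | daytime concentration of movement and false alarms |
| sensor noise | 0.005 g white, per axis | consumer MEMS accelerometer noise floor |

Gravity sits on the z axis with slow orientation drift; every bout and
seizure projects onto a random 3-D unit vector; samples are clipped to ±8 g
with a warning if ever exceeded. All randomness flows from one integer seed
through one `numpy` generator — identical configurations are bit-identical;
cohort folds derive child seeds and cycle day/night start clocks.

What passing tests on this cohort do show: the template/GDF/SCR machinery
recovers the designed band contrast, amplitude-invariance rejects
high-amplitude low-frequency activity that defeats the standard-deviation
baseline, and the full protocol's ordering (equal sensitivity, far lower
spectral FPR) emerges end-to-end. What they do not show: performance on
real patients — real interictal life is far richer (transients, sensor
detachment, seizure-like voluntary movement with 4–25 Hz content), real
GTCS morphology varies more than a jittered chirp, and the clean band
separation here is by construction.

## Numerical and design choices

* Hamming coefficients use the symmetric 0.54/0.46 form; rectangular taper
  available for analytic tests.
* `eps_floor` applies to both GDF numerator and denominator (identity
  property exact; empty interictal bins give finite, large weights).
* Score/threshold comparisons are strictly greater-than.
* Degenerate inputs: empty recordings are valid (0 windows); traces shorter
  than the smoothing length yield empty smoothed traces; zero-detection
  folds report PPV 0 with a warning; a fold with no seizures reports
  sensitivity as not-applicable and is excluded from the mean.
* Threshold calibration errors out, naming the recording, if a training
  seizure contains no scores.
* The evaluation consumes explicit fold manifests; it never splits data
  itself.
* The statsmodels-style `SeizureDetector`/`SeizureDetectorResults` pair is
  the primary library surface; the functional modules it wraps are public
  and individually tested, and the click CLI wraps both.

## Known limitations

* Inputs must already be at the configured sample rate; no resampling.
* The GDF is population-level; no per-patient personalization or online
  template updating.
* Only the clonic-phase oscillation is simulated (no tonic stiffening
  phase), and distractors are pure enveloped sinusoids.
* Specificity depends on the epoch convention (5 s default); other epoch
  lengths change its absolute value though rarely its ordering.
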