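# Methods

This note records the models, conventions and numerical choices behind
`pumpguard`, the assumptions the synthetic generator makes, and what passing
tests do and do not establish about real pump logs.

## Data model and formats

Vendor log exports are proprietary, so the package defines an open CSV dialect
(UTF-8, header row, ISO-8601 local timestamps at one-second resolution) plus a
column-map config through which other delimited dialects can be adapted. A
single facility's fleet shares one clock, so no time-zone arithmetic is done;
all latencies are whole-second differences of log timestamps. Unparseable rows
are quarantined with a reason and the conservation law *parsed + quarantined =
input rows* is enforced; quarantine is never silent deletion. Formularies cap
the core medication name and the therapy line at 20 characters each, matching
the pump display field; TALLman spellings are stored verbatim and only removed
by normalisation at comparison time.

## Pairing and classification

Events sharing a sequence id on one device+module form an alert sequence; the
terminal event fixes the outcome (override, reprogram, cancel, start,
unresolved). Each cancelled sequence is paired with the next sequence on the
same device whose first event falls within the pairing window.

* **Window, 120 s default.** Observed correction latencies reach 113 s
  (medication corrections) and 116 s (dose corrections); 120 s covers both
  with margin while staying far below unrelated-program inter-arrival times.
* **Cross-module pairing.** The replacement is searched device-wide, with the
  same module preferred on ties. This is required: a wrong-channel error —
  a PCA medication initially loaded in a syringe driver — is only observable
  when the corrected program appears on a *different* module of the same
  device.
* **Decision-time convention.** "Error recognition to cancellation and
  correction" admits two readings; the package defaults to
  cancel-to-correct (replacement confirmation − cancellation), because those
  are the two unambiguous log anchors, and exposes select-to-cancel as an
  option. Pairs missing an endpoint are excluded from statistics, not imputed.
* **Cause ladder.** First match wins: (1) concentration-limit alert in the
  cancelled sequence; (2) replacement is a drug-calculator start; (3) same
  medication, PCA↔syringe module swap; (4) different medication name;
  (5) same name, dose or concentration differing beyond unit-normalised
  equality at relative tolerance 1e-6 (so float formatting can never
  fabricate a dose error); (6) indeterminate. Concentration breaches are
  tested first because the pump flags them with a dedicated alert and they
  surface under reprogram-limit (hard) alerts — they must not leak into the
  dose-error category, and their share of cancellations is reported as N/A
  with the cancellation denominator excluding them.
* **Dose-error factors.** Cancelled over corrected dose after unit conversion
  (mass, activity, molar and volume bases; per-kg and per-time denominators
  must match). Factors below 1 (potential underdoses) are retained and
  summarised separately; headline summaries use the overdose convention
  "times the corrected dose". Incompatible units yield no factor and a flag.

## Percentages

Every percentage is an exact round-half-up quotient at two decimals computed
through a single code path, and is always emitted beside its numerator and
denominator. Published tables of this kind contain mixed truncation/rounding
(e.g. printed 15.37 and 13.81 where exact division gives 15.38 and 13.82,
74.29 vs exact 74.28, and one quotient printed both as 8.80 and 8.81); the
package always emits the exact value and leaves the printed variants to
documentation rather than silently matching them.

## Divergence-position classification

No formal rule for judging the "key letter position" of a confused name pair
exists, so the package defines one and calibrates it on the ten published
exemplar pairs of cancelled/corrected infusion names. Names are case-folded
(removing TALLman capitals) and whitespace-collapsed; therapy suffixes remain
part of the compared string, as they are part of the pump display. With *i*
the first divergent character index and the *shorter* normalised name as the
denominator — the shorter name bounds the region a reader must scan before the
names can disagree — the fraction f = i/|shorter| classifies as BEGINNING
(f < 1/3), MIDDLE (1/3 ≤ f < 3/5) or END (f ≥ 3/5). The half-open boundaries
are exhaustive and mutually exclusive, and the rule is symmetric in its
arguments.

This rule reproduces 8 of the 10 printed exemplar labels. The two discordant
pairs ("Sodium bicarbonate"→"Sodium phosphate", printed END, computed MIDDLE;
"Acetylcysteine"→"Acyclovir", printed MIDDLE, computed BEGINNING) resist any
simple positional rule we tried; the printed labels there plausibly reflect
human judgement of the discriminating *syllable*. They are fixture-tested at
their computed class. The plain thirds boundary (END at f ≥ 2/3) with the
longer-name denominator reproduces only 5 of 10 and was rejected. A
WORD_TOKEN mode (position of the first differing whitespace token) is exposed
as the plausible alternative reading.

Edit distances for confusability screening come from `edlib`; ranking is by
ascending normalised edit distance, ties broken by descending common-prefix
length, then lexicographically, making the screen fully deterministic.

## Synthetic generator

The generator emulates the statistical structure a 12-month review of a large
facility's fleet exhibits, and its defaults *are* those study conditions:

| parameter | default | basis |
|---|---|---|
| compliance | 74.2849% | 1,050,531/1,414,191 library starts |
| alerts per library start | 0.2768 | 290,807 alerts / 1,050,531 starts |
| alert mix (hard/soft/cancel/other) | .1382/.4865/.1538/.2216 | printed alert-type counts |
| cause mix (6 causes) | counts 10,017/8,533/26,144/17/10/603 | printed cancellation-cause counts |
| position mix (beg/mid/end) | .6979/.2140/.0881 | printed position counts |
| medication-correction time | mean 27.00 s, SD 22.25, on [4, 113] | printed moments and range |
| dose-correction time | mean 26.52 s, SD 24.71, on [6, 116] | printed moments and range |
| dose-error factor | log-normal median 1.5, σ=1, 11 extremes on [101, 500] | printed median, >100× count, maximum |
| basic vs calculator bypass | 95/5 | not reported; calculator mode is the rarer bypass |

Modelling decisions:

* **Decision times** are truncated log-normals matched *by moments* (root
  solve on the truncated mean/SD equations) — positive, right-skewed, median
  below the mean as observed. Draws use inverse-CDF sampling restricted to
  the truncation interval, so bounds hold by construction; the generator
  rounds to whole seconds when placing timestamps and records the rounded
  latency in the truth table. For the dose-correction parameters the moment
  match converges to an extreme-parameter solution whose median (~16 s)
  undershoots the observed 19 s; mean and SD are exact, and the median is not
  a configured target.
* **Dose factors**: the observed mean (14.52, SD 57.89) is driven by ≤500×
  outliers that a parametric tail would reproduce only in expectation, so the
  extreme tail is planted explicitly — exactly `extreme_outlier_count`
  factors drawn log-uniformly from [101, 500] — while the body is log-normal
  around median 1.5, resampled to stay ≤50 and at least 0.01 away from 1 so
  no body draw crosses the extreme threshold or degenerates into an
  undetectable zero-delta reprogram.
* **Scenario accounting.** Concentration-limit cancellations are generated
  inside the cancellation stream (per the cause mix) but surface as
  hard-limit alerts, so the internal plain-hard scenario probability is the
  configured hard share minus that spill-over; the recovered alert mix then
  equals the configured one in expectation. Indeterminate cancellations are
  realised as cancellations with no replacement inside the window (IV-access
  failure, condition change, therapy discontinuation); they consume no
  infusion start.
* **Arrivals.** Inter-arrival structure across a real fleet is unknown; the
  generator spreads episodes uniformly over the study window per device with
  a 300 s minimum gap — an explicit, replaceable assumption that guarantees a
  planted replacement is the only sequence inside any cancellation's pairing
  window. Device 0 always carries LVP+syringe+PCA modules so wrong-channel
  swaps are realisable.
* **Determinism.** One `numpy` Generator stream, draws ordered by generation
  step: identical config + seed reproduce the log and truth byte for byte.
  Reproducibility *across* RNG implementations is not promised; recovery
  checks are statistical, not byte-level.

## What the synthetic tests show — and do not

On generated logs, cause classification is checked to agree with the planted
truth for 100% of cancellations, recovered alert/cause/position mixes to fall
inside 99% binomial bands of the configured proportions at 50,000 starts, the
recovered decision-time mean to sit within 3 standard errors of its target,
and every planted >100× factor to be detected. These are *internal
consistency* results: they show the pipeline inverts the generative model
exactly and estimates its parameters without bias at realistic scale. Real
logs differ in ways the generator deliberately omits — clock drift across
modules, interleaved cancellations during busy periods, free-text name
variants beyond the exemplar catalog, partially recorded episodes — so the
validation report (orphan resolutions, duplicate sequence ids, time
regressions) and the quarantine path exist precisely because real data will
exercise them.

## Problem sizes

The default test suite runs the full recovery check at 50,000 infusion starts
(~115,000 events, a few seconds end to end) and unit tests at 2,000 starts;
the acceptance script uses 50,000 starts. These sizes put ~350 wrong-medication
and ~320 wrong-dose corrections in the log — enough that every cause category
with a nontrivial share is exercised and binomial bands are informative, while
keeping any single run comfortably fast.

## Known limitations

* The pairing heuristic attributes at most one replacement per cancellation
  and cannot recognise corrections completed on a different *device*.
* Wrong-channel detection requires the swap to be PCA↔syringe, per its
  clinical definition here; other module swaps are not classified.
* Therapy-suffix stripping only removes suffixes the formulary lists — with
  no formulary, display names are compared whole.
* Unit conversion covers mass/activity/molar/volume bases with per-kg and
  per-time denominators; concentration-bridged conversions (mass↔volume via
  mg/mL) are flagged incompatible rather than guessed.
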