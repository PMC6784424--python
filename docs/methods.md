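# Methods

This note records the model, the conventions the implementation commits
to where the method leaves room, and what the synthetic data can and
cannot show.

## The moving-average QC model

The QC signal for one analyte is an average over its own patient results,
updated at every new result. With results `x(t)` in measurement order:

* **Simple MA**, batch size `n`: `z(t)` is the unweighted mean of the
  last `n` *accepted* results. The formula is defined only for a full
  batch, so the series emits no value until `n` accepted results exist —
  there is no partial-window warm-up.
* **EWMA**, weighting factor `λ`: `z(t) = λ·x(t) + (1−λ)·z(t−1)`. Smaller
  `λ` smooths more and reacts more slowly. The starting value `z(0)` is
  the arithmetic mean of the truncation-accepted values of the whole
  historical stream (the same filtered population that defines the
  procedure), unless an explicit number is given. The series is defined
  from the first accepted result onward.
* **Truncation limits** are *inclusive*: a result exactly equal to a
  limit is accepted (limits are quoted as "≤ c", so the boundary is in
  range). Rejected results never enter the average; the series carries
  its previous value forward and no alarm evaluation happens there —
  alarm state can only change when the average changes.
* **Control limits** are the minimum and maximum of the defined MA values
  on the unbiased historical stream, per procedure. An **alarm** is
  strict exceedance (`z > upper` or `z < lower`). Strictness is a
  deliberate choice the source method leaves open: the limits are
  themselves attained by the defining series, so a non-strict rule would
  alarm on the very data used to set the limits, while the strict rule
  gives exactly zero false alarms on that data. This zero-false-alarm
  property is a construction, not an empirical finding.

Internally both algorithms are evaluated over the compacted vector of
accepted values — the simple MA via cumulative sums, the EWMA via the
linear-filter form of the recursion — and then scattered back onto result
positions with forward-filling. Tests pin both against independent
oracles (a from-scratch trailing-window mean; the explicit expansion
`z(t) = λ·Σᵢ(1−λ)ⁱ·x(t−i) + (1−λ)ᵗ·z(0)`; a one-result-at-a-time pure
Python replay) at 1e-9 relative. MA values are kept at full double
precision; no rounding to reporting precision is applied.

## Bias-injection simulation

A systematic error of size `b%` is modelled as multiplicative and
persistent: every result from the injection point to the end of the
detection window is multiplied by `1 + b/100`, *before* truncation, so a
gross bias can push results outside the truncation limits and out of the
average entirely — the mechanism behind the truncation trade-off.

Conventions the implementation commits to:

* **Injection points** are the starts of consecutive non-overlapping
  blocks of 400 results, beginning with the second block (the first block
  only warms the MA state). This reading of "every 400 consecutive
  results" maximises the number of independent runs while keeping
  windows disjoint. A stream of `N` results yields `⌊N/400⌋ − 1` runs
  per bias size.
* **Detection window = block size.** A run with no alarm within the
  window is *censored*: it is reported (`n_detected`/`n_runs`) but
  excluded from median/min/max, which therefore always refer to detected
  runs.
* **Counting.** `n_to_detection` counts *all* results presented after
  injection up to and including the alarming one — including
  truncation-rejected ones, because it measures patient-result exposure
  while the error is active. The accepted-only count is retained
  alongside (`n_accepted_to_detection ≤ n_to_detection`, equal whenever
  nothing is truncated).
* Each run restarts from the deterministic unbiased replay of the
  prefix; no state leaks between runs. The replay is vectorised per run
  (prefix state is precomputed once per stream × procedure), which keeps
  the full grid — 108 procedure/truncation combinations across the four
  analytes × 18 bias sizes × ~15–35 injections each — at around a second
  of CPU.
* **Medians** of even-sized samples are the mean of the central pair.
* Bias grid: ±{50, 40, 30, 20, 10, 5, 3, 1}% plus ±TEa rounded to the
  nearest integer percent (half away from zero: 17.97 → 18, 3.57 → 4),
  merged when coincident (albumin's 10%).

## Candidate evaluation and ranking

Feasibility uses the worst case: a bias level is "reliably detected"
when every run alarmed and the **maximum** results-to-detection is at
most the daily test volume — the question being whether an error is
certainly caught within a day. Criterion (a) applies this at ±TEa;
criterion (b) at every |bias| > TEa. Any non-detection at |bias| ≥ TEa
makes a candidate infeasible: going blind to a gross error is worse than
detecting it slowly.

The selection among feasible candidates is, in the source method, partly
visual; here it is codified as an explicit deterministic chain: ascending
median at +TEa, then at −TEa, then the worst median over all
|bias| ≥ TEa, then the simpler configuration (fewer truncation limits,
then larger λ / smaller n), then the config id. This chain is an
interpretation, documented as such, and is the only place where the
package goes beyond the stated criteria.

## Synthetic streams

The generator emulates an outpatient primary-care population described
only by summary statistics:

* **Core distributions**, matched to median and IQR exactly by
  construction: shifted log-normal for right-tailed analytes (creatinine:
  max 971 µmol/L against a median of 70 implies a heavy right tail),
  truncated normal for near-symmetric ones (sodium, potassium), and a
  *mirrored* shifted log-normal for mildly left-tailed albumin
  (41–43–44 g/L with a minimum of 20) — a symmetric core cannot produce
  that asymmetry, and mirroring reuses the same three-quantile fit.
* **Pathological tail**: with a small per-analyte probability
  (creatinine/albumin 1.2%, potassium/sodium 0.6%) a draw is replaced by
  a uniform value over the observed [min, max], so rare extremes exist
  and truncation-candidate limits actually reject something. Values are
  clipped to [0.9·min, 1.1·max].
* **Day structure**: per-day counts are Poisson around the daily volume;
  timestamps are sorted uniform seconds within 07:00–15:00 working
  hours; no weekend gap (an outpatient population without a weekend
  effect). 121 working days reproduce the six-month totals of the four
  packaged profiles (≈14.5k creatinine … ≈2.4k albumin results).
* **Independence**: values are i.i.d. by default. Real streams carry
  autocorrelation (analyser drift, patient mix through the day) that the
  source data did not quantify; an optional sinusoidal day-level drift
  (multiplicative, amplitude default 0, period 30 days) is provided for
  sensitivity experiments but is off everywhere. Consequently, passing
  tests show the *machinery* is correct and the qualitative trade-offs
  (truncation vs gross bias, λ/batch-size trade-offs) reproduce; they do
  not certify detection-delay numbers for any real laboratory, which
  must be re-derived on that laboratory's own streams.
* **RNG**: one explicitly seeded generator per stream, seed recorded in
  the stream metadata and in every output file header.

## Degenerate inputs and numerical edges

* A profile with `q1 = median = q3 = min = max` yields a constant
  distribution; zero IQR with a spread range is rejected as infeasible,
  as are quantile triples contradicting the declared skew family.
* An EWMA with `λ → 1` tracks the raw accepted values; `λ → 0` stays at
  its starting value (property-tested at the representable extremes).
* Streams whose every value is truncated raise an error rather than
  emitting an empty series; control limits require at least one defined
  MA value.
* Control limits carry the key of the procedure that derived them;
  mixing limits and procedure raises a configuration-mismatch error.
  Hand-built limits (e.g. transcribed from an external table for
  closed-form checks) carry no key and are accepted as given.

## Known limitations

* Only persistent multiplicative bias is simulated — no random-error
  (imprecision) increase, intermittent or drifting error shapes, and no
  cost weighting of delayed detection.
* Whether reported extremes should include censored runs (e.g. at the
  window size) is a representational choice; censored runs are kept out
  of the statistics and reported as counts instead.
* The generator does not model demographics, inpatient/outpatient mix,
  haemolysis-index or platelet-count filtering; truncation limits are
  the only inclusion criterion, as in the method being implemented.
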