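# Methods

This note records the models, conventions, and numerical choices behind
`esn-analysis`, including the decisions made where the procedure left
genuine freedom, and what the synthetic calibrations do and do not show.

## Task model and windows

A session consists of encoding blocks (≈ 20 self-paced episodes each;
cue shown 2 s before the associates, validated to ±1 ms), a distractor
gap, and a retrieval block per encoding block.  All windows are
half-open `[start, end)` in float seconds from session start, which
makes spike counts additive over window partitions and avoids double
counting.  The encoding analysis window runs from associate onset
(when the whole episode is first present) to the plausibility response;
"end of the episode" is taken to be that response.  The retrieval
window runs from cue onset to the remembered-count response.  Tables
are UTF-8 TSV with header rows; times round-trip losslessly because the
writer emits `repr(float)`.

## Rate-code ESN detection

* z-scoring uses the sample sd (ddof = 1; `sd_ddof` switches to the
  population convention for sensitivity analysis).  Units with zero
  rate variance are excluded with a warning rather than propagating
  NaNs.  Standardization happens over **all** episodes first; the
  remembered/forgotten restriction subsets the z-vectors afterwards —
  the order matters and is covered by a test.
* Thresholds are the 99th percentile of the pooled permuted values
  using numpy's linear-interpolation percentile definition, making
  thresholds bit-reproducible.  Encoding order is permuted uniformly
  over all n! orderings (identity included); retrieval stays fixed.
* Threshold and gate comparisons use `≥` (a `strict_threshold` flag
  switches to `>`); measure values are continuous, so ties only occur
  in degenerate fixtures.
* `normalized_product` floors `|E − R|` at 1e−6 to keep E = R finite.
* All p-values use the `(1 + b)/(1 + N)` estimator, so 10,000 draws can
  report "P < 0.001" without ever claiming zero.
* The group test redraws one *stored* first-level permutation per unit
  per draw, so both levels share the same randomization — the package
  stores, per unit, the qualification flag of every permutation, which
  is sufficient for the second level and orders of magnitude smaller
  than the index matrices.
* The Experiment-1 cue-response exclusion treats the reinstated
  episodes' encoding-cue onsets as presentations and the pre-cue 500-ms
  windows of **all** episodes as the baseline pool (the natural pooled
  null; using only reinstated episodes' baselines would leave 1–3
  samples).  Experiment-2 exclusion instead uses the visual-tuning
  task via the concept-cell test.
* The miss-ESN bootstrap samples, per unit, as many remembered events
  (with replacement) as that unit has forgotten events; a unit is a
  null miss-ESN when any sampled event was reinstated.  The one-sided
  p asks whether the empirical miss-ESN count is *lower* than this
  matched-count null.

## Temporal-code (tESN) detection

* Traces are sampled at 1 kHz, which puts the ±2.5 s lag grid exactly
  on samples.  Kernels are evaluated analytically per spike (peak 1 at
  the spike time, truncated at ±300 ms), so convolution linearity is
  exact and a spike on the grid contributes exactly 1.0 at its own
  sample.
* The raw window is response − 6 s … response + 1 s; convolution runs
  on the raw window and 1 s is trimmed from each edge afterwards, so
  spikes within kernel reach of the trimmed edges keep their mass.
  Both phases anchor to their own response events.
* The ≥ 10 spikes gate applies to the raw window of **both** phases of
  a trial; units need ≥ 10 qualifying trials.
* Cross-correlation is the raw (unnormalized) sliding inner product, as
  in common numerical environments; positive lag means encoding leads.
  A normalized (cosine) variant sits behind a flag.  All n² pairwise
  maxima are computed once (batched FFT correlation), making the 1,000
  pairing shuffles a table lookup.
* The pairing shuffle permutes which retrieval trial each encoding
  trial is correlated with, uniformly over permutations; pooled maxima
  give the 99th-percentile threshold and the empirical value must
  *reach* it (`≥`).

## Concept-cell (visual tuning) test

* The 1-s post-stimulus period is tiled with 19 overlapping 100-ms bins
  at a 50-ms step — the unique tiling producing 19 bins.
* Each bin's counts across an image's presentations are compared with
  the pooled 500-ms pre-onset baselines of *all* presentations in the
  session: two-tailed Mann–Whitney U, normal approximation with
  continuity and tie correction (counts are heavily tied); scipy's
  exact enumeration is used only when both groups have ≤ 8 tie-free
  observations, since the exact method does not correct ties.
* The 19 p-values are combined with the Simes procedure
  (`min_i m·p_(i)/i`); no correction across images, by design.
* **Significance additionally requires the response to be an
  increase** (the best bin's rate above the pooled baseline rate).
  This is deliberate: bin counts (100 ms) are systematically smaller
  than baseline counts (500 ms), so an undirected two-tailed call
  would flag essentially every unit firing above ≈ 2 Hz for
  "tuning" in the *decrease* direction (measured false-positive rate
  0.98 at 2 Hz, 0.00 at ≤ 1 Hz).  Tuned responses in this literature
  are firing increases, and the exclusion logic that consumes this
  test is defined in terms of increases.  With the gate, the null
  false-positive rate is controlled at all firing rates (tested).
* Baseline windows that overlap a preceding image's display are kept;
  the inter-onset interval (≥ 1.5 s) prevents overlap with response
  windows.

## Time-cell test

* "Width factor 2.5" of the 251-sample kernel is interpreted as the α
  parameter of the classic parametric Gaussian window (sd = (N−1)/2α ≈
  50 samples = 50 ms at 1 kHz).  This inverse-of-sd convention is the
  one numerical environments attach to that phrase; it is configurable.
* The Kruskal–Wallis groups are the 40 per-block bin means (one sample
  per block per bin), for both the duration-normalized and the
  NaN-padded layout; the two agree exactly when all blocks have equal
  length (tested).  The vectorized H implementation (tie-corrected,
  NaN-omitting) is verified against `scipy.stats.kruskal`.
* The null shifts each block's unpadded trace circularly by an
  independent uniform offset and re-bins via a cumulative-sum lookup
  (O(bins) per shift).  A unit is a TC when its empirical H reaches
  the 95th percentile of its own null.

## Spike-density comparison

* Densities use the same 100-ms kernel on [cue − 1 s, cue + 5 s) at
  1 kHz.  The z-score's denominator is the standard deviation across
  the per-episode **baseline means** (matching the notation of the
  defining equation), plus the 0.1 regularizer that keeps silent units
  finite; the numerator centers on the grand baseline mean.
* Bootstrap equalization resamples both classes with replacement down
  to the smaller class size, N = 100 draws.
* The cluster test forms clusters from the per-timepoint paired t
  statistic at the two-tailed α = 0.05 critical value; cluster mass is
  the summed t; the null flips condition labels within units (sign
  flips of the paired differences, computed in closed form from the
  per-unit sums of squares) and records the maximum absolute cluster
  mass.  Single-timepoint clusters are allowed.  The per-timepoint
  proportion of bootstrap draws whose significant cluster covers the
  timepoint is reported alongside mean ± s.e.m. traces.

## Synthetic generator

The generator emulates the statistical structure the detectors assume:

* Baseline spiking is homogeneous Poisson per unit (default 2 Hz) —
  the minimal null consistent with the rate statistics; no bursting,
  refractoriness, drift, or waveform structure is modelled.
* Episode durations are log-uniform (encoding 5–20 s, retrieval
  3–12 s): self-paced timing is right-skewed and only the distractor
  range (22.43–224.52 s, also log-uniform here) is pinned by the task
  description.  Remembered labels are i.i.d. Bernoulli at the observed
  hit rate (default 0.68), with planted-effect episodes forced
  remembered.
* Planted effects: rate ESNs multiply the Poisson rate by `rate_gain`
  inside one episode's two analysis windows; temporal ESNs emit a
  3-spike latency motif (20-ms jitter), repeated 3× per phase — a
  single motif is statistically marginal against the max-over-lags
  background of trials already gated to ≥ 10 spikes; concept cells add
  rate for 1 s after each presentation of one image; time cells add
  rate inside one of 40 within-block spans of every encoding block.
  Tuning-task images are linked to episodes by the
  `"<episode_id>:<role>"` id convention.
* Surrogates: episode-granular circular rotation of per-segment spike
  blocks (offsets preserved proportionally; a session-level circular
  shift sits behind a flag, since the one-sentence description of the
  procedure leaves the granularity open), and integer-valued random
  spike times on the rounded empirical range.
* Every generator is a pure function of (config, seed).

### What the calibrations show — problem sizes

The acceptance script runs the pseudo-rate null calibration at full
width (585 units, 40 + 40 trials, variance factors 2–5) with 1,000
first-level permutations and 10,000 second-level draws, 200 repetitions
per factor.  The test suite uses scaled-down versions of the same
calibrations (e.g. 100-unit pseudo-rate repetitions, 300–1,000
permutations, 20–60 seeds per suite), chosen as the package's own
test-size policy.  Recovery runs use conditions where the planted
effect is the effect the detector targets at a realistic strength:
gain-5 rate effects on 2-Hz units (20 units × 30 episodes), the
repeated latency motif on 2-Hz units (30 episodes), gain-10 image
responses on a high-firing 20-Hz unit (count separation, not the gain
ratio, powers the binned rank-sum test: at 2 Hz even perfectly
separated counts from 6 presentations cannot reach P < 0.0005), and
gain-8 time fields over 12 five-episode blocks (block repetitions power
the rank-based bin test).

Passing these calibrations shows the inference machinery is unbiased
and sensitive **under Poisson statistics with stationary baselines**.
They do not demonstrate robustness to bursting, rate drift across a
session, spike-sorting contamination, or electrode artefacts, all of
which real recordings contain.

## Known limitations

* The concept-cell test has little power below ~5 Hz response rates
  with only 6 presentations; this mirrors the count-based original
  method rather than a defect of the implementation.
* The episode-granular circular surrogate rescales within-segment
  offsets proportionally when segment lengths differ, which slightly
  distorts inter-spike intervals.
* The cluster test assumes exchangeable units and a common time base;
  it is not a spatio-temporal cluster test.
* Parahippocampal/region comparisons are supported only through the
  `region` metadata; no anatomical processing is included.
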