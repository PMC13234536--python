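# Methods

## The control scheme being modeled

A single surface-EMG sensor reports muscle activity as integers 0–1023.
A *flex* is one contraction episode: the maximal run of processed samples
strictly above a user-adjustable resting baseline. Its *peak* (the run
maximum) is defined only once the signal has dipped back below the
baseline; the peak is then compared against ordered gesture-zone minimums,
each zone spanning from its minimum to the next minimum (or 1024 at the
top), and the containing zone selects the gesture. The assessment game cues
a zone, accepts exactly one flex per cue, and scores a trial out of 15 cues.

## Signal conditioning

The conditioning chain is rectification → 2 Hz Butterworth high-pass
(order 2) → moving-average smoothing (50 ms window) → global scale →
round-half-away-from-zero quantization clamped to [0, 1023].

Numerical choices worth stating:

* The nominal analog band extends to the sampling limit, so no digital
  low-pass is applied; at 1000 Hz sampling the upper band edge is realized
  by the sampling itself. Only the 2 Hz high-pass side is digital. The
  filter family and order are this package's declared choices; the device
  specification names only the band edges.
* Rounding is half-away-from-zero (the usual embedded-device convention),
  fixed so quantization is exactly testable; it is monotone and satisfies
  `quantize(v, s) == quantize(v·s, 1)`.
* `filter_and_smooth` rejects traces shorter than the filter warm-up length
  rather than returning transient-dominated output.
* Boundary semantics are the narrowest reading of "above"/"below": a sample
  exactly equal to the resting baseline neither opens nor closes a flex,
  and a zone is closed at its minimum (`peak == minimum_i` lands in zone
  *i*). A contraction still open at end-of-stream emits nothing in batch
  mode (its peak is not yet defined); `flush` force-emits for interactive
  use. No refractory period is imposed after a flex.
* Packets arriving at ~60 Hz are buffered and consumed in arrival order at
  the 30 Hz frame cap (33.3 ms per processing step); no samples are dropped
  or reordered (`iter_frames`).

One detector property deserves a caveat: "raising the resting baseline
never increases the event count" holds for unimodal-burst signals (the
physiological case, and how it is tested) but **not** for arbitrary jagged
streams, where a higher baseline can split one above-threshold run into
two. The run-based definition makes this unavoidable.

## Calibration and zones

Calibration observes the maximum voluntary contraction (MVC) peak and sets
`global_scale = target_fraction × 1023 / mvc_peak`, so a repeat of the MVC
quantizes exactly to `round(target_fraction × 1023)`. Equal segmentation
places the first zone minimum at `resting + 1` (so every detected flex is
in some zone), uses integer widths `round((1024 − first)/n_zones)`, and
lets the top zone absorb the rounding remainder up to 1024. Minimums are
validated to be strictly increasing and above resting; no further bound is
imposed, matching the device's "manually set" freedom.

## The simulated participant

Human participants are replaced by a deliberately minimal behavioral model:

* **Aiming.** A cue response's processed peak is drawn from
  `Normal(center of cued zone, aim_sd)`, clipped to [0, 1023] and
  quantized. `aim_sd` (device counts) is the single accuracy knob. The
  per-zone hit probability is then the normal CDF increment over the zone
  (with half-count offsets for integer quantization, top-zone mass added
  for ceiling clipping, and the resting gate respected) — closed-form,
  Monte-Carlo-checkable, and invertible: `estimate_aim_sd` recovers the
  generating value from per-zone hit counts by 1-D maximum likelihood.
* **Waveform.** Each response is 200 ms of baseline noise, a raised-cosine
  burst (default 300 ms), and 200 ms more noise. The conditioning chain is
  positively homogeneous in amplitude, so a short secant iteration solves
  the burst amplitude that makes the processed, quantized peak equal the
  sampled target *exactly* — the direct-draw route and the full-DSP route
  provably agree, which the tests assert event by event.
* **Baseline.** Sensor noise is Gaussian (mean 10, SD 2 raw units, clipped
  at 0); after conditioning it stays far below the default resting
  threshold of 20 counts, so no spurious flexes occur at defaults.
* **Population.** Per-participant `aim_sd ~ LogNormal(median 200 counts,
  σ_log 0.3)`, a realistic novice level giving roughly 60% per-cue accuracy
  at 3 zones. A `peak_floor` option models the structural single-zone
  ceiling (a participant who always produces *some* detectable flex).
* **Surveys.** Integer item responses are rounded clipped Gaussians around
  cohort profiles anchored to the published cohort-level SUS/TLX means; EHI
  tallies are right-biased binomials over 10 items. Because items are
  integers, a cohort's mean score matches its profile target only in
  expectation.

What the generator does **not** emulate: fatigue across trials (the study
managed it procedurally with 1-minute rests), learning effects, electrode
shift, or any correlation between a participant's accuracy and their survey
answers. Passing tests therefore demonstrate the pipeline's correctness and
the model's internal consistency, not fidelity to any particular human
cohort; no published per-zone accuracy breakdown exists against which
`aim_sd` could be calibrated non-circularly, so matching the human cohorts'
3- and 5-zone score means is explicitly not claimed.

## Cue randomization and schedules

Cues are i.i.d. uniform over zones by default — "randomized" is the only
stated constraint, so the minimal assumption is the default — with an
optional balanced mode (equal per-zone counts, shuffled). Cohort schedules
are fixed: A1 (1,1,1), A2 (3,3,3), A3 (5,5,5), B1 (1,3,5); each schedule is
played on the right arm then the left as independent repeats with separate
derived seeds. All randomness descends from one seed via `SeedSequence`
spawning.

## Statistics

Test statistics are delegated to scipy.stats; effect sizes are computed
here with their conventional definitions and asserted as identities on
every emitted result:

* Paired contrasts: paired t (df = n−1), paired Cohen d =
  mean(diff)/sd(diff), Hedges g = d·(1 − 3/(4 df − 1)); a Shapiro–Wilk gate
  on the differences (p < .05) attaches a Wilcoxon signed-rank sensitivity
  result.
* Between-cohort contrasts: Welch t with Welch–Satterthwaite df and a
  t-based 95% CI; pooled Cohen d uses the pooled SD at df = n₁+n₂−2 (the
  conventional definition, even though the test is Welch); d_av divides by
  the plain average of the two SDs. The exact gamma-ratio Hedges
  correction is available behind a flag and cross-checked against the
  approximation.
* Nonparametrics: tie-corrected Kruskal–Wallis; Spearman with midranks;
  Mann–Whitney U (a-side count convention) with rank-biserial
  r = 1 − 2U/(n₁n₂), exact null for small tie-free samples and the
  tie-corrected normal approximation otherwise.
* Everything is two-sided at α = .05 and *nothing* is adjusted for multiple
  comparisons — a property of the reproduced analysis plan, asserted in the
  tests (no adjusted columns exist).
* All SDs use the n−1 denominator. (The analysis plan's phrase "SDs use
  t(n−1)=1 for effect size testing" is not interpretable as written; the
  sample SD is the standard reading and is what is implemented.)
* Degenerate inputs are flagged rather than silently propagated: zero-
  variance differences (paired d undefined), zero variance in both Welch
  groups, constant Spearman input (NaN with a warning).
* The NASA-TLX composite is the unweighted mean of the six subscales with
  performance inverted (100 − performance), labeled
  `composite_inverted_performance`; it reconciles the published overall
  column to rounding for three of four cohorts and is never used as an
  empirical anchor. No pairwise TLX weighting is applied (raw-TLX variant).
* Report rendering rounds means/SDs to 1 decimal and differences, CI
  bounds and effect sizes to 2, matching the published tables' precision.

The matched-trial design compares the progressive cohort's trial *k*
against the static cohort with the same zone count at the same trial index
(B1 t1 vs A1 t1, B1 t2 vs A2 t2, B1 t3 vs A3 t3), equalizing both zone
count and exposure time. Published participant-level data were not
released, so the published *inferential* values (specific t, H, p) are not
reproducible and are not targets; what the pipeline reproduces exactly is
the in-table arithmetic (overall columns, the size-weighted overall SUS
mean of 73.6, the 12.9-point SUS gap) and the structurally forced
single-zone ceiling.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks use 3-standard-error tolerances at their stated draw
counts (50k–100k peak draws for hit rates; 10⁴ random streams for the
detector oracle; all 1024 peaks × 50 random threshold sets for zone
assignment). The `aim_sd` recovery check uses 200 simulated participants ×
45 cues at a true value of 80 counts (chosen so per-zone hit rates are
informative, i.e. away from 0 and 1) and requires recovery within 10%.
Cohort-level simulation tests use 2–5 participants per cohort, enough to
exercise every code path while keeping the full-DSP route (≈2 ms per
simulated contraction) comfortably fast.
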