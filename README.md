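# mdat — single-sensor EMG magnitude-discretization trainer, headless

Multigesture myoelectric prostheses driven by **one** surface-EMG sensor
discretize contraction *strength* instead of fusing many electrodes: a light
flex triggers one gesture, a hard flex another. `mdat` is a headless,
testable implementation of that control scheme and of the gamified
assessment built around it (the Muscular Discretization Assessment Tool,
MDAT), for researchers who want to simulate, score and statistically analyze
discretization-training studies without hardware or a GUI.

The package covers the whole pipeline:

* **Signal chain** (`mdat.signal_core`) — rectification, a 2 Hz Butterworth
  high-pass, moving-average smoothing, and quantization onto the 10-bit
  device scale (0–1023), sampled at 1000 Hz and consumed at a 30 Hz frame
  cap (33.3 ms per processing step).
* **Flex detection** (`mdat.flex_detector`) — a two-state machine: a
  contraction ("flex") is a maximal run of samples strictly above the
  resting baseline, and its **peak** — the run maximum — is emitted when the
  signal dips back below the baseline.
* **Zones & calibration** (`mdat.zones`) — gesture zones are half-open
  intervals `[minimum_i, minimum_{i+1})` on the 0–1023 axis (top zone open
  at 1024); a flex's peak selects the zone. Calibration "zooms in" the axis
  so a user's maximum voluntary contraction lands at a target fraction of
  full scale.
* **Cue game** (`mdat.game_engine`) — 15 randomized zone cues per trial, one
  contraction per cue, success iff the peak lands in the cued zone; static
  cohorts A1/A2/A3 play 1/3/5 zones for all three trials, progressive
  cohort B1 advances 1 → 3 → 5.
* **Synthetic participants** (`mdat.simulated_user`) — resting noise plus
  cue-targeted raised-cosine bursts whose processed peak is
  `Normal(zone center, aim_sd)`; per-zone hit probability has the closed
  form `Φ((u−μ)/σ) − Φ((l−μ)/σ)`, so accuracy is analytically checkable and
  `aim_sd` is recoverable from hit rates. Also generates cohort-structured
  survey responses.
* **Psychometrics** (`mdat.surveys`) — SUS (odd items `x−1`, even `5−x`,
  sum × 2.5), raw NASA-TLX (`(x−1)×5` per subscale, performance inversely
  oriented), and the Edinburgh handedness laterality quotient
  `(R−L)/(R+L)×100`.
* **Statistics** (`mdat.stats_pipeline`) — paired t with a Shapiro–Wilk
  gate and Wilcoxon sensitivity check, Welch t with pooled Cohen *d*,
  Hedges *g* = *d*·(1 − 3/(4 df − 1)) and *d*<sub>av</sub> (mean difference
  over the average SD), Kruskal–Wallis, Spearman, Mann–Whitney with
  rank-biserial *r* = 1 − 2U/(n₁n₂), and the cohort report tables.

## Worked example

Simulate a small progressive cohort and report it:

```python
import mdat

scores = mdat.simulate_cohort("B1", n_participants=5, seed=1)
print(scores.groupby("trial")["score"].mean().round(1))
```

```
trial
1    14.6
2    10.1
3     6.0
```

Mean scores out of 15 fall as the schedule advances from 1 to 3 to 5 zones:
with zone width shrinking, the same aiming noise (default population:
`aim_sd ~ LogNormal(median 200, σ_log 0.3)` device counts) hits the cued
zone less often. A perfect aimer saturates every mode:

```python
from mdat import UserModel, SessionPlan, run_session
trials = run_session(UserModel(aim_sd=0, seed=3), SessionPlan(cohort="A3"), seed=2)
print([t.result.score for t in trials])   # [15, 15, 15, 15, 15, 15]
```

The same pipeline is scriptable from the shell:

```sh
mdat demo --seed 7 --out demo_out       # simulate all four cohorts + report
mdat simulate --cohort B1 --seed 3 --out sim_out
mdat score-surveys sim/surveys_raw.csv --out surveys_scored.csv
mdat analyze trial_scores.csv --surveys-csv surveys_scored.csv --out report
```

`demo` writes `trial_scores.csv`, raw and scored survey tables, and a
`report/` directory with the cohort×trial performance table, matched-trial
Welch contrasts (B1 trial *k* vs the static cohort with the same zone
count), SUS by cohort with the size-weighted overall mean, TLX subscale
tables with Kruskal–Wallis p values, and pairwise subscale contrasts
ordered by significance.

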