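# Methods

This note documents the models, numerical choices, and open design
decisions behind `cagephys`, in the spirit of a statistical package's model
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Task rules and visit classification

The cage has four operant corners. Adjacency is not observable from event
logs, so the geometry is *derived from the corner-switch cycle*: corners
consecutive in the cycle 1 → 3 → 4 → 2 are adjacent, hence the diagonals
are {1, 4} and {2, 3}. The geometry is a parameter
(`CornerGeometry(cycle=...)`); a 1 → 2 → 3 → 4 cycle yields the alternative
{1, 3}/{2, 4} pairing. Some program schematics in circulation pair corners
2 and 4 as opposites, which is inconsistent with the switch cycle above;
the cycle-derived geometry is the default and the alternative is one
constructor call away.

Classification conventions:

* a visit is classified by its **entry time**; phase intervals are
  half-open `[start, end)` and visits spanning a boundary are not split;
* visits outside the drinking-session window are excluded from scoring
  (the tasks are defined only during the session);
* adaptation programs (free / nosepoke / time) generate no labels;
* in the sequencing task, a correct-corner visit with **zero nosepokes** is
  labelled correct but does not trigger the diagonal swap, because the door
  switch is nosepoke-triggered (configurable via
  `swap_requires_nosepoke=False`);
* a visit to the non-correct corner of the assigned diagonal is labelled
  `previously_correct` even before the first swap: the four-way label set
  reserves that category for the "opposite" diagonal corner, and before any
  swap that corner has never been rewarded, so the label reads as
  "opposite member of the assigned diagonal".

The incremental sequencing state machine is verified against a brute-force
oracle that recomputes the correct corner from the complete visit history
at every visit.

The published program table sums to 17 days while the accompanying text
declares an 18-day experiment; `ProgramTimeline` reports both
(`total_days`, `declared_total_days`) and never silently reconciles them.

## Learning curves and AUC

The curve is a right-continuous step function of normalized session time:
event-driven steps, no interpolation, because visits are instantaneous.
The default denominator is the **whole-session visit count** (each correct
visit adds `1/N`); a running-fraction variant (cumulative correct /
cumulative total) is available behind `denominator="running"` and is
exempted from the monotonicity invariant. Lateral and previously-correct
visits count in the denominator as non-correct visits. AUC is the exact
step integral over [0, 1], so it is dimensionless in [0, 1] and bounded by
the curve's final value. Clock time, not visit index, is the default time
axis; chance-level visiting under four corners gives curves near 0.25·t and
AUC near 0.125 (half of the final fraction when correct visits are spread
uniformly).

Exclusion follows the stricter methods wording: a session enters the
analysis only with **more than 25 visits** (≤ 25 excluded); the threshold
is a parameter.

## The cohort simulator

The generator's defaults are the study conditions: four groups
(18 F-control, 19 M-control, 10 F-mutant, 11 M-mutant; 58 animals), cages
of eight housed by sex, corners dealt so at most two animals share a
correct corner, nightly 3-h sessions, and the published program timeline.

Each animal is an instrumental learner:

* visit times: homogeneous Poisson process within the session, default
  rate **λ = 20 visits/h** (~60 visits/session), which keeps essentially
  every animal above the >25-visit inclusion threshold — matching a study
  in which no animal was excluded;
* corner choice: softmax over **contextual action values**
  `Q[prev_corner, prev_rewarded, corner]` (context 0 at session start).
  Conditioning on the previous outcome is the minimal state that makes the
  sequencing alternation rule learnable; a flat per-corner learner
  provably converges to an accuracy independent of its learning rate within
  one session, which cannot express persistent group differences in this
  task;
* update: `Q ← Q + α (reward − Q)` on the visited corner's entry, where
  reward is 1 iff the task engine labels the visit correct. Values reset at
  program boundaries (a new rule) and persist across days within a
  program; the sequencing rule state resets nightly;
* the softmax inverse temperature is derived from the asymptotic accuracy
  parameter: β = ln(3·p_max/(1 − p_max)), so a fully learned corner is
  chosen with probability `p_max` (default 0.85) and the naive agent is at
  the chance floor 1/4.

Group effects enter as multipliers on α (and optionally p_max). The default
places the advantage on female controls only (α multiplier 1.0 vs 0.3), a
pure sex × genotype interaction mirroring the qualitative pattern of the
study this emulates. The magnitude is a calibration choice — the source
experiments publish test statistics, not per-animal data — set once so that
the day-2 sequencing interaction is detected in well over 80% of replicate
cohorts at the study group sizes, with a simulated F on the order of
10–15 (the published counterpart is larger still).

What the simulator does **not** model: circadian structure and drinking
motivation outside sessions (out-of-session nuisance visits can be injected
at a configurable rate purely to exercise session filtering), lick
microstructure, social interference at corners, and day-to-day motivation
drift. Passing recovery tests therefore certify the *pipeline's*
statistical behaviour under the stated generative model, not the biology of
real cohorts.

## The sweep synthesizer

Waveforms use alpha-function kinetics, `f(s) = (s/τ)·e^(1−s/τ)`, chosen
because analytic slopes and window positions are available for oracles:
a biphasic fiber volley at 1 ms latency and a negative-going fEPSP at 3 ms
latency (τ = 4 ms) after the stimulus, plus additive Gaussian noise. The
fEPSP amplitude is back-calculated from the alpha-function shape factor so
that the *programmed slope* is exactly what the standard 20–80% fitting
policy recovers on a noiseless sweep; the shape factor is computed from the
pure waveform, independently of the trace-measurement code path.

Input–output gain is a Hill saturation in stimulus magnitude
(`i_half = 30 μA`, exponent 1.8), which puts the 30–40% threshold at
−20 μA on the standard −5…−80 μA grid. The paired-pulse model is

    PPR(IPI) = 1 + (1 − Pr)·F·e^(−IPI/τ_f) − Pr·e^(−IPI/τ_rec)

with defaults Pr = 0.35, F = 1.5, τ_f = 120 ms, τ_rec = 150 ms — facilitation
scaled by the unreleased fraction minus a depletion term, recovering to 1
at long intervals and strictly decreasing in Pr at every interval (the
inverse Pr–facilitation relation). Any monotone-in-Pr alternative could be
substituted without breaking the pipeline's invariants.

Potentiation after theta-burst induction follows

    P(t) = 1 + A_stp·e^(−t/τ_stp) + A_e·e^(−t/τ_e) + A_late,

defaults (A_stp, A_e, A_late) = (0.8, 0.3, 0.25) with τ_stp = 10 min and
τ_e = 60 min, so the decaying components dominate the STP window, are
mostly gone by the E-LTP window, and P(t) → 1 + A_late = 1.25 defines the
late plateau.

All randomness flows from one root seed through named `SeedSequence`
substreams (per animal, per sweep), giving byte-identical logs and sweeps
for identical seeds.

## Sweep measurement

* **Slope**: artifact blank 1 ms post stimulus; the fEPSP peak is sought
  from 4 ms (past the fiber volley) to 30 ms; the slope is a linear
  least-squares fit of the raw samples between the 20% and 80% crossings of
  the peak deflection on the initial falling phase. Peak and crossing
  *detection* run on smoothed copies of the deflection (~1 ms and ~0.25 ms
  moving averages respectively), and each crossing is the midpoint of the
  first-above and last-below indices: taking a raw maximum over hundreds of
  noisy samples overestimates the peak (and therefore both thresholds),
  and one-sided crossing picks are biased along the limb — both effects
  otherwise bias low-amplitude (baseline) sweeps more than potentiated
  ones and so inflate normalized LTP. Acquisition software rarely
  documents its internal slope algorithm; this policy is explicit and
  configurable (`SlopePolicy`). Slopes are stored signed (negative-going);
  magnitudes are used for ratios, I/O curves and normalization.
* **Fiber volley**: peak-to-trough within 1–4 ms post stimulus
  (configurable window).
* **Threshold stimulus**: smallest-magnitude stimulus whose response
  fraction of the maximum lies in [0.30, 0.40]; when no grid point falls
  inside, the nearest point below the upper edge is returned with a
  warning. The response measure is the fEPSP **amplitude** by default
  (slope selectable) — the published protocol states amplitude for the
  threshold and is ambiguous for the later 40% selections.
* **Flat traces** (no deflection beyond `min_amplitude_mV = 0.02`) raise a
  `MeasurementError` rather than returning a junk slope.
* **LTP phases**: slopes are normalized to the mean of the 15-min
  pre-induction baseline (×100), averaged per whole minute, then averaged
  over the inclusive windows 11–20 / 51–60 / 111–120 min, interpreted as
  minutes post induction. Windows not covered by the recording are
  reported as missing, never extrapolated. Per-slice series are summarized
  first; animal-level aggregation (mean of a subject's slices) is left to
  the caller.

## Statistics

* **Two-way between-subjects ANOVA**: Type III sums of squares with
  sum-to-zero contrasts (the convention of the graphing software used for
  unbalanced 2 × 2 designs of this kind; Type II by flag), delegated to
  statsmodels OLS. The test suite cross-checks it against an independent
  cell-means/model-comparison computation built directly on `numpy.lstsq`.
* **Mixed repeated-measures ANOVA**: classical split-plot decomposition,
  implemented in-package so the Greenhouse–Geisser ε̂ (computed from the
  pooled within-group covariance of the subjects × levels matrix via
  orthonormal contrasts) can multiply the within-factor degrees of freedom
  and be reported fractionally, e.g. `F(1.8477, 64.6695)`. ε = 1 exactly
  for two within levels; the 1/(k−1) lower bound is enforced. F statistics
  agree with `pingouin.mixed_anova` to numerical precision; the correction
  is applied unconditionally by default (`gg="never"` disables it), since
  adaptive application cannot be inferred from published legends. Subjects
  with missing within-factor cells are dropped listwise.
* **Post-hoc**: Šídák on a caller-specified contrast family (the family
  size is never inferred silently; comparisons use the pooled error term),
  and Tukey HSD via the studentized range over all group pairs.

## Problem sizes

The verification harnesses use 1,000 random logs (≤ 200 visits) for the
label-oracle equivalence, 1,000 random curves for the integration check,
1,000 null simulations (n = 12/cell) for type-I calibration, 50 replicate
cohorts at the study group sizes for interaction recovery, and single-slice
135-sweep LTP time courses at 5% trace noise for phase recovery — sizes at
which the binomial/Monte-Carlo error of each check is small compared to its
acceptance band while the whole suite runs in about half a minute.

## Known limitations

* The behavioral agent is a minimal delta-rule learner; it reproduces
  chance-start saturating learning curves and rule-dependent group
  separations, not fine-grained visit microstructure.
* The sweep model has fixed latencies and no stimulus-artifact shape
  beyond the blanked window; the fiber volley does not scale with
  postsynaptic parameters, so slope linearity in the programmed amplitude
  is exact only up to ~1% foot contamination.
* The mixed ANOVA uses the classical weighted split-plot sums of squares;
  heavily unbalanced within-group designs beyond one between factor are out
  of scope (no mixed-effects modelling).
* Real event logs are assumed time-zone-naive wall-clock, consistent with
  a fixed nightly session window.
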