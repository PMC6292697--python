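# Methods

This document records the statistical model behind each analysis, the scope
and defaults of the session generator, and the calibration measurements that
justify every threshold used in the test suite. Where a published method
description leaves a degree of freedom, the choice made here and its
rationale are stated explicitly.

## 1. Data model

A `Session` holds trials, per-neuron spike trains, and per-spout lick trains
on a single session-time axis. Spike and lick timestamps are strictly
increasing with a minimum separation of 1 µs; serialization (CSV session
directories) rounds times to the 1 µs grid, and the deserializer validates
separation with a tolerance factor of `1 − 1e-6` so that grid-rounded
differences (e.g. `9.9999e-7`) round-trip cleanly.

Each `Trial` records the cue time, concentration (wt%), intensity label
(Low < 7.5 wt% ≤ High), choice, correctness, reward, response/return onsets,
the second lateral lick time, and the epoch intervals
(Return → Stimulus → Response → Outcome). `AlignedRaster` is the common
analysis currency: event-relative spike times per trial plus optional
per-trial labels; `bin_counts` produces half-open 20 ms bins with a closed
final bin so every in-window spike is counted exactly once.

## 2. Session generator

**Scope.** The generator produces the statistical structure the analyses
assume — no more. It models: rhythmic ~6.5 Hz licking with lognormal
inter-lick jitter; the trial sequence (return, dry licks, cue on the n-th
lick, palatability-dependent stop-licking latency, movement, lateral licking
whose duration depends on reward); sigmoidal psychometric choice behavior;
and spike trains from an inhomogeneous Poisson process sampled by thinning.
It does not model spike-sorting artifacts, bursting/refractory dynamics
beyond the 1 µs separation, electrode drift, or session-to-session
nonstationarity.

**Rate model.** A neuron's rate at time *t* in a trial is

```
r(t) = max(0, gain · [ baseline
                      + evoked_delta · 1[cue+onset ≤ t ≤ cue+onset+duration]
                      + intensity/concentration/choice/direction/outcome terms ]
              · lick_factor(t))
```

with `lick_factor = 1 + depth·cos(phase)` advancing linearly through each
inter-lick interval (gaps > 0.4 s unmodulated), and `gain` a per-trial
shared multiplier `max(0, 1 + σ·z)` drawn once per trial per noise group —
this is what produces noise correlations between group members. The label-
dependent terms are confined to the epochs the corresponding detectors
analyze (intensity/concentration: cue → cue+0.6 s; choice: response onset
−0.4/+0.8 s; direction: response and return onsets +0.7 s; outcome: second
lateral lick +0.6 s).

**Key defaults and rationale.**

| parameter | default | rationale |
|---|---|---|
| lick rate | 6.5 Hz | center of the 4–12 Hz licking band the coherence analysis targets |
| concentrations | {0, 3, 4.75, 7.5, 11.75, 18} wt% | the task's stimulus set; 3/18 for discrimination trials |
| psychometric slope / midpoint | 0.6 /wt%, 7.5 wt% | ~90% discrimination accuracy with a sigmoid resolvable across the generalization set |
| stop-licking latency | 0.55 s + 0.011 s/wt% | palatability effect: sweeter cues sustain licking slightly longer |
| preset evoked deltas | +30 Hz (phasic, 0.05–0.15 s), ±10–11 Hz tonic | "strong effect" archetypes that recovery tests should detect ≥ 90% of the time |
| coherent preset depth | 0.9 | well above the multitaper detection threshold at ~20 dry-lick segments/session |
| shared-gain σ | 0.2 | produces r_sc in the 0.1–0.3 range typical of cortical pairs |

Determinism: `simulate_session(config, seed)` spawns independent child
generators (behavior, gains, one per neuron) from a `SeedSequence`, so
identical (config, seed) gives identical sessions and adding a neuron never
perturbs the others.

## 3. Modulation profiles

Classification uses correct discrimination trials only, rasters over
[−0.3, 0.6] s around the cue. Precedence: lick-coherent → Phasic →
Tonic (≥ 0.2 s) → Non-modulated; coherent neurons are split Active/Inactive
by the sign of their best-window delta (Coherent-Non-evoked if none).

**Phasic.** Wilcoxon rank-sum of the 0–0.2 s rate against a
duration-matched baseline (−0.2–0 s) at α = 0.05; if significant, a CUSUM
on the binned PSTH finds the excitatory bout; Phasic requires onset ≤ 0.1 s
and duration 0.04–0.2 s.

**Best-window scan.** Windows on a (center, size) grid — sizes 0.05–0.6 s
and centers 0.05–0.5 s in 0.05 s steps, windows fully inside [0, 0.6] s;
70 windows total. Per-trial rates are computed from counts on a 0.025 s
cell grid (the coarsest grid all window edges fall on), and exposures are
rounded to 10 decimals so equal-duration windows share one float divisor —
without this, spurious float differences (0.30000000000000004 vs 0.3)
destroy cross-sample rate ties and bias the rank-sum (measured null
rejection up to 0.72 at some size-0.3 windows before the fix).

Each window's rates are tested against a **duration-matched baseline
interval** (capped at the 0.3 s of available baseline). Testing short
windows against the full 0.3 s baseline is miscalibrated even under the
null with equal means, because rate granularity and zero-inflation differ
between unequal exposures (measured per-window null rejection up to ~0.6 at
size 0.05); duration matching makes the rank-sum exact for sizes ≤ 0.3 s
and leaves only ~2× nominal inflation at sizes 0.45–0.6 s. The best window
is the significant window maximizing |Δ| vs the mean baseline rate
(ties broken toward smaller size, then earlier center).

**Modulation duration** for the ≥ 0.2 s tonic rule is the maximum size
among significant windows that have the same sign as, and overlap, the best
window — the best window's own size alone under-estimates duration because
max-|Δ| favors small windows.

**Scan-level error rate.** The 70-window scan is deliberately run
uncorrected. Consequence, measured under a global null (flat-rate
neurons, 200-trial sessions): ~40% of null neurons acquire a tonic label
through family-wise error. The parameter-recovery criterion is therefore
evaluated as the overall confusion-matrix diagonal of a balanced cohort
(measured 94.8% / 95.5% at 600 neurons, seeds 1/2), and the null
false-positive clause is applied to the four coding detectors, with the
intensity detector held to an empirically calibrated family-wise bound
(§7).

**Lick–spike coherence.** Multitaper estimate (DPSS, fs = 250 Hz, NW = 3,
5 tapers) averaged over the 4–12 Hz band, on 0.512 s dry-licking segments
that end at the cue. Pre-cue segments are used because cue-evoked
transients are lick-triggered and contaminate whole-bout coherence
estimates. Significance: coherence above
`sqrt(1 − α^(1/(m−1)))`, m = segments × tapers; jackknife CI on the
atanh scale; sessions with < 20 segments are flagged insufficient.

## 4. Intensity selectivity and sensory tuning

`intensity_selective` runs the same window grid with a two-group contrast
(Low vs High rank-sum per window); selective iff any window is significant,
preference by the higher best-window rate. The lick confound control
computes per-0.1 s-bin auROC between Low and High lick rates with bootstrap
CIs and reports the fraction of the neuron's best window covered by
significant lick bins. `sensory_tuning` (generalization sessions) finds the
window maximizing |Pearson r| between rate and concentration and corrects
by permutation of concentration labels (p = (k+1)/(n+1)); population
profiles are normalized to the 3 wt% response and grouped by slope sign.

## 5. Pseudo-population decoding

**Classifier.** Maximum-correlation template matching: per fold, training
features (20 ms counts, 0–0.6 s, all neurons concatenated) are z-scored by
training statistics; class templates are mean training vectors; a test
trial takes the class whose template has the highest Pearson correlation
with its feature vector; exact score ties are broken uniformly at random.
Each of the 50 runs resamples `n_trials_per_class` trials per class per
neuron and performs a fresh stratified 5-fold split; accuracy averages
folds and runs.

A property worth knowing: because Pearson correlation removes the feature-
vector mean, this classifier is *blind to offsets that are uniform across
the entire feature vector*. Class information must be structured — across
time bins or across neurons. Test fixtures are built accordingly.

**Estimator variance.** The 50-run mean is *not* 50 independent estimates:
runs share the underlying trial pool. Measured dataset-level SD of the
run-mean under the null (50 neurons, 30 bins, iid Poisson counts,
8 datasets per condition):

| trial pool per class | SD of 50-run mean |
|---|---|
| 110 | 4.0% |
| 250 | 1.7% |
| 500 | 1.0% |
| 1000 | 0.7% |

A chance-level assertion of 50 ± 2% is therefore unreachable from a
near-minimal session no matter how correct the decoder is. The acceptance
fixture simulates 2800 trials (~1000 correct discrimination trials per
class); the resulting run-mean was 49.2–51.3% across four seeds. Tests that
assert post-shuffle chance use the pre-measured dataset-level SD (1.0% at
their pool size) for their ± 3 SE band, since the run-SEM understates it.

**Controls.**

- *Spike-timing shuffle*: per event window, in-window spikes are replaced
  by the same number of uniform draws (redrawn if any pair violates the
  1 µs separation); per-trial counts are conserved exactly, so any accuracy
  drop isolates timing information.
- *Noise correlation*: per neuron and stimulus, trial rates are z-normalized
  ((FR − mean)/σ, ddof = 1), Low/High blocks concatenated, r_sc = Pearson
  correlation of the pair; significance by within-stimulus permutation on
  |r|, p = (k+1)/(n+1). Pairs on the same channel are skipped; zero-variance
  blocks are reported undefined.
- *Decorrelation*: within-class row permutation for flagged neurons —
  destroys trial alignment, provably leaves every per-neuron marginal
  exactly invariant.
- *Inclusion/dropping*: decoding restricted to one modulation-profile
  population, or to everything but one.

**Outcome decoding** aligns spikes (all neurons) or the lateral lick train
to the second lateral lick, window −0.2 to 0.6 s, and decodes rewarded vs
omitted on cumulative bin prefixes; a time is significant when the lower
2.5th percentile of run accuracies exceeds 50% for ≥ 5 consecutive bins.

## 6. Decision coding

- **Sliding ROC / choice**: 0.2 s windows stepped 0.1 s over (1) 0–0.6 s
  post-cue and (2) −0.4–0.8 s around response onset; a center is significant
  when the bootstrap CI of auROC excludes 0.5; a Choice candidate needs ≥ 5
  consecutive significant centers in either interval, then must reach ≥ 70%
  correct in a (window × threshold) neurometric grid search. The
  neurometric curve (per-concentration % classified High) is fitted with
  the same 4-parameter logistic as behavior, and "matches behavior" iff the
  bootstrap slope CIs overlap.
- **Direction**: `P_index = 2(auROC − 0.5)` between leftward and rightward
  trials in the Response (onset +0.7 s) and Return epochs, all trials
  included; permutation test (two-sided on |auROC − 0.5|, p = (k+1)/(n+1));
  a Direction neuron requires significance with the same sign in both
  epochs.
- **Outcome**: auROC between omitted and rewarded trials after the second
  lateral lick, permutation-tested; sign splits Active (omission-excited)
  from Inactive.
- auROC uses midranks, so ties contribute exactly ½ and identical samples
  give exactly 0.5; `P_index` endpoints (±1, 0) are exact, not approximate.

## 7. Overlap statistics

Populations are compared with Fisher's exact test on 2×2 contingency tables
over a common neuron universe, two-sided p computed by hypergeometric
enumeration (tables with probability ≤ observed·(1+1e-9) accumulated), with
optional Bonferroni correction across the report's cells. A perfect
association [[10,0],[0,10]] gives p = 2/C(20,10) = 2/184756 exactly.

## 8. Calibration measurements behind test thresholds

All calibrations were run on seeds independent of the test suite's, before
the corresponding tests were written.

| quantity | measured | test bound |
|---|---|---|
| intensity-detector null FPR (70-window scan FWER, 50 trials/label, 200 reps) | 0.625 | ≤ 0.625 + 3·SE(100) ≈ 0.770 |
| direction-detector null FPR (50 reps) | 0.00 | ≤ 0.05 + 3·SE(50) ≈ 0.142 |
| outcome-detector null FPR (50 reps) | 0.10 | ≤ 0.142 |
| choice-detector null FPR (50 reps) | 0.00 | ≤ 0.142 |
| detector sensitivities at preset effects | 10/10 each | ≥ 27/30 |
| six-class confusion diagonal (600 neurons) | 0.948 / 0.955 (seeds 1/2) | ≥ 0.90 |
| chance-decode run-mean SD at 1000-trial pool | 0.67% | t1 band ± 2% |
| timing-fixture post-shuffle accuracy (3 seeds) | 48.6–50.7%, SD ≈ 1.0% | ± 3.0% |

The per-window rank-sum level of the best-window scan is itself tested
(level ≤ α + 3 binomial SE) in the unit suite, so the duration-matched
baseline calibration cannot silently regress.
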