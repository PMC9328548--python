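# Methods

`mtiat` simulates and analyses paired keyboard / mouse-tracking race-IAT
sessions. This note documents the models, the defaults and the numerical
choices; everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`, not asserted from outside.

## Task structure

Both task variants follow the classic seven-block IAT schedule: two
single-category blocks (faces, then valenced words), two stereotype-congruent
combined blocks (White+positive / Black+negative share a response), one
reversed single-category block, and two stereotype-incongruent combined
blocks — 20/20/40/40/20/40/40 = 220 experimental trials, with the four
critical blocks (3, 4, 6, 7) providing 80 congruent and 80 incongruent
trials. The mouse variant prepends 40 colour-categorisation practice trials.
Responses sit in boxes at the top-left/top-right of a 1024 × 768 screen; the
cursor starts at the bottom centre and is sampled at 100 Hz. The side holding
the correct response varies pseudo-randomly across trials, which is why
trajectories are later mirrored ("remapped") to a common side.

Each critical trial is labelled with its attribute-by-race *pairing* cell:
in congruent blocks, White faces and positive words both index the
White-Positive pairing (they share a response) and Black faces / negative
words the Black-Negative one; incongruent blocks reverse the pairings.

## Synthetic-session generator

A single latent implicit-bias strength `b ≥ 0` per subject (population:
normal with mean 0.27, SD 0.10, clipped at 0) drives both tasks, so the
keyboard score and the mouse congruency effects are correlated by
construction and their association is recoverable downstream.

**Keyboard.** `log RT ~ N(base + b·1[incongruent], σ)` with per-subject
`base ~ N(log 700 ms, 0.12)` and within-subject σ = 0.22 log-units. Error
probabilities are 0.04 on congruent trials and `0.04 + 0.22·b` on
incongruent ones (≈ 0.10 at the population mean), matching a typical
~0.96/~0.88 accuracy split. With these constants the improved-algorithm D
score averages ≈ 0.9–1.0 across a cohort — a clear pro-White effect of the
size conventionally reported for this paradigm.

**Mouse.** Initiation time is `N(base_it + κ·b·1[incongruent], 45 ms)`
truncated at one sample, with `base_it ~ N(240, 30)` ms and κ = 120 ms per
unit bias. After movement onset the cursor integrates, every 10 ms step,

    heading ∝ (1 − w_t) · u_target + w_t · u_opposite,     w_t = w0 · e^(−t/τ_eff)

rotated by Gaussian heading noise (SD 0.15 rad/step), at speed
`v(t) = (v_base + v_peak · exp(−(s·t − t_peak)²/2σ_v²)) · s` — a bell-shaped
profile over a floor, guaranteeing arrival. Three constants carry the
conflict:

* **attraction gain** λ = 0.45: `w0 = 0.18 + λ·b` on incongruent trials —
  stronger initial pull toward the incorrect box, hence larger MD and AUC;
* **conflict persistence** 3.0: `τ_eff = 250 ms · (1 + 3.0·b)` on
  incongruent trials — the pull decays more slowly, so the deviation apex
  (MD-Time) arrives later. This is what produces the Mid-phase congruency
  effect; an initial-weight change alone leaves the apex time nearly fixed
  because the decay clock does not move;
* **conflict slowdown** 0.35: `s = 1/(1 + 0.35·b)` on incongruent trials
  dilates the whole speed profile in time, lengthening the movement
  uniformly (Late phase and total RT). Dilation, rather than a plain speed
  cut, keeps the slow tail of the bell from blowing the Late phase up
  nonlinearly for high-bias subjects.

Speed constants: floor 0.6 px/ms, bell amplitude 0.9 px/ms peaking 350 ms
after onset with SD 180 ms; movement is capped at 10 s (exceeding the cap
raises an error rather than returning a truncated path). Error trials head
to the wrong box under identical dynamics, so downstream filters see
realistic incorrect trials. Mouse error rates are the keyboard rates scaled
by 0.4, reflecting the higher accuracy of reaching responses; combined with
the RT screen this lands total critical-trial exclusions near 2%
(congruent) and 4% (incongruent).

These defaults were fixed once, by scanning for the qualitative effect
structure the generator is meant to emulate — positive D, positive Δ-MD and
Δ-Acc-Max-Time with positive D-associations, unimodal MD within condition,
Mid phase carrying the largest congruency effect with Early and Late
smaller, and a mouse task slower but more accurate than the keyboard task —
and are not tuned per analysis.

**Randomness.** A single global seed expands deterministically:
`SeedSequence([seed, subject_index, stream])` with stream 0 = subject
parameters, 1 = keyboard session, 2 = mouse session, 3/4 = schedules. Within
a mouse session all draws have fixed shapes and order (choice uniforms,
initiation normals, then 384-column blocks of heading noise drawn on
demand), so any single trial is reproducible by regenerating the subject's
blocks and slicing one row; batching trials across subjects is bitwise
identical to per-subject simulation because the dynamics are elementwise.

**What the generator does not emulate.** No pauses, mouse lifts, or device
quantisation beyond the 10 ms grid; no "Faster"-prompt behaviour beyond the
initiation-time distribution; no sub-movement structure or feedback delays;
no order/practice effects across blocks; stimulus content (faces, words) is
categorical only. Passing tests therefore show that the *analysis chain* is
correct and that its statistics behave as designed under a plausible
smooth-trajectory model — not that real cursor data satisfy that model.

## Preprocessing

Initiation is the first sample displaced from the start by more than ε
(default ε = 0 px — any movement; configurable). Space normalization
translates the start to (0, 0), flips y to mathematical orientation and
divides both axes by the same factor — the vertical start-to-box-row
distance — so the response row lies at y = 1 and angles/distance ratios are
preserved. Time normalization linearly interpolates x and y at 101 equally
spaced real-time points spanning stimulus onset → response click (the span
is configurable to onset-of-movement → click), recording each step's real
time; endpoints are preserved exactly. Left-ending paths are mirrored so all
trajectories end top-right; the operation is idempotent.

Exclusions on critical-block trials apply in a fixed order: (1) incorrect
trials; (2) RTs outside mean ± 3 SD, computed per subject over that
subject's remaining critical trials (pooled scope available; per-subject is
the common mouse-tracking default); (3) initiation times strictly longer
than 500 ms. The report gives per-condition counts and percentages.

## Trial metrics

All geometry is measured on the 101-step remapped trajectory against the
straight segment from its start to its end point. Signed conventions:
positive MD/AUC lie on the side of the non-chosen (left) response, negative
values are overshoot on the chosen side. MD is the signed perpendicular
distance of largest magnitude (first step on ties), AUC the shoelace area of
the closed trajectory-plus-chord polygon. Velocity and acceleration are
first and second finite differences of the time-normalized x series
(dimensionless, per-step); the `*_time` metrics map the first step attaining
each maximum back to ms through the step-time table — the normalized series
orders the steps, the recorded times date them. x-flips counts sign
reversals of nonzero x-steps (zeros skipped). Sample entropy uses the
first-differenced x series, template length m = 3, tolerance 0.2 × SD,
Chebyshev distance, self-matches excluded, both template sets over the same
N − m offsets; zero variance or zero matches yield an undefined flag rather
than a number.

## D score

The improved scoring algorithm, fixed to one variant: delete trials slower
than 10,000 ms; flag (never drop) subjects with more than 10% of remaining
trials under 300 ms; replace each error trial's RT with its block's
correct-trial mean + 600 ms; score pairs (block 3, 6) and (block 4, 7) as
(incongruent mean − congruent mean) / pooled SD of the pair's adjusted RTs
(sample SD, ddof = 1), and average. Positive D = incongruent slower =
pro-White direction.

## Phase decomposition

From per-subject, per-condition means of IT, MD-Time and RT (kept trials
only): Early = IT, Mid = MD-Time − IT, Late = RT − MD-Time. The three phase
indices are the incongruent − congruent differences; their sum telescopes to
the subject's RT congruency effect exactly, which the suite checks at
1e-9 ms. Indices are computed at the subject-mean level, matching the
formulas' per-participant averages.

## Dip test

The dip statistic is the classic iterative greatest-convex-minorant /
least-concave-majorant construction over a shrinking modal interval,
working in count units and dividing by 2n at the end, so the uniform
lattice attains the lower bound 1/(2n) and two infinitely separated tight
clusters approach 1/4. The implementation is validated in the test suite
against an independent exact oracle: a linear program minimising the
sup-norm distance to a convex-then-concave cdf over all mode placements.
p-values are Monte-Carlo under the uniform null — the least-favourable
unimodal distribution — with 2,000 replicates by default; a precomputed
null table can be shared across tests of equal n. Because the dip is
affine-invariant, z-scoring within versus across conditions cannot change
d; z-scored values are used for comparability of the distributions shown.
Against a peaked unimodal truth (standard normal) the uniform-calibrated
test is conservative; the suite bounds its rejection rate at α = .05 by
0.07 over 1,000 replicates of n = 150.

## Group-level inference

Mixed models with random intercepts are replaced by within-subject
cell-mean contrasts followed by one-sample t-tests — for balanced
within-subject designs these test the same directional hypotheses without a
mixed-model fitter. The attribute-by-race interaction is the per-subject
double difference (WhiteNeg − WhitePos) − (BlackNeg − BlackPos). Pairwise
phase comparisons are paired t-tests with Holm's correction (in place of
mixed-model Tukey contrasts); Benjamini–Hochberg is available where several
metric contrasts are reported together. Wilcoxon signed-rank comparisons of
the two tasks use the normal approximation with tie and continuity
corrections, reporting r = Z/√n with the sign of the rank-sum shift (exact
enumeration backs the approximation in tests at small n). Associations with
the D score are ordinary least squares (slope, t, df = n − 2). Tucker's
congruence coefficient φ = Σab/√(Σa²Σb²) is computed column-wise on
externally supplied factor loadings; no factor extraction is performed here.

## Problem sizes and runtimes

The replicate-based checks run at 40 subjects per cohort: 100 seeds for the
positive-bias recovery pattern and 500 seeds for the null-bias type-I
calibration (rates required to sit in [0.03, 0.08] at α = .05), sizes at
which a binomial standard error of ≈ 0.01 makes the band meaningful. The
smoothness check uses 20 three-subject cohorts (≥ 150 critical trials per
condition pooled across subjects). `scripts/acceptance.py` simulates 60
subjects and uses 2,000 dip-null replicates. The heavy loops skip the
sample-entropy column, which no replicate-level statistic uses.

## Known limitations

* The generator's movement model is a design choice, not an estimate; no
  claim is made that its constants describe human reaching.
* The dip p-value is calibrated to the uniform null; it is conservative for
  peaked unimodal alternatives, as the calibration test documents.
* Phase indices inherit the MD-Time definition (first signed-maximum step);
  trajectories with several near-equal deviation peaks date the apex at the
  earliest one.
* With ε = 0, any jitter in a real recording counts as initiation; raise ε
  for hardware with positional noise.
* The keyboard/mouse comparison uses per-subject medians and accuracies over
  critical blocks; block-level order effects are not modelled.
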