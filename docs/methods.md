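# Methods

`kinemid` analyses individuality and fatigue-related drift in the joint-angle
waveforms of a repeatedly executed ballistic movement — the karate front kick
(*mae-geri*) — over a single fatiguing training session. Because raw
motion-capture recordings of such a session are rarely shareable, the package
pairs the analysis chain with a synthetic waveform generator that reproduces
the session's protocol structure, so every stage is testable end to end.

## Session protocol

A session (per subject) consists of `n_sets` = 9 sets of submaximal (K-80)
kicks, each set holding 3 blocks of 10 kicks per leg, plus maximal-intensity
(K-100) probes: 3 kicks per leg at 11 time points (before the session, after
each set, after a closing rest). That is 270 K-80 and 33 K-100 kicks per leg,
606 kicks per subject, and 9696 kicks for a 16-subject cohort. Kinematics are
sampled at 333 Hz; each kick spans the phase from first forward foot motion
to maximum knee extension. Nine joint/segment angles (left/right ankle, knee,
hip; sternoclavicular; left/right thigh-to-thorax) are decomposed into Cardan
angles about three axes, giving 27 waveform variables per kick.

## Synthetic waveform model

Each variable of a kick is a cubic B-spline curve on normalized time [0, 1]
with `n_basis` = 8 coefficients. The coefficient vector decomposes into
additive, independently drawn components (all Gaussian, units: degrees):

| component | default SD | timescale it encodes |
|---|---|---|
| grand-mean template | scale 20 | the movement itself |
| subject offset | 3.5 | the individual signature |
| leg offset | 1.75 | left/right asymmetry |
| set-drift random walk (step) | 0.4 | slow drift, tens of minutes |
| block offset, reused across sets | 0.25 | fast repeating structure, tens of seconds |
| per-(set, block) offset, non-repeating | 0.12 | fast non-repeating drift |
| per-kick noise | 1.5 | trial-to-trial variability |

K-100 kicks multiply the waveform by `intensity_gain` = 1.15 and shorten
duration by ×0.9 — enough to keep intensity separable without a distinct
shape model. Kick duration is uniform on (0.4 s, 0.8 s): the session is paced
at one kick every 2 s, which bounds but does not fix the movement time. Each
kick is additionally passed through a smooth monotone random time warp
(cumulative softplus of a random cubic, peak deviation `warp_sd` = 0.05 of
duration by construction, default 0.02), which produces the temporal
misalignment that time normalization cannot fully remove.

Legs are generated as independent template offsets, not mirror images: all
analyses treat legs separately, so anatomical mirroring would add complexity
without changing any result. Randomness derives from one seed split into
per-subject streams, so a subject's kicks are bit-for-bit reproducible and
invariant to cohort size.

The default effect sizes were chosen once so that the generated data live in
the regime the analysis is designed for: inter-individual waveform CV near
32% with intra-individual CVs near 16–18%, perfect participant separability,
and intra-individual task accuracies well above chance but far from perfect
(set ≈ 60–65%, 27-class block ≈ 25–30%) with the within-set periodicity
visible in the distance profiles. They are choices, not measurements.

What the generator does *not* emulate: marker-level noise and soft-tissue
artifact, inter-joint coupling (variables are drawn independently),
biomechanical constraints (no inverse kinematics, no ground reaction), and
any physiological fatigue signal (no HR/lactate analogue). Passing tests
therefore show that the pipeline recovers structure of this additive kind at
realistic magnitudes; they cannot certify behavior on real recordings.

## Preprocessing

The chain runs filter → segment → time-normalize → z-score → min–max, in
that order.

* **Filter** — Butterworth low-pass, zero phase (forward–backward), stated
  order 6, cut-off 15 Hz. The default `effective` convention designs a
  3rd-order filter per pass and raises the per-pass cut-off by
  1/C, C = (√2 − 1)^(1/(2·3)), so the combined dual-pass response is −3 dB at
  15 Hz (Winter's convention). `per-pass` designs the full 6th order as
  given, for pipelines that read "sixth-order zero-phase" literally.
* **Segmentation** — start: first sample where the forward foot velocity
  (central difference of the filtered position) exceeds `v_min`; end: the
  maximum knee extension at or after the start. The generator emits kicks
  already spanning this phase, so the pipeline applies segmentation only
  when a foot-position channel is present; the segmenter is exercised
  against constructed signals with known events.
* **Time normalization** — 101 points on 0–100% of the kick, piecewise
  linear by default (endpoint-exact, idempotent on the grid); a cubic-spline
  option exists. Linear is the robust default because the warp-induced
  misalignment dominates interpolation error at 101 points.
* **Feature assembly** — the 27 time-normalized variables concatenate to a
  2727-vector per kick. Column order is fixed by a versioned registry
  (variables lexicographic, then grid point), so feature indices are stable
  across runs and stored artifacts.
* **Normalization** — per feature column: subtract the training mean, divide
  by the training population SD (zero-variance columns get SD 1 and a logged
  warning), then map the training range affinely onto (−1, 1). By default the
  statistics are fitted on each cross-validation fold's training rows only
  and applied to its test rows (leakage-safe); `normalize_scope = "global"`
  fits them once on the whole matrix for pipelines that normalize before
  splitting. Whether per-column z-scoring should instead be per variable or
  per kick is underdetermined for this kind of data; per column is the
  package's choice.

## Classification

Four multiclass designs on one (intensity, leg) slice of the features:
participant (one class per subject), and — within one subject — block
(set-major chronological class 3·(set−1)+block, 27 classes), set (9), and
block-within-set (3). The classifier is a one-vs-rest linear-kernel SVM
(liblinear); one-vs-one is a config option since multiclass reductions can
differ slightly.

Cross-validation is **coverage-complete**: test folds partition the task
matrix, so every kick is tested exactly once and each fold's test rows are
evenly distributed over classes. Folds derive from the protocol structure —
leave-one-set-out for the participant and block-within-set tasks (9 folds),
leave-one-time-point-out for participant at K-100 (11 folds), and
kick-index folds for the block and set tasks (fold f tests the f-th kick of
every block; `kicks_per_block` folds). Where published fold-count
annotations for such designs conflict with the tested-exactly-once
guarantee, the guarantee is taken as binding and fold counts follow from
structure.

The SVM cost is selected per outer fold by grid search over
C = 2⁻⁵, 2⁻⁴·⁷⁵, …, 2¹⁵ (81 candidates), scored by 3-fold stratified
inner CV accuracy on the training rows only; ties resolve to the smallest
cost (the least-complex model). Whether the search should be nested per
fold or run once globally is an open choice; nesting is the leakage-safe
reading and is the default here.

Reported metrics are accuracy and macro-averaged F1, precision and recall
(mean ± SD over folds, percent); macro matches the balanced test design. The
pooled predictions yield a row-normalized confusion matrix and, for the
chronologically ordered tasks, a **distance profile**: the proportion of
predictions at each ordinal distance d = |predicted − true|, averaged over
the true classes for which d exists, with an availability-corrected variant
(per-class-at-distance proportion) under which a uniform random classifier
is flat. The d = 0 entry is per-class accuracy; local maxima at d = 3 and 6
in the 27-class block task indicate that the same within-set block index
recurs in neighboring sets.

## Variability

Winter's waveform coefficient of variation for equal-length trials x_i(t):

    CV% = 100 · sqrt( mean_t s_t² ) / mean_t |x̄_t|

with s_t² the between-trial variance (sample, n−1 denominator — the
conventional choice) at grid point t. CV is computed per variable and
averaged (unweighted) over the 27 variables. CVs are computed on the
time-normalized but *unscaled* waveforms by default: z-scoring drives the
mean waveform toward zero and destabilizes the denominator; computing CV on
fully normalized features remains possible by passing such a matrix.

Groupings mirror the classification designs: inter-individual (all kicks of
a leg × intensity pooled across subjects), per (subject, block), per
(subject, set), and per (subject, within-set block index pooled across
sets) — the last giving the 3-level layout of the block-within-set design.

Group comparisons use a normality-gated repeated-measures design with
α = 0.05: if no level rejects Shapiro–Wilk, one-way RM-ANOVA (partial η²;
Greenhouse–Geisser-corrected degrees of freedom when Mauchly's test rejects
sphericity) with paired-t post-hocs and paired Cohen's d; otherwise Friedman
(Kendall's W) with Wilcoxon signed-rank post-hocs and r = |Z|/√n. Post-hocs
run only after an omnibus rejection and are Holm–Bonferroni adjusted
(step-down: adjusted_(i) = max_{j≤i} min(1, (m−j+1)·p_(j))). Degenerate
layouts with zero within-subject variance leave the F ratio undefined and
are treated as no evidence of an effect.

## Numerical and reproducibility notes

* All randomness flows from explicit integer seeds; per-fold grid-search
  shuffles derive from `seed + fold`.
* Linear-algebra reductions are kept single-threaded in the test-suite and
  acceptance entry points (threadpoolctl), since multi-threaded BLAS
  reorders floating-point sums and breaks bitwise run-to-run equality of
  SVM fits.
* CSV artifacts round-trip floats exactly (full-precision writing,
  `float_precision="round_trip"` reading), so reports regenerated from
  stored artifacts are byte-identical.
* Kicks shorter than 2 samples, non-finite waveforms, missing variables and
  out-of-range parameters are rejected at ingest with named errors;
  segmentation failures carry a diagnostic of the velocity threshold.

## Problem sizes used in the shipped checks

The structural checks assemble the full 16-subject protocol (9696 kicks,
4320 × 2727 and 528 × 2727 participant matrices). The classification
behavior checks run on reduced cohorts (1–8 subjects, 3–9 sets, 3–5 kicks
per block) with either the full 81-point cost grid (headline
individual-separability result) or a coarse grid (property checks), chosen
so each check exercises the full pipeline at sizes where the expected
behavior is unambiguous.

## Known limitations

* The generator's additive-Gaussian coefficient model cannot produce
  asymmetric or multimodal trial distributions; non-normal routes of the
  statistics module are exercised with constructed tables instead.
* Real-data accuracies depend on recording specifics (marker model, filter
  interactions, segment definitions) that no synthetic surrogate fixes; the
  package reproduces design behavior and analytic structure, not empirical
  values from any particular cohort.
* The Cardan decomposition flags gimbal proximity (middle angle within 0.5°
  of ±90°) but does not re-sequence automatically.
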