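# Methods

## The fusion rule

`rankfuse` fuses M classifiers' per-class confidence vectors (softmax
outputs; each row normalized to sum to 1 within 1e-6) at the decision
level. Each confidence x is mapped to a fuzzy rank by a re-parameterized
Mitscherlich function

    R(x) = 2 (1 − 2^(x−1)) = 2 − 2^x,

the exponential saturation law of crop-yield response, rewritten as a
decreasing map on [0, 1] with R(0) = 1 and R(1) = 0. Its derivative,
−2^x ln 2, grows in magnitude with x, so the transform is most sensitive
near confident predictions — the region where base models that are all
"fairly sure" must be told apart. The value R(0) = 1 doubles as the rank
penalty P_R; the confidence penalty is P_CoF = 0.

Per classifier and sample, classes are sorted by ascending fuzzy rank
(ties broken by class position) and the k best form that classifier's
top-k set. The fuzzy rank sum FRS_c adds the fuzzy rank where class c is
in the top-k and P_R = 1 where it is not; the complemented confidence
sum CCFS_c is one minus the mean of the included confidences (excluded
terms contribute P_CoF = 0). The final decision score FDS_c = FRS_c ·
CCFS_c is minimized over classes, ties again broken by class order. A
class in no classifier's top-k attains FRS = M, CCFS = 1, hence FDS = M
exactly — the ceiling of the score — and cannot win.

### The CCFS reading

The flattened published equation for CCFS is a plain mean of included
confidences, but that reading is internally inconsistent with the rest
of the rule: its own name says *complement*, its penalty (0, "prevent an
improbable winner") would under a plain mean make an all-zero-confidence
class the argmin winner, and with M = 1 the literal FDS = R(x)·x is
minimized at x = 0. The default here is therefore the complement reading
CCFS = 1 − mean(included CoF), under which the penalty rationale is
true and the M = 1 rule reduces to the model's own argmax (FDS =
R(x)(1−x) is strictly decreasing). The literal reading remains available
as `variant="literal"` for auditability.

### Parameters

- **k** (top-k cut, default 2, range 1..C): how many classes per
  classifier escape the penalties. The source method never states its k;
  k = 2 is the smallest cut that exercises the penalty machinery on a
  3-class task. k = C disables penalties entirely; k = 1 reduces each
  classifier's contribution to its argmax class.
- **P_R = 1, P_CoF = 0**: fixed constants (surfaced in `FusionResult`
  for transparency, not configurable).
- **Row-sum tolerance 1e-6, policy `renormalize`** (default): softmax
  rows saved at limited precision rarely sum to 1 exactly, so deviating
  rows are rescaled with a logged warning; `strict` turns deviation into
  an error. Inputs to the rank transform may overshoot [0, 1] by at most
  1e-9 (clamped); beyond that is a hard error naming the coordinates.

## Baseline rules

Maximum probability (argmax of the per-class max over classifiers),
average probability and sum rule (identical labels, since sum = M ×
mean), majority voting (plurality of per-model argmax labels; ties
broken by highest mean confidence, then class order — the source states
no rule), and a weighted average with weights proportional to each
model's validation accuracy (the simplest reading of weights that "take
only the accuracy metric into account"). Maximum probability is read as
max-over-classifiers-then-argmax.

## Evaluation

Per-class precision, recall and F1 are one-vs-rest from the confusion
matrix; zero denominators yield 0 with a warning (a conservative
convention — any choice here is arbitrary). Headline aggregates are
macro (unweighted) means, which is the convention that reproduces the
published overall cells of both lung-CT test sets; support-weighted
aggregates are reported alongside. Display rounding is 4 decimals, half
away from zero (required so that a macro recall of 0.92945 prints as
0.9295). Reports emit fraction-scaled and percent-scaled views, never
mixing scales in one table.

ROC-AUC is one-vs-rest per class via the rank statistic (ties counted
half, delegated to scikit-learn); a class without both positives and
negatives is reported as undefined (`None`), never 0. For the fused
output, FDS is converted to a "higher is better" score s_c ∝ (max FDS −
FDS_c), normalized per sample — the conversion the source leaves
unstated; any strictly decreasing affine map gives the same AUC.

McNemar's paired test uses the discordant counts b, c: for b + c < 25
the exact doubled-tail binomial p (clamped at 1), otherwise the
continuity-corrected chi-square (|b−c|−1)²/(b+c) on 1 df; b = c = 0 is
reported as degenerate with p = 1. Near b ≈ c the continuity correction
pulls the chi-square p below the exact p = 1; both are then far from any
significance threshold, which is how the regime-consistency test states
the property.

## Synthetic score banks

The generator emulates M softmax classifiers on an imbalanced 2–3-class
CT task. Truth labels are drawn from the class proportions (default the
120/561/416 split of a 1097-sample 3-class test set). For each
sample/model pair a target class is the true class with probability
equal to that model's accuracy (defaults 0.9902/0.9726/0.9945, the base
models' published accuracies), otherwise a wrong class; with probability
`error_correlation` all erring models on a sample share one uniformly
drawn wrong target (correlated failure), otherwise each errs on its own.
The confidence vector is a Dirichlet draw with unit concentration on
every class and `concentration` (default 10) added on the target, i.e.
Dir(1,…,1+κ,…,1): κ = 10 makes the target the argmax with ≳99 %
probability on 3 classes while leaving realistic soft mass elsewhere.
All randomness flows from a single integer seed; identical configs give
byte-identical banks.

What the generator does *not* emulate: calibration quirks of specific
CNN architectures, within-class difficulty structure, and any
image-level correlation beyond the single shared-error mechanism. Tests
passing on these banks therefore show the fusion arithmetic and its
ensemble-gain regime (independent errors, equal accuracies), not
performance on real CT score distributions.

`condorcet_check` operationalizes the ensemble-gain claim: with
independent errors and equal per-model accuracies above chance, the
fused decision is correct on most samples where only a minority of
models errs, so fused accuracy exceeds each base accuracy (asserted as a
seed-pinned regression at n = 5000, accuracy 0.85, 10 seeds — an
empirical property at that scale, not a theorem).

## Numerical and design notes

- The rank-transform endpoints are exact in IEEE arithmetic (2^−1 and
  2^0 are exact powers); an interior clip guards sub-ulp negatives.
- All ties (ordinal ranking, argmin, baseline argmax) break toward the
  first-listed class, making every output deterministic and
  order-stable.
- Class identity at the file boundary is by column label, not position;
  rows are aligned across the M score files by sample id in labels-file
  order, so a reordered or column-swapped file is either realigned or
  rejected, never silently misread.
- Vectorized fusion is validated against a naive scalar transcription of
  the rule (pure-Python loops in the test suite) to 1e-12 on random
  banks up to n = 50, C = 5, M = 4.
- Problem sizes in the test and acceptance runs (simulation n ≤ 5000,
  200 oracle banks) were chosen as the smallest scales at which the
  stochastic properties are stable across seeds.

## Known limitations

- Only the Mitscherlich transform ships; `register_rank_function` is an
  extension point for benchmarking other decreasing transforms, but no
  fitting of transform parameters to data is provided or intended.
- No classifier weighting inside the fuzzy-rank rule, no streaming
  fusion, no stacking/boosting/Choquet-integral fusion.
- The published end-to-end results of the source method depend on
  trained CNNs and external image datasets; this package only ingests
  the score tables such models emit, so those headline numbers are
  reproducible here only at the level of their printed per-class
  arithmetic.
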