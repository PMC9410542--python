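# Methods

## The detection model

`fakefinder` treats each questionnaire as a "document" and each response
value as a "term", transplanting the TF-IDF weighting of information
retrieval to Likert data. For respondent *r*, item *i*, response *v*:

- **TF** — the multiplicity of *v* within *r*'s own questionnaire,
  including item *i* itself (so TF ≥ 1, and a value used once has TF = 1).
  This captures response *style*: a faker pushing many items toward the
  desirable pole repeats the same high value.
- **IDF** — log10(*N*/*n*), where *N* honest reference respondents
  answered the questionnaire and *n* of them gave value *v* to item *i*.
  IDF is 0 iff the value is unanimous (*n* = *N*). Counting is inclusive:
  when a reference member is scored, their own response is part of *n*.

The log base is 10; the continuity correction *n* ← 0.5 for values never
observed in the reference keeps the score finite while making it larger
than that of any observed value. No leave-one-out correction is applied
when scoring members of the reference sample (an option, not the default:
the whole-sample counts are the published convention for this score).

The score is an anomaly index, not a probability: high values mean "this
respondent repeatedly used an answer honest people rarely give here".
Honest respondents on the 10-item Big Five concentrate below a mean
TF-IDF of ~2; dishonest ones reach higher, and a mean above 3 is the
respondent-level faker rule.

## Thresholds

Item-level detection flags a response when its score **strictly** exceeds
a per-item cutoff; ties count as honest. Cutoffs are a single shared
percentile of the per-item honest score distributions (linear-interpolation
percentile; the convention matters because TF-IDF distributions are
heavily tied). The percentile is selected by K-fold (K = 10) cross-
validated grid search over {50, 60, 70, 75, 80, 85, 90, 95, 99, 100}:
per fold, reference counts and cutoffs are fitted on training-fold honest
respondents only and each candidate is scored on the validation-fold faked
responses. The fold unit is the respondent — both administrations of a
person travel together, so nobody's honest data helps set the cutoffs
used to judge their own faked data. The objective defaults to F1
(precision is available); ties go to the lower percentile. The final
cutoff set is refitted on the full honest sample at the winning
percentile. Raw response values run through the identical code path
(`mode="raw"`), forming the distribution-based baseline; since instructed
faking is "faking good" on the recoded scale, the same one-sided
upper-tail rule applies.

## Evaluation conventions

Ground truth comes from paired administrations: a cell is faked iff the
dishonest response differs from the honest one. Positives are faked
cells. Per-respondent accuracy is correct items / total items (so "8/10"
for one person); dataset accuracy is the **macro** mean of per-respondent
accuracies, while precision, recall and F1 pool all cells (micro). The
pooling convention is stated because aggregate numbers depend on it. Any
0/0 metric is reported as 0 with a warning rather than an error, so grid
extremes (nothing flagged, everything flagged) survive a sweep.

Distribution separation is measured per item by KL(dishonest ‖ honest)
with natural log, additive smoothing ε = 1e-6 and renormalisation; raw
responses use one bin per scale value, TF-IDF scores 10 equal-width bins
over the pooled range. These choices (direction, base, binning) are
deliberately fixed and documented because KL values are only comparable
under identical conventions.

Respondent-level odds are the count ratio of faked to honest mean scores
above the cutoff (3.0); odds *o* convert to a probability of dishonesty
as 100·*o*/(1+*o*).

## The simulator

The generator emulates three instructed-faking studies on the 10-item
Big Five (contexts CC, JIS, JIHO), from their published per-item summary
statistics:

- **Honest responses** are independent draws per (respondent, item) from
  a normal distribution discretised onto the scale (bins [v−0.5, v+0.5),
  outer bins absorbing the tails) whose (μ, σ) are solved numerically so
  the *discrete* mean and SD match the context's honest targets within
  0.02. Infeasible targets raise an error naming the feasible SD range.
- **Faking** is per-item independent given the row: with the item's
  empirical faking probability the response is altered; an alteration
  moves toward scale_max with probability `increase_share`
  (increased/(increased+decreased) from the study's direction table:
  0.774 CC, 0.776 JIS, 0.800 JIHO; 0.78 pooled default), else toward
  scale_min, the new value uniform over admissible values strictly beyond
  the current one. At a scale bound the only feasible direction is taken,
  so a drawn alteration always changes the value and the truth table is
  exactly the inequality of the pair.

Design choices made where the data underdetermine the model: alteration
magnitude is uniform rather than jump-to-extreme (the published dishonest
SDs of ~0.7–1.25 rule out everyone choosing 5), and there is no latent
per-respondent faking-intensity trait (only marginal probabilities are
published; a trait model would be invention). Sample sizes mirror the
studies (221/243/230 retained of 258/287/272 enrolled after the
comprehension-check exclusions, which the roster generator reproduces).

**What the simulator does not reproduce.** Inter-item correlations (no
correlation matrix is published), test–retest unreliability of the honest
condition, and the exact observed direction mix: because responses
already at the desirable bound are forced downward when altered, the
realised increased share is ≈41% rather than the observed 48% for CC, and
high-mean items (Q1, Q6) can show slightly *deflated* dishonest means —
both are closed-form consequences of the mechanism and are tested against
that closed form. Passing tests therefore show the pipeline is correct
and directionally faithful (TF-IDF beats the raw baseline in F1 and KL
separation on this synthetic bed), not that real-data performance numbers
are reproduced; those depend on the authors' datasets.

## Numerical and degenerate-input conventions

- Percentiles: NumPy linear interpolation between order statistics.
- Reverse-keyed recoding v ↦ scale_min + scale_max − v is an involution;
  double recoding is rejected, and all scoring requires recoded input.
- Missing or out-of-range responses are load-time errors naming the cell;
  TF is undefined on partial rows, so nothing is imputed.
- Reference models serialise counts (integers); IDF is recomputed on
  load, so serialisation is exact.
- Problem sizes used by the test suite: oracle equivalence on 200 random
  20×10 matrices; calibration comparisons at n = 400 over 5 seeds;
  moment/parameter recovery at n = 2000. The full suite runs in seconds.

## Known limitations

- The score needs a trustworthy honest reference sample from the same
  population; a contaminated reference dilutes IDF and lowers power.
- One shared percentile across items is tuned, not per-item percentiles
  (combinatorial, and not what the method prescribes).
- Scales are integer Likert only; no continuous or free-text responses.
- The faker cutoff of 3.0 was established on 10-item, 5-point data;
  other questionnaire lengths or scales likely need recalibration.
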