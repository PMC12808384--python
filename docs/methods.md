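# Methods

## The scoring model

The Boston Bowel Preparation Scale (BBPS) grades bowel cleanliness per
colon segment from 0 (mucosa unseen behind solid stool) to 3 (entire
mucosa visible), for a 0–9 total over the three segments. `autobbps`
implements an automated, frame-level variant of that assessment: a
per-frame classifier assigns each video frame to one of six categories —
the four cleanliness grades, the ileocecal landmark and instrument
operation — and the engine aggregates those predictions into a single
cumulative score

    score = 9·f3 + 6·f2 + 3·f1,
    f_k = n_k / (N − n_instrument),

where n_k counts counted frames predicted BBPS k and N is the number of
counted frames. The score therefore spans the familiar 0–9 range: 9 when
every counted non-instrument frame is BBPS 3, 0 when none is BBPS 1/2/3.
Note this is a *global* frame-fraction score over the whole withdrawal,
not a sum of three per-segment ratings; segment boundaries are not
detected and per-segment scoring is explicitly out of scope. The two
scales coincide only at the extremes, which is why the analytic
acceptance checks pin exactly those two points.

### Streaming state machine

Scoring is armed by the ileocecal landmark: the first qualifying landmark
observation (confidence ≥ threshold, sustained for `trigger_run_length`
consecutive qualifying frames) sets the trigger, and counting begins with
the *next* frame. After the trigger:

* observations below the confidence threshold are excluded from both the
  numerator and the denominator, and tracked in `below_threshold_count`
  for audit — the threshold exists to keep unreliable predictions out of
  the score, and removing them from the denominator keeps the score a
  proper weighted mean of the frames actually trusted;
* instrument frames are counted but subtracted from the denominator, so
  therapeutic interludes of any length leave the score untouched
  (instrument-invariance is a tested property);
* post-trigger ileocecal frames count in the denominator with weight 0 —
  the formula subtracts only instrument frames.

The engine is a pure fold over the observation stream, so the streaming
trace and a batch recomputation agree identically, and the final score is
invariant to permuting the post-trigger frames.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `confidence_threshold` | 0.80 | minimum per-frame confidence to count a frame (and to arm the trigger); the value the κ-based sweep selects |
| `trigger_run_length` | 1 | consecutive qualifying ileocecal frames required to arm scoring; raise for robustness against isolated false landmark detections |
| `frame_stride` | 1 | process every n-th frame by index; skipped frames touch no counter |
| `strict` | off | raise on out-of-order frame indices and undefined final scores instead of tolerating them |

An undefined score (no countable frame) is a first-class value
(`defined=False`, NaN payload, `--` in displays), never silently 0.

Video-level classes in {0, 1, 2, 3} are assigned by `round(score / 3)`
with halves rounded away from zero (7.5 → 3), clipped to [0, 3]. This
mapping is a repository convention: video-level labels exist in the
evaluation design this package emulates, but no explicit mapping from the
continuous score is prescribed there.

## Preprocessing and augmentation

Inference-time preprocessing is letterboxing alone: scale by
`640 / max(H, W)`, resize to `round(H·s) × round(W·s)` (round half away
from zero — fixed so geometry tests are bit-exact), center on a 640×640
canvas filled with mid-gray (114), odd leftover pixel to the
bottom/right. Aspect ratio is preserved within the half-pixel rounding
envelope.

Training-time augmentation composes, in order: horizontal flip
(p = 0.50) → random resize (shorter side × U[0.90, 1.10], aspect ratio
× U[0.90, 1.10]) → random crop (side ratio U[0.80, 1.00]; proposals whose
realized ratio falls below 0.80 through rounding are rejected and
redrawn) → HSV jitter (hue additive ±0.015 with wrap; saturation and
value multiplicative gains 1±0.70 and 1±0.40, clipped). Two points were
genuinely open and are fixed here as package conventions: the aspect
jitter is a multiplicative factor on the ratio (not on one side), and the
saturation/value jitters are multiplicative gains, matching the semantics
of the YOLO-style built-in the ranges come from. The pipeline is online:
one seeded generator drives all draws, so an epoch's augmented stream is
reproducible without storing augmented images.

## Evaluation metrics

Per-class metrics come from the K×K confusion matrix by one-vs-rest
collapse: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), accuracy (TP+TN)/(TP+TN+FP+FN), F1 the harmonic mean of
precision and sensitivity. Per-class accuracy is one-vs-rest accuracy
(near, but not equal to, overall accuracy). Weighted averages use
support shares as weights, which makes weighted sensitivity identical to
micro accuracy (trace/total) — asserted as an algebraic identity in the
tests. Zero denominators yield 0 plus a `degenerate` flag rather than
NaN, keeping weighted averages defined.

AUC is the trapezoidal integral ½·Σ(FPR₁₊ᵢ−FPRᵢ)(TPR₁₊ᵢ+TPRᵢ) over the
threshold-swept ROC curve with endpoints (0,0) and (1,1); tied scores are
grouped into single threshold steps, which makes the trapezoid equal the
Mann–Whitney pairwise-ranking probability (the test oracle, exhaustive on
small instances). AP is the untruncated step integral of precision over
recall — no 11-point interpolation. Multiclass AUC/AP are one-vs-rest
with the class's confidence as the score.

## Rater agreement and threshold selection

Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal products;
when p_e = 1 both marginals are degenerate on the same label, so the
series agree everywhere and κ is 1 by convention.

The threshold sweep evaluates a grid (default 0.50–0.95, step 0.05).
Sub-threshold predictions *abstain* and are excluded from the agreement
table — mirroring the engine's exclusion rule — with the retained
fraction recorded per threshold. κ is computed on the retained items; the
selected threshold maximizes κ, ties broken by the higher F1 of retained
predictions (precision = correct/retained, recall = correct/total — the
selective-prediction operationalization of a "stable precision–recall
trade-off"), then by the smaller threshold. Whether the original sweep
recomputed κ on all predictions or only retained ones is not documented;
abstention-exclusion is this package's recorded choice.

The 2×2 χ² test compares two correct/incorrect proportions with the
Pearson statistic on 1 df, no Yates correction by default (configurable);
p-values via `scipy.stats.chi2.sf`.

## Synthetic data

The generator emulates the system's input regime, not colonoscopy
imagery: a post-ileocecal frame stream with a cleanliness mix
(g0, g1, g2, g3), instrument interludes at a given rate, one landmark
frame, and a two-band confidence model (correct predictions ~N(0.95,
0.02), incorrect ~N(0.55, 0.10), clipped to [0, 1]) chosen so the
confident/hesitant split gives the threshold sweep something to optimize;
no confidence distributions are prescribed anywhere, so these bands are a
package convention. Class fractions are realized by largest-remainder
rounding by default, so the planned score 9·g3 + 6·g2 + 3·g1 is hit
exactly (not just in expectation) at zero noise — the basis of the
machine-precision recovery tests. Classifier noise flips post-trigger
cleanliness frames to a different cleanliness grade; it never forges
landmark or instrument detections, so noise cannot trigger scoring early
(an early false trigger would change the *task*, not just add error).

Toy videos carry the category in a reserved solid border hue (six hues
60° apart, so the ±0.015-turn hue jitter can never cross cells) and the
confidence in a 2-px grayscale ring; the oracle classifier inverts the
encoding exactly on unaugmented frames, giving an end-to-end
video → classify → score path with known ground truth. The codec-free
containers are PNG frame directories and multi-frame TIFF stacks;
`.mp4`/`.avi` require an ffmpeg-backed imageio plugin and fail with an
explicit error naming the container when none is present.

The default 94-video panel reproduces the (11, 26, 28, 29) class
composition of the video evaluation set this design targets; each video's
fractions are drawn from a class-biased Dirichlet and accepted only when
the realized exact-count score maps to the assigned class with a 0.05
margin from the rounding boundaries, so zero-noise engine runs recover
every label.

What passing these tests shows — and does not. The synthetic streams
validate the aggregation algebra, the trigger logic, the exclusion rules
and the metric/agreement implementations exactly. They say nothing about
real-frame classification difficulty: real confidence distributions are
not two clean bands, landmark detection can be ambiguous, and cleanliness
varies within a withdrawal in ways a stationary mixture does not capture.
Headline accuracies of any trained model are out of scope here.

## Numerical choices and problem sizes

Rounding half away from zero everywhere a display or geometry rule needs
a fixed convention; top-k ties broken by fixed vocabulary order; category
labels parsed case-insensitively with lowercase "instrument" canonical.
The test suite's simulation sizes (1,000 random streams of ≤ 50 frames
for the engine oracle; 500 instances of ≤ 20 samples for the AUC oracle;
1,000 independent-rater pairs of 1,000 items; 100 recovery specs at 100
counted frames; 10,000 augmentation draws) keep the whole suite within a
few seconds while leaving the statistical checks at 3–4 standard errors
of slack.

## Known limitations

* Global frame-fraction score; no right/transverse/left segmentation.
* The classifier seam ships with the synthetic oracle only; plugging in a
  real exported model is an adapter exercise (letterbox to 640, emit a
  six-float vector) left to the user.
* Frame streams are assumed index-ordered; non-strict mode tolerates but
  does not reorder out-of-order input.
* The annotated-video exporter writes PNG frame directories; encoded
  video output needs an ffmpeg plugin in the environment.
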