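# autobbps

Automated, streaming **Boston Bowel Preparation Scale (BBPS)** scoring for
colonoscopy video — the aggregation engine, evaluation suite and synthetic
test bed around a pluggable per-frame classifier.

Bowel cleanliness determines how much mucosa a colonoscopist can actually
inspect, and the BBPS (0 = mucosa unseen behind solid stool … 3 = entire
mucosa visible, summed 0–9) is the standard way to report it. Scoring is
usually done from memory after the procedure, which makes it subjective and
inconsistent between raters. `autobbps` implements the automated
alternative: a classifier labels every frame as one of six categories
(BBPS 0–3, the ileocecal landmark, instrument operation), and the engine
turns that stream into an objective, real-time cumulative score. The
package is for engineers and researchers building or evaluating such
systems: everything is exercisable without clinical data or a trained
model, through a synthetic-data module and an oracle classifier.

## The model

Scoring arms when the ileocecal landmark is detected (confidence ≥ the
threshold, default 0.80) and counts every subsequent frame. With n_k the
number of counted frames predicted BBPS k and N the total counted:

    score = 9·f3 + 6·f2 + 3·f1,    f_k = n_k / (N − n_instrument)

Instrument frames are subtracted from the denominator, so therapeutic
interludes never move the score; frames below the confidence threshold are
excluded from numerator and denominator alike and tracked for audit. The
score spans 0–9: exactly 9 when every counted non-instrument frame is
BBPS 3, exactly 0 when none is BBPS 1/2/3. Video-level classes {0,1,2,3}
are assigned by `round(score/3)`, half away from zero.

Alongside the engine: the letterbox-to-640 preprocessing and the
flip/resize/crop/HSV augmentation pipeline with their exact parameter
ranges; one-vs-rest sensitivity/specificity/precision/accuracy/F1 with
support-weighted averages, trapezoidal AUC and step-integral AP; Cohen's κ
with the 0.50–0.95 confidence-threshold sweep (κ-maximizing selection, F1
tie-break) and the 2×2 χ² accuracy comparison. See `docs/methods.md` for
the full account of conventions and assumptions.

## Worked example

Generate a 241-frame toy video (landmark at frame 0; cleanliness mix
10/20/30/40 % of BBPS 0/1/2/3; 20 % instrument interludes; 5 % classifier
noise), then score it through the built-in oracle classifier:

```
$ cat spec.yaml
n_frames: 241
fractions: [0.1, 0.2, 0.3, 0.4]
instrument_rate: 0.2
ileocecal_at: 0
classifier_noise: 0.05
seed: 7

$ autobbps simulate video --spec spec.yaml --out vid
video at vid, ground-truth score 6.0156

$ autobbps score vid --report report.json --trace trace.csv
final score: 6.05  (video class 2)
```

`report.json` (abridged):

```json
{
 "final_score": 6.049450549450549,
 "video_class": 2,
 "counts": {"BBPS 0": 19, "BBPS 1": 34, "BBPS 2": 54, "BBPS 3": 75,
            "ileocecal part": 0, "instrument": 48},
 "total_counted": 230,
 "below_threshold_count": 10,
 "frames_seen": 241
}
```

Reading: of 241 frames, the landmark armed scoring at frame 0; 48
instrument frames were counted but excluded from the denominator
(230 − 48 = 182 scoring frames) and 10 low-confidence frames were excluded
entirely — most of those are the noisy mislabeled frames, whose hesitant
confidences fall under the 0.80 threshold. The resulting 6.05 sits within
0.04 of the stream's ground-truth score 6.0156 despite 5 % label noise,
and maps to video class 2. With `classifier_noise: 0` the engine
reproduces the planned score 9·0.4 + 6·0.3 + 3·0.2 = 6.0 exactly.

The trace CSV gives the running score per frame for the real-time display
path, and `--out DIR` writes annotated frames (category, confidence,
running score overlay). Other subcommands: `autobbps evaluate` (metric
report from truth/prediction CSVs), `autobbps sweep` (κ-based threshold
selection), `autobbps predict` (top-5 report for a single image),
`autobbps simulate stream|video|panel`.

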