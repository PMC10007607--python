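# affectstream

Streaming emotion classification from consumer-grade EEG.

`affectstream` is a library and CLI for classifying a person's affective
state — binary *valence* (unpleasant/pleasant) and *arousal*
(calm/excited) — from a live multichannel EEG stream, the way a
real-time application must: one sample at a time, with incremental
classifiers that predict before they see a label, and with labels that
may arrive minutes late.

It is aimed at affective-computing and physiological-computing
researchers who want a reproducible streaming baseline: the whole
pipeline runs on plain CSV recordings from wearable headsets (Muse S,
Neurosity Crown, Emotiv EPOC profiles are built in) and ships a seeded
synthetic session generator, so every experiment here is runnable with
no external data.

## The pipeline

1. **Preprocess, per tumbling window** (length `l` seconds, `l × sf`
   samples, no overlap): 2nd-order IIR notch at 50 Hz, 5th-order
   Butterworth band-pass 0.5–45 Hz, common average reference.
2. **Featurize**: per channel, Welch-PSD band powers for Delta
   (0.5–4 Hz), Theta (4–8), Alpha (8–16), Beta (16–32), Gamma
   (32–45), the total power, and the 10 pairwise band-power ratios —
   16 features per channel, i.e. 64 / 128 / 224 per window for the
   4- / 8- / 14-channel profiles.
3. **Label**: unit-scale ratings per stimulus, thresholded at 0.5 into
   low/high; a window inherits the label of the stimulus interval that
   wholly contains it.
4. **Learn online**: logistic regression by single-sample SGD
   (`w ← w + 0.1 (y − p) x`), or drift-aware Hoeffding-tree ensembles
   (adaptive-forest and random-patches variants).
5. **Evaluate prequentially**: test-then-train — each window is
   classified before its label is used for training, with

   ```
   Accuracy = (TP + TN) / (TP + TN + FP + FN)
   F1       = TP / (TP + (FP + FN)/2)
   ```

   tracked cumulatively (macro F1 averages the high-positive and
   low-positive views). In the *delayed* protocol, predictions are
   buffered and scored only when their stimulus's label arrives, then
   the model is updated — with zero delay this reduces exactly to
   ordinary test-then-train.

See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

Evaluate a synthetic Muse S subject (16 videos, balanced
valence–arousal quadrants, labels delivered after each video) in the
immediate-label setting with online logistic regression, 5 shuffle
repeats:

```sh
cat > demo.yaml <<'EOF'
device: muse_s
seed: 7
learner: {kind: lr}
evaluation: {repeats: 5, dimensions: [valence, arousal]}
EOF
affectstream run-immediate --config demo.yaml --out demo_run
```

which prints (abridged):

```
valence  mean_macro_f1=0.996  sd=0.003  mean_accuracy=0.996
arousal  mean_macro_f1=0.738  sd=0.018  mean_accuracy=0.740
```

The generator plants the valence classes in the alpha band and the
arousal classes in the beta band (amplitude ×1.6 vs ×0.625). Valence is
recovered almost perfectly; arousal is harder for a linear model here
because the beta effect overlaps the broadband 1/f noise more, so its
macro F1 sits lower — the gap between the two dimensions is a property
of this synthetic subject, not of the protocol. `demo_run/metrics.json`
holds per-repeat values; `demo_run/run_meta.json` records config hash,
seeds and versions for reproduction.

Other verbs: `affectstream profiles` (list devices), `synth` (write a
synthetic subject's recording/label CSVs + ground truth), `featurize`
(labeled feature table), `run-sweep` (window lengths 1–5 s),
`run-delayed` (two-part live protocol, or `--induced` fixed label lag,
e.g. 86 windows). Every verb takes `--config`, `--seed`, `--out`.

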