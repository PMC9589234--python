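# eegdep

Resting-state EEG screening for depression, rebuilt as a reusable,
tested Python pipeline. The package targets researchers who want to
study — or stress-test — the popular "EEG → image → CNN" diagnostic
recipe without access to clinical recordings: every stage, from raw
19-channel EEG to cross-validated diagnostic metrics and
questionnaire-score correlations, runs end-to-end on a seeded
synthetic cohort.

## What it implements

- **Synthetic cohorts** (`eegdep.synth`): 19-channel eyes-closed EEG
  (10–20 montage, 500 Hz) as pink noise plus an occipitally dominant
  alpha rhythm, with eye blinks, 50 Hz line noise, high-amplitude
  artifact epochs and dead channels; a controllable between-class
  frontal alpha asymmetry (left-frontal alpha scaled by
  exp(−effect·severity/2)); and questionnaire scores (SDS, SAS,
  SCL-90, EPQ) tied monotonically to a latent severity, with
  SDS ≥ 73 defining major depression.
- **Preprocessing** (`eegdep.preprocess`): zero-phase FIR bandpass
  0.5–50 Hz + 50 Hz notch, 2 s epochs, bad-electrode detection and
  spherical-spline interpolation, extended-infomax ICA blink removal,
  ±70 µV epoch rejection, the ">50% effective segments" screening
  rule, and EDF export of the cleaned signal.
- **Feature maps** (`eegdep.featuremap`): non-overlapping 10 s
  windows rendered as square grayscale images (0 µV → mid-gray,
  ±70 µV saturating), 60 per 600 s recording, written as PNG with a
  manifest.
- **CNN** (`eegdep.cnn`): three conv + two max-pool + three FC layers
  ending in a sigmoid *AI score* in [0, 1]; dropout and L2 on the FC
  layers; SGD training with per-epoch train/validation accuracy and
  optimal-epoch selection. Implemented directly on NumPy with
  verified backpropagation — no deep-learning framework required.
- **Evaluation** (`eegdep.evaluation`): ten stratified 64/16/20
  train/validation/test splits at image or subject level, confusion
  matrices, accuracy/precision/recall/F1, and Mann–Whitney AUC with a
  bootstrap 95% CI.
- **Statistics** (`eegdep.stats`): per-subject AI scores, Spearman
  correlations against the scales, and normality-gated group tests.

A key methodological point the package makes explicit: image-level
splitting (the protocol that reproduces the reference cohort's image counts)
places windows of the same subject in both train and test sets.
A `unit="subject"` mode is provided for leakage-free estimates.

## Worked example

```python
from eegdep import (GeneratorConfig, generate_cohort,
                    preprocess_recording)
from eegdep.featuremap import make_feature_maps

cfg = GeneratorConfig(n_healthy=2, n_nonmajor=1, n_major=1,
                      duration_s=120.0, seed=7)
recordings, roster = generate_cohort(cfg)
print(roster[["subject_id", "group", "sds"]].head(4))
res = preprocess_recording(recordings[0], seed=7)
print(res.report)
print(len(make_feature_maps(res.effective, size=100)), "feature maps")
```

prints

```
  subject_id      group        sds
0       h001    healthy  34.836388
1       h002    healthy  40.761744
2       n001  non_major  67.686764
3       m001      major  77.926217
```

— the major-depression subject's SDS is ≥ 73 by construction —

```
ScreeningReport(subject_id='h001', n_epochs_total=60,
    n_epochs_effective=54, bad_channels=[],
    n_ica_components_removed=1, included=True,
    effective_fraction=0.9)
10 feature maps
```

i.e. one blink component removed by ICA, 54 of 60 epochs surviving the
±70 µV rule (> 50%, so the recording is included), and the 108 s of
effective signal yielding 10 ten-second feature maps.

The full pipeline — synth → preprocess → featurize → train →
evaluate → correlate — runs from one seed:

```bash
eegdep run-all --out runs/demo --demo --seed 7
```

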