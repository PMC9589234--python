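# Methods

`eegdep` re-implements, as a tested pipeline, a resting-state-EEG
screening workflow for depression: 19-channel eyes-closed EEG is
cleaned and screened, cut into 10 s windows rendered as grayscale
images, and classified by a small convolutional network whose sigmoid
output — the *AI score* in [0, 1] — feeds diagnostic metrics and
correlations with questionnaire severity scales. Because no clinical
recordings ship with the package, a seeded synthetic cohort generator
provides data with the statistical structure the analysis assumes.

## Synthetic cohort generator

Each subject carries a latent severity in [0, 1], drawn uniformly
within a group band (healthy 0–0.25, non-major 0.35–0.58, major
0.70–0.98). Questionnaire scores are bounded linear maps of severity
plus Gaussian noise, clipped to instrument ranges: SDS = 25 + 75·s
(noise SD 2), SAS = 30 + 45·s (SD 4), nine SCL-90 subscales
1.3 + 3.2·s (SD 0.3, clipped to 1–5), EPQ-N 30 + 45·s (SD 6); EPQ
E/P/L are severity-independent. A subject is labelled *major
depression* exactly when SDS ≥ 73, and the generator clips the drawn
SDS to the labelled side of the threshold so the label and score never
disagree.

Signals are synthesised per channel as pink (1/f) background noise
plus a band-limited 8–13 Hz alpha rhythm with regional gains
(occipital 2×, parietal 1.5×, frontal 0.6–0.7×, frontopolar 0.5×).
Default amplitudes are 5 µV RMS background and 8 µV RMS baseline
alpha, i.e. an alpha-dominant eyes-closed record in which frontal
alpha carries roughly half the frontal variance; this is what makes
the injected class effect detectable at the per-window level, and it
is within the textbook range for eyes-closed adult EEG (occipital
alpha here ≈ 45 µV peak-to-peak).

The between-class effect is frontal alpha asymmetry: left-frontal
channels (FP1, F3, F7) have their alpha amplitude multiplied by
exp(−effect_size·severity/2), so the F3/F4 alpha log-power ratio
shifts by −effect_size·severity. Nuisance components are eye blinks
(300 ms biphasic pulses, 90–130 µV, projected mainly to FP1/FP2, 10
per minute by default), a 50 Hz line sinusoid (5 µV), high-amplitude
artifact bursts covering 5% of 2 s epochs, and dead (flat) channels
with probability 0.03 per channel. Every output is a pure function of
`(config, seed, subject_id)`.

What the generator does *not* emulate: volume conduction and
inter-channel correlation structure, non-stationarity, inter-subject
trait variability beyond severity, muscle/ECG artifacts, eyes-open
data. Passing tests therefore demonstrate that the pipeline machinery
recovers a planted, physiologically-motivated effect — not clinical
validity on real EEG.

## Preprocessing

The chain runs in a fixed order: (1) zero-phase FIR bandpass
0.5–50 Hz (Hamming window, automatic transition widths, as in common
EEGLAB defaults) plus a 48–52 Hz FIR band-stop; (2) segmentation into
non-overlapping 2 s epochs from t = 0, remainder dropped (600 s →
300 epochs); (3) bad-electrode detection — flat channels
(variance < 1e−12 µV²) or robust log-variance outliers
(median/MAD z > 5) — followed by spherical-spline interpolation at
standard 10–20 positions; recordings with more than half the montage
bad are excluded; (4) extended-infomax ICA with a fixed seed;
components whose source correlates with the FP1/FP2 mean at |r| ≥ 0.8
*and* whose mixing weights are ≥ 2× stronger on FP1/FP2 than
elsewhere are zeroed (eye blinks); (5) automatic rejection of epochs
with any sample strictly exceeding ±70 µV; (6) screening: a recording
is included only if strictly more than 50% of its epochs survive;
(7) kept epochs are concatenated, re-filtered as in (1), and exported
to EDF (16-bit, ±200 µV physical range — headroom above the rejection
threshold).

Effective segments are counted after the full chain (the alternative —
counting before ICA — is not implemented). On clean synthetic data the
inclusion rate is 100%, although individual epochs can still cross
±70 µV through Gaussian tails.

## Feature maps

Each cleaned recording is cut into non-overlapping 10 s windows
(600 s → 60 windows). A window's 19 × (10·fs) amplitude matrix becomes
a square grayscale image (400×400 by default): nearest-neighbour
replication across channels, linear interpolation along time, then the
symmetric intensity map pixel = ⌊(amp + clip)/(2·clip)·256⌋ clipped to
0–255 with clip = 70 µV, so 0 µV is mid-gray (128) and ±70 µV
saturates. Negating a window complements the image except on the
measure-zero lattice of exactly representable midpoints. Images are
written as 8-bit PNG with a manifest CSV (subject, group, window,
path).

## CNN

The default network follows the reference architecture census: three
convolutions (11×11×128 stride 4; 5×5×256; 3×3×256), max-pooling
(2×2, stride 2) after the first two, and three fully connected layers
(256, 64, 1) with a sigmoid output. Unstated details were fixed as:
ReLU activations, binary cross-entropy loss, SGD with momentum 0.9,
He initialisation, dropout (0.5) and L2 weight decay (1e−4) on the
fully connected layers only, batch size 32, 20 epochs, learning rate
1e−4 (a 1e−3 variant is reachable through the config). The 11×11
first-layer stride of 4 follows the AlexNet convention — an 11×11
stride-1 convolution with 128 filters over a 400×400 input is not
computable in reasonable time or memory on a CPU. The network is
implemented directly on NumPy (im2col convolutions, manual
backpropagation, numerically verified against finite differences);
training and scoring are deterministic given the seed.

Per-epoch training and validation accuracies are recorded; the
*optimal epoch* maximises min(train, val) by default (an
argmax-of-validation rule is available), ties resolving to the
earliest epoch, and the selected epoch's weights are retained.

For CPU-scale demonstrations a reduced configuration
(`reduced_training_config`) uses 100×100 inputs, 8/16/16 filters,
32/16 FC units, Adam (lr 1e−3), dropout 0.25 with L2 1e−3 on the FC
layers, and label-preserving augmentation (random circular
time-shift, amplitude sign flip, time reversal — all exact symmetries
of the generator's signal model). The augmentation prevents a small
network from memorising individual noise realisations instead of
learning the amplitude texture that carries the class signal;
adaptive optimisation is needed because the discriminative feature is
second-order (row-band energy) and its gradient signal is weak at
small sample sizes. The explicit regularisation matters for the null
control too: a model that overfits pure-noise training images scores
systematically *below* chance on the held-out remainder of a finite
image pool (the split parts of a zero-covariance sample are
negatively dependent), and dropout plus weight decay keeps that bias
small. Optional batch normalisation exists in the config but is off
by default.

## Evaluation

Splitting follows the reference protocol: ten stratified random
splits, 80/20 train/test at the image level, with a further 80/20
train/validation split inside the training set (64/16/20 overall).
Image-level splitting reproduces the reference cohort's image counts exactly
(3720 images → 1440/1536 train and 360/384 test for diagnosis;
768/192 per class for severity) but places windows of the same
subject in both train and test; a subject-level mode removes this
leakage and is the right choice when estimating generalisation to new
subjects.

Metrics are the confusion-matrix definitions (accuracy, precision,
recall, F1 = 2TP/(2TP+FP+FN)) at threshold 0.5 with score = 0.5
counting as positive. AUC is the Mann–Whitney pair-concordance
statistic (ties ½), verified in tests against brute-force pair
counting; its 95% CI is a seeded stratified bootstrap (2000
resamples, percentile). Per-fold and pooled-over-folds results are
both reported, since either convention is defensible.

## Statistics

Image AI scores aggregate to one score per subject by the mean
(median available). Spearman rank correlations (average-rank ties,
two-sided p) relate subject AI scores to each scale. Group contrasts
use Welch-free independent t-tests when both groups pass Shapiro–Wilk
at α = 0.05, otherwise Mann–Whitney U; categorical variables use
chi-squared without continuity correction. No multiplicity correction
is applied by default.

## Problem sizes in the shipped checks

The test suite and the acceptance script use a reduced demonstration
for the end-to-end effect-recovery and null-control runs: the full
30/16/16 cohort with 120 s recordings at 12 windows/subject rendered
at 100×100 (744 images), a strong injected effect (effect_size 3) for
the effect arm and effect_size 0 for the null arm, the reduced
training configuration, and two 64/16/20 splits of the image-level
protocol with test scores pooled. Sample size is the binding constraint for
convolutional texture learning here — with ~150 training images the
network plateaus near AUC 0.75 regardless of effect strength, while
the 744-image cohort recovers a strong effect cleanly — so the
demonstration keeps the cohort full-size and reduces recording
length, image resolution and fold count instead. These sizes are the
package's chosen balance
between statistical resolution and a single-CPU runtime of a few
minutes; the full-size protocol (62 subjects, 600 s, 400×400, 10
folds) is available through the same APIs and the `eegdep run-all`
CLI.

## Known limitations

- The generator's spatial structure is per-channel independent noise;
  spherical-spline interpolation is therefore tested on synthetic
  smooth fields rather than on generator output.
- With ~10² training images the CNN operates far below the
  sample sizes convolutional texture learning normally needs; the
  reduced demonstration quantifies effect recovery relative to a null
  control rather than approaching the information-theoretic ceiling.
- EDF export quantises to 16 bits over ±200 µV (≈0.006 µV steps);
  round-trips are exact to that resolution only.
- Two candidate learning rates (1e−3 and 1e−4) are exposed; the
  default is 1e−4.
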