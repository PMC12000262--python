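# Methods

`ceusnine` implements a nine-input deep-learning pipeline for classifying
focal liver lesions from multi-phase contrast-enhanced ultrasound (CEUS)
series, together with a synthetic phantom generator that makes every stage
trainable and testable without clinical data. This note records the models,
the defaults and why they were chosen, and what the synthetic experiments do
and do not demonstrate.

## The classification problem

A Sonazoid CEUS examination of a liver nodule yields eleven still frames:
pre-injection B-mode, six arterial-flow (AF) frames from the 20–40 s window,
and single frames at 1, 2, 5 and 10 min (the 10-min "Kupffer" phase). The
three diagnostic classes — benign, hepatocellular carcinoma (HCC), and
non-HCC malignant — differ chiefly in washout timing: benign nodules sustain
enhancement beyond 5 min, HCCs wash out mildly from around 2 min, and
non-HCC malignancies (metastases, ICC) wash out markedly within 1 min.
Because washout timing is the signal, a classifier that sees many time
phases at once should beat one that sees at most three; that architectural
comparison is what the package operationalizes.

## Phantom model

### Time–intensity kinetics

The field reports these kinetics qualitatively, so the generator uses a
minimal parametric form (linear, pre-log-compression intensity units):

- parenchyma: `P(t) = Pb + Ap · (1 − exp(−(t − ta)/τp))` — saturating
  wash-in to a sustained plateau (Sonazoid parenchymal enhancement persists
  well beyond 10 min);
- lesion: `L(t) = Lb + A · w(t) · d(t) + g`, with wash-in
  `w(t) = 1 − exp(−(t − ta)/τin)` and washout factor `d(t) = 1` before
  `washout_onset`, decaying exponentially (time constant `washout_tau`)
  to the floor `1 − kupffer_defect` afterwards.

`g` (`artifact_gain`) models the residual tissue-harmonic brightness of
nodules hyperechoic before injection: it adds to the lesion at **every**
phase including pre-injection B-mode, and at 10 min it pushes the washout
score back toward iso/hyper — the artifact that makes B-mode frames
diagnostically useful in combination with Kupffer-phase frames.

Defaults: `Lb = 24`, `Pb = 30`, `ta = 15 s`, `τin = 5 s`, `τp = 3·τin`,
`A = 116`, `Ap = 110`. These were fixed once so that (a) all classes show
arterial-phase hyperenhancement, (b) a benign lesion is exactly iso at late
phases, and (c) the pre-injection lesion is mildly hypoechoic and —
critically — *identical across classes*, so nothing before contrast arrival
carries class information.

### Class priors

Washout parameters are drawn per case from class-conditional priors with
±20 % lognormal jitter (σ = ln 1.2):

| class | washout onset | washout τ | Kupffer defect |
|---|---|---|---|
| benign | ∞ (never) | – | 0 |
| HCC (typical, 85 %) | 120 s | 300 s | 0.6 |
| HCC (atypical, 15 %) | 40 s | 60 s | 0.8 |
| non-HCC malignant | 40 s | 60 s | 0.9 |

The HCC prior is a mixture: a 15 % atypical fraction draws metastasis-like
fast washout, mirroring the clinically documented minority of HCCs that wash
out within 1 min and would be scored LR-M. This keeps the class boundaries
realistically imperfect, reproduces the ordinal structure of the washout
count table (non-HCC > HCC > benign at every phase, fractions non-decreasing
in time), and caps attainable accuracy below 100 % the way clinical data
does. Amplitude jitter uses one shared gain factor for lesion and parenchyma
(dose/system gain) plus a small (2 %) independent lesion factor; fully
independent amplitude jitter would make benign late-phase ratios wander far
from iso, which contradicts the defining behaviour of the benign class.

One deliberate simplification: the clinical washout table shows a
*non-monotone* benign column (more benign washout at 2 min than 5 min); the
phantom's benign class is clean (never washes out), so its table is
monotone by construction.

### Rendering

Each phase is rendered as a lesion disk on a uniform parenchyma background,
multiplied by unit-mean Rayleigh speckle (`speckle_scale` interpolates
between noise-free and fully developed speckle), log-compressed over a
63 dB display dynamic range (the scanner setting of the source protocol)
against a fixed 200-unit full scale, and quantized to 8 bits. Rendering is
bit-deterministic given the case seed. The six AF frames sit at
20/24/28/32/36/40 s.

What the phantom does **not** emulate: depth-dependent attenuation and
focusing, respiratory motion, heterogeneous parenchyma texture, partial-
volume lesion boundaries, vendor post-processing. Tests passing on phantoms
therefore demonstrate that the pipeline's machinery is correct and that the
architecture can exploit washout timing — not that the printed clinical
accuracies would be reproduced on patients.

## Assembly

- **ROI**: square window, side = round(1.5 × lesion diameter), constant
  within a case, shifted (never padded) at frame edges to preserve speckle
  statistics.
- **Phase selection** (nine slots, time-ordered): B-2m uses all nine
  available datasets; B-1m duplicates B-mode; B-AF triplicates it (the
  duplication rule extended to the next-shorter limit, where the source
  protocol is silent); B-5m/B-10m drop one/two AF frames uniformly at
  random, seeded per case. The degenerate limit "B" ([B]×9) is also
  accepted for completeness.
- **Packing**: slots 3k..3k+2 become the channels of pseudo-RGB image k;
  the (3, H, W, 3) stack is the unit on which augmentation operates.
- **Resize**: bilinear to the configured input side; the default follows the
  source protocol's printed 244 (not the conventional 224); experiments here
  use 64.
- **Splits**: stratified 10-fold cross-validation at case level with an 8:2
  stratified train/validation sub-split; the sub-split falls back to plain
  random when the validation part cannot hold one case per class.

## Synchronized augmentation

One transform — zoom U[0.8, 1.2], horizontal/vertical flips Bernoulli(0.5),
shifts U[±10 %] of the side, rotation U[±15°] — is sampled per training
example and applied identically to all nine slices (bilinear resampling,
constant-black fill, matching the non-insonified background). Synchrony is
exact: stack-wise application equals slice-wise application pixel for pixel.
Augmentation touches training batches only.

## Classifier

Three weight-independent CNN branches consume the three pseudo-RGB images;
each branch ends in a fully-connected layer (width 256 by default, 64 in the
desk-scale experiments — the source figure's widths are not recoverable);
the three outputs are concatenated and mapped to a 3-class softmax head.
The reference model is the identical single-branch network fed one
pseudo-RGB image (for the B-mode-only condition, the B frame replicated on
all three channels, the only option a 3-channel input leaves for one phase).

Two backbones are defined. `resnet50-transfer` denotes the transfer-learning
configuration of the source protocol; building it requires a deep-learning
runtime with pretrained ResNet50 weights, which this package intentionally
does not bundle, so requesting it raises with a clear message. `small-cnn`
(default) is a from-scratch numpy network: a 2×2 mean-pool stem (the
diagnostic signal is low-frequency contrast, so early downsampling is
free), three 3×3 conv + ReLU + 2×2 max-pool blocks (8/16/32 channels),
global average pooling, and the per-branch FC layer. Inputs are standardized
inside the model ((x − 0.875)/0.1, the nominal mean/spread of rendered
phantoms on the [0, 1] pixel scale); without centering, optimization stalls
on the large DC offset. Analytic gradients are verified against central
finite differences in the test suite.

Training: minibatch Adam, categorical cross-entropy, validation loss
monitored each epoch with best-validation weights restored at the end.
`TrainConfig` defaults mirror the source protocol (batch 32, 600 epochs,
10 folds, Adam 1e-4). The desk-scale experiment protocol — used by all
tests and by the acceptance script — overrides this to 40 epochs at Adam
3e-3 on 64×64 inputs, one cross-validation fold per run; 3e-3 was chosen
over 2e-3 because it escapes the early loss plateau reliably across seeds.
Problem sizes: 100 phantoms per class, 270 training / 30 held-out test
cases per fold.

## Evaluation

- Per-class correct rates are the table rows; the "Average" row is their
  class-size-weighted mean (weights 48/78/55 in the source cohort; the
  unweighted mean is available behind a flag). Numeric reconstruction of the
  printed tables identifies the weighted form as the one used.
- Merging HCC and non-HCC into "malignant" leaves the benign row untouched,
  so binary specificity ≡ the benign per-class rate (an exact identity,
  tested over random matrices), and binary sensitivity ≥ the size-weighted
  mean of the two malignant per-class rates, since cross-misclassification
  among malignant classes still counts as binary-correct.
- Observer-study totals use 133 malignant / 49 benign, the combination that
  reconciles the printed observer accuracies; the source's own tables
  disagree between 48 and 49 benign (181 vs 182 total) and both are
  supported via the class-sizes option.
- Reported percentages round half-up to one decimal, matching the printed
  cells.
- ROC analysis uses the empirical curve over all rating thresholds; the
  cutoff maximizes the Youden index (sensitivity + specificity − 1), ties
  broken toward higher specificity; AUC by trapezoid. A brute-force
  all-thresholds oracle in the test suite cross-checks every random
  instance.
- Washout scoring: per phase, the ratio of mean lesion-disk to mean
  parenchyma intensity is computed in the *linear* domain (pixels inverted
  through the display mapping; the lesion mask is shrunk to 0.8× and the
  parenchyma taken outside 1.3× the lesion radius to avoid boundary
  mixing); hypo if r < 1 − δ, hyper if r > 1 + δ, else iso, with δ = 0.10 by
  default (the observer study states no numeric threshold). "Washout" at a
  phase means hypo. The AF phase is scored on the last AF frame.

## What the phantom experiments show

On the default cohort (100/class, identical B-mode statistics), the
nine-input small-cnn model reaches ≈ 93–97 % held-out accuracy at the
B-10m limit, while the B-mode-only reference stays statistically
indistinguishable from chance — the mechanism behind the source's
nine-input vs single-input comparison. Median held-out accuracy over three
seeds rises monotonically across time limits B-AF → B-1m → B-2m → B-5m →
B-10m (≈ 0.33 → 0.55 → 0.63 → 0.93 → 0.95 in a representative run),
because each later limit adds washout information. The residual errors are
dominated by atypical fast-washout HCCs predicted as non-HCC malignant —
the same confusion the clinical data exhibits.

## Known limitations

- No GPU path and no transfer learning: the numpy backbone is desk-scale by
  design; absolute accuracies are not comparable to the clinical study.
- The phantom's kinetic curve forms and amplitudes are invented; only the
  ordinal washout structure is calibrated.
- Single lesion per frame, no motion: the "six AF frames" are redundant in
  a way clinical AF frames are not.
- Statistical model comparison between classifiers (beyond the binomial
  chance test) is out of scope.
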