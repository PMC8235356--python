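# Methods

## Problem

Patient–ventilator asynchrony (PVA) is a mismatch between the breath
phases delivered by a mechanical ventilator and the patient's own
respiratory effort. Two event types dominate clinical recordings and are
the targets here:

* **Double triggering (DT).** The patient's inspiratory effort outlasts
  the ventilator's set inspiratory time; a second breath is triggered
  within a short window after the first cycles off, before exhalation
  completes. The hallmark is *breath stacking*: the second breath starts
  at nonzero lung volume. A DT event is counted as two consecutive
  breaths, both labeled DT.
* **Ineffective inspiratory effort during expiration (IEE).** A
  sub-threshold inspiratory effort during the expiratory phase fails to
  trigger a breath, leaving a transient flow deflection toward positive
  and a concave dip in airway pressure.

Everything else — passive breaths and miscellaneous disturbances — is
the **OTHER** class. Detection is framed as two separate binary tasks
(DT-vs-OTHER, IEE-vs-OTHER).

The method encodes each breath's pressure/flow/volume traces as a
224×224×3 image, extracts features with a convolutional trunk carrying
weights transferred from a source task, pools them with global average
pooling (GAP), and classifies with either a dense softmax head or a
Gaussian-kernel SVM. The central claim probed by the test suite is that
transfer-initialized extractors degrade far more gracefully than
randomly initialized ones as labeled data shrinks.

## Waveform simulator

Clinical PVA corpora are not publicly available, so the package ships a
seeded generator of pressure-control ventilation breaths built on
single-compartment respiratory mechanics:

    P_aw(t) + P_mus(t) = R·Q(t) + V(t)/C + PEEP,

integrated by explicit Euler at the fixed 50 Hz sampling rate. The
ventilator applies `P_aw = PEEP + ΔP·(1 − exp(−t/τ_rise))` for the set
inspiratory time, then releases with a short (0.04 s) decay constant.
Reported volume is the trapezoidal integral of reported flow (plus the
cycle's starting volume), so the volume/flow identity is exact on the
emitted arrays.

Defaults (jittered ±10% per cycle in `generate_dataset`): PEEP
5 cmH2O, driving pressure 15 cmH2O, respiratory rate 15/min,
inspiratory time 1.0 s, rise constant 0.1 s, resistance
10 cmH2O·s/L, compliance 0.05 L/cmH2O — a 0.75 L tidal volume and
4 s cycle, in the stated typical 4–6 s range.

Mechanisms:

* **DT** — sustained effort (half-sine `P_mus`, peak 6 cmH2O) past
  cycle-off; the ventilator retriggers after a uniformly drawn 0.1–0.3 s
  expiratory pause, so the second breath inherits the undischarged
  volume.
* **IEE** — a half-sine effort (2–4 cmH2O, 0.4–0.6 s) placed in
  mid-expiration; measured airway pressure dips by 0.4·P_mus. The effort
  is below the trigger threshold by construction and never starts a
  breath. An effort with onset during inspiration is rejected — that
  would be a different asynchrony type.
* **Noise** — additive zero-mean Gaussian, standard deviation
  `noise_sd` × the channel's per-cycle amplitude, applied to pressure
  and flow; volume is re-integrated from the noisy flow. Default
  `noise_sd = 0.02`.
* **Artifacts** — optionally (off by default) a 5–10 Hz oscillation on
  OTHER cycles imitating circuit condensation; the label stays OTHER.

With `noise_sd = 0` a two-rule classifier — second-breath starting
volume > 0.02 L for DT; exactly one expiratory flow excursion above the
fitted passive-decay envelope for IEE — recovers every label, so the
learning problem is well-posed by construction. The generator reproduces
the two target morphologies only; it makes no claim of physiological
fidelity beyond them, does not simulate flow or cycling asynchronies,
and its breaths are far cleaner and more homogeneous than ICU
recordings. Passing results bound what the pipeline can do on data of
this character; they do not certify clinical performance.

## Image encoding

Per breath and per channel: (1) linear resampling to length 224 with
endpoints preserved, then min–max normalization to [0, 1] (a constant
trace maps to zeros with a warning); (2) rasterization into a 224×224
binary image — sample j in column j, value v at row round((1−v)·223)
(row 0 = top), consecutive samples joined by 1-pixel Bresenham segments
so the trace is 8-connected and every column is covered; (3) fusion of
the pressure/flow/volume rasters as channels 0/1/2.

Choices made where the procedure was open: normalization is per breath
and per channel (each image fills its full vertical range, and encoding
becomes amplitude-invariant — the variant normalizing over a whole
record is available via `norm_scope="record"`); rendering is binary
with no anti-aliasing, so images are bit-identical across platforms;
each breath of a DT pair is encoded independently, contributing two
DT-labeled images.

## Feature extractors

All trunks are built layer-by-layer in the package's own NumPy NHWC
core (`ventasync.nn`): convolution via strided im2col and BLAS matmul,
TF-convention asymmetric "same" padding, batch normalization with
moving statistics, full backpropagation for chain-structured networks,
and an Adam optimizer. Parameter totals count trainable weights plus
batch-norm statistics, the convention used by mainstream frameworks'
model summaries.

| trunk | structure | trunk params | GAP features |
|---|---|---|---|
| `tiny_cnn` | conv 5×5/s4 (16) + BN; conv 3×3/s2 (32) + BN; conv 3×3/s2 (64) + BN | 24,688 | 64 |
| `mobilenet_v1` | width-1.0 depthwise-separable stack | 3,228,864 | 1024 |
| `vgg16_bn` | 13 VGG16 convs + BN before each of the 5 max-pools | 14,720,576 | 512 |
| `inception_resnet_v2` | standard stem + 10×block35 + 20×block17 + 10×block8 | 54,336,736 | 1536 |

With the 2-unit dense head these give 24,818 / 3,230,914 / 14,721,602 /
54,339,810 total parameters. Note on `vgg16_bn`: its printed feature
size is sometimes quoted as 1024, but the weight total 14,721,602 is
arithmetically consistent only with the standard 512-map VGG16 trunk
(14,714,688 conv weights + 5,888 batch-norm + a 512→2 head); this
package therefore reports 512 features for it. `tiny_cnn` is the
desk-scale trunk used by the training experiments; the three published
architectures are exercised for construction, counting, feature
extraction and CAM.

Activations are ReLU throughout (the original MobileNet's ReLU6 clamp
is immaterial here and omitted). Batch-norm uses eps 1e-3 and momentum
0.9 — the faster momentum matters because training runs are tens of
epochs, and slowly converging moving statistics would otherwise leave
inference far from the batch-statistics regime the weights were trained
in. Weight init is He-normal, seeded.

## Source task and transfer

Large-corpus pretraining is emulated at desk scale: the source task is
five-way classification of procedurally drawn curve families (sine,
smoothed square, sawtooth ramp, Gaussian bump, damped oscillation),
rendered through the *same* trace/derivative/integral three-channel
plotting pipeline as the breath images — so the trunk learns exactly
the kind of thin-trace geometry the target task presents, which is the
mechanism ImageNet weights supply for natural images. Defaults: 40
images per class, up to 10 epochs, Adam at 1e-3, batch 32. An optional
loader accepts externally obtained weights for the published trunks;
nothing in the tests depends on it.

Fine-tuning follows one protocol everywhere: categorical cross-entropy
on one-hot labels; 30% of provided data held out (stratified) for
validation; learning rate ×0.1 after 10 stagnant validation epochs
(probes use patience 10 at lr 1e-2; the schedule is a standalone,
separately tested component); stop after continued stagnation; restore
the best-validation weights. `freeze_extractor=True` (default in the
sweep harness) trains only the head on cached GAP features — features
are standardized for optimization and the affine transform is folded
back into the head weights, so the stored head applies to raw features.
`freeze_extractor=False` trains end to end (chain trunks only; the
inception graph is forward-only).

## Evaluation protocol

Partial-dropping 5-fold cross-validation: ids are randomly partitioned
into k=5 equal-as-possible folds; for each fold the other four form the
pool M; a retained subset M1 of size floor(PRR·|M|) is drawn (class-
stratified by default, so PRR=0.01 cannot produce a single-class
training set; `floor` vs `round` truncation is selectable) and M2 is
dropped. Dense heads split M1 70/30 train/validation; SVM heads use all
of M1. The test fold is never touched during training — asserted by an
exhaustive disjointness oracle in the suite.

Metrics per fold: accuracy, sensitivity, specificity, and an F1 defined
as the harmonic mean of sensitivity and specificity (this differs from
the precision-recall F1; it is the convention adopted throughout this
package and its tests). Undefined ratios (no positives or no negatives
evaluated) surface as NaN, never silently as zero.

The model zoo names follow `{Pr|Rd}_{Tiny|Mobile|VGG|InceRes}_{DC|SVM}`
(pretrained vs random init; dense vs SVM head) plus `Manual_SVM` (a
Gaussian-kernel SVM on 34 handcrafted time-domain features: nine
statistics — mean, max, min, range, SD, mean |slope|, max slope, min
slope, area — for each of the three channels, plus inspiratory time,
expiratory time, their ratio, total duration, inspired volume,
expiratory flow area and expiratory peak count; the list is this
package's reconstruction, so results depending on it are approximate)
and `LSTM` (two stacked 32-unit LSTM layers on the resampled length-224
three-channel sequences). SVM defaults: C = 1.0, kernel width from the
median-pairwise-distance heuristic on standardized features.

## Interpretability

For GAP + dense models the class activation map is the head-weight-
weighted sum of last-convolution feature maps,
M_c(x,y) = Σ_u w_uc·f_u(x,y), bilinearly upsampled to 224×224 and
min–max normalized (both choices fixed here for reproducibility;
gradient-based CAM variants are out of scope). Overlays are rendered by
alpha-blending a heat colormap over the fused image. A seeded property
check trains `tiny_cnn` end to end on noise-free IEE data and verifies
that the top-decile CAM mass overlaps the expiratory-notch columns more
than a spatially uniform baseline in the majority of five seeds; with a
frozen source-pretrained trunk the evidence is *not* localized — only
end-to-end adaptation produces notch-focused maps.

## Benchmark scale and numerical choices

The stochastic transfer properties run on 300 cycles per class (150 DT
events + 300 OTHER breaths), `tiny_cnn`, five seeds, PRR ∈ {1.0, 0.01},
chosen so the full suite and the acceptance script each run in minutes
on one CPU while leaving the 1%-retention regime nontrivial
(floor(0.01·480) = 4 retained breaths). Typical results: F1 ≈ 1.00
(pretrained) vs 0.97 (random) at full retention, ≈ 0.83 vs 0.63 at 1% —
the gap widens as retention shrinks, in every seed.

Other numerical details: forward passes are float32 (the test-suite
gradient oracles cast to float64); min–max normalization guards the
constant-input case; fold construction errors out when
floor(PRR·|M|) < 2 rather than producing an unsplittable set; all
randomness flows from explicit integer seeds through
`numpy.random.default_rng`, making every experiment bit-reproducible.

## Known limitations

* Synthetic breaths are much cleaner than ICU recordings; absolute
  accuracies here say nothing about clinical accuracy.
* The two big published trunks are exercised forward-only; end-to-end
  fine-tuning at their scale is impractical in this CPU core.
* The 34-feature list and several training hyperparameters are
  package-level reconstructions where the procedure was underspecified.
* Only DT and IEE under pressure-control ventilation are modeled; flow
  and cycling asynchronies appear at most as unlabeled artifacts.
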