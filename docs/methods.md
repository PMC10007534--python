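# Methods

`strokegcn` classifies four tennis strokes — forehand, backhand, volley
forehand, volley backhand — from 3D optical motion-capture marker
trajectories, using an attention temporal graph convolutional network
(A3T-GCN). This note documents the model, the experimental harness, the
synthetic data generator, and the design decisions taken where the
architecture description leaves choices open.

## Input representation

A trial is a `T x M x 3` array of marker coordinates in millimetres at
100 Hz. `M = 39` for the body alone (the Vicon Plug-in Gait full-body
marker set) or `M = 46` with the seven-marker racket cluster appended.
Trials in a corpus are zero-padded at the end to the corpus-wide maximum
frame count `nf`; padded frames are exactly zero and no masking is applied
(the temporal encoder simply runs over them). Before padding, each trial
is translated so that the first-frame mid-pelvis (mean of LASI/RASI/
LPSI/RPSI) is the origin and rescaled from millimetres to metres;
both steps can be disabled (`ModelConfig.center`).

## The marker graph

Markers are nodes of an undirected graph `G = (V, E)`. Spatial
aggregation uses the self-looped, symmetrically normalized adjacency

    O-tilde = O + I,  T-tilde = diag(rowsum(O-tilde)),
    O-hat = T-tilde^(-1/2) O-tilde T-tilde^(-1/2).

The edge set is not dictated by the classifier: the package ships a
default anatomical table (segment chains joined at shared landmarks:
head ring, spine, shoulder girdle, arm chains with a doubled wrist bar,
pelvis ring, leg chains) as an editable text file
(`strokegcn/data/body_edges_39.txt`). The racket's seven markers form a
complete subgraph — the racket is a rigid body, all of its points move
under one transform — and the bottom-of-handle marker connects to the
gripping hand's wrist-bar markers (right by default, configurable).
Node order is body markers in canonical Plug-in Gait order, then racket
markers; the order fixes the layout of all weight matrices.

## The classifier

Per frame, a three-layer graph convolution maps `M x 3` coordinates to
`M x Z` embeddings:

    f(X) = sigmoid( O-hat · ReLU( O-hat · (O-hat · X · Psi0) · Psi1 ) · Psi2 )

with `Psi0 : 3 x F`, `Psi1 : F x F`, `Psi2 : F x Z` (defaults `F = 64`,
`Z = 16`). The embeddings are flattened to an `M·Z` frame vector
(flattening rather than node-pooling preserves *which* marker moved —
essential for exploiting the racket channels; mean-pooling is available
via `ModelConfig.pool`).

The frame-vector sequence is encoded by a bidirectional gated recurrent
network. Each direction applies, per step,

    ugc_t = sigmoid(Wu [x_t, h_{t-1}])      update gate
    rgc_t = sigmoid(Wr [x_t, h_{t-1}])      reset gate
    mc_t  = tanh(Wc [x_t, rgc_t ⊙ h_{t-1}]) candidate memory
    h_t   = ugc_t ⊙ h_{t-1} + (1 - ugc_t) ⊙ mc_t

Note the state update deliberately keeps the published gate convention:
the update gate multiplies the *previous* state and its complement the
candidate — the mirror image of the usual GRU wiring. The two directions
have independent parameters and their states are concatenated
(`u_t`, width `2H`, default `H = 64`).

Soft attention pools the sequence: a two-layer affine map scores each
step, `e_t = psi2 (psi1 u_t + b1) + b2` (no hidden nonlinearity — the
two-layer map is taken as printed), a softmax over time yields weights
`alpha`, and the context vector is `Cv = sum_t alpha_t u_t`. The softmax
is computed with max-subtraction; it is shift-invariant and the weights
sum to 1.

A two-layer perceptron maps `Cv` to 4 class scores, followed by a
terminal softmax so the output is a probability vector and the sparse
categorical cross-entropy `-log p[true]` (probability clamped at 1e-12)
is well defined. Two aspects are deliberate design choices:

- *The printed head is degenerate.* Taken literally, the first head layer
  has one softmax-activated unit — a softmax over a single unit is
  constantly 1, so the prediction cannot depend on the input. The default
  head therefore has a configurable hidden width (default 16); the
  literal wiring remains available as `ModelConfig(faithful_head=True)`
  for inspection.
- *The hidden activation is tanh, not softmax.* Generalizing the printed
  softmax activation to a wider hidden layer turned out to cripple
  optimization in practice: on the synthetic task, training with a
  softmax- (or ReLU-) activated hidden layer collapses the context vector
  to a constant (between-class separation shrinks ~30x) and accuracy pins
  at the level achievable from the forehand/backhand distinction alone.
  With tanh the same network trains to 100% on separable data. The
  softmax variant is kept as `ModelConfig(head_activation="softmax")`.

### Autodiff and optimization

No deep-learning framework is used; the package carries a small
reverse-mode automatic-differentiation engine over numpy float64 arrays
(`strokegcn.autodiff`) implementing exactly the operations the model
composes. Its correctness is pinned by per-operation finite-difference
tests and an end-to-end gradient check through the full model
(max relative error ≤ 1e-4 on a 3-node, 2-frame instance).

Training uses Adam (lr 1e-3 default; the bundled experiments use 3e-3),
batch 16, up to 200 epochs with early stopping on validation loss
(patience 20 default). The best-validation-loss checkpoint is returned
together with full per-epoch accuracy/loss curves. Divergence (non-finite
loss) raises; in repeated runs a divergent run is excluded and flagged
rather than crashing the summary. All randomness flows through
`numpy.random.Generator` objects seeded explicitly; two runs with the
same seeds are bit-identical.

## Experimental harness

- **Splits**: stratified 60/20/20 train/validation/test. Per class,
  `floor(0.6 n)` trials go to train and `floor(0.2 n)` to validation;
  the remainder is the test set (the rounding rule is a package choice).
- **Repeated runs**: 20 independent split+train+evaluate cycles by
  default, summarized as Mean/Max/Min/SD on the percent scale, overall
  and per class (precision, recall, F1, and one-vs-rest accuracy per
  class — the per-class "accuracy" is interpreted one-vs-rest).
- **Metrics**: accuracy = trace/total of the 4x4 confusion matrix;
  per class, `P = TP/(TP+FP)`, `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`;
  undefined 0/0 ratios are reported as 0 with a warning.
- **LOOCV**: for each trial, train on the remainder (with a stratified
  validation carve-out for early stopping) and record the one-hot truth
  and predicted probability vector. The summary RMSE is the square root
  of the mean squared *entry-wise* difference over all folds. The
  operand of this RMSE is a convention of this package (a classification
  task does not fix one); it is declared, not claimed to match any
  external convention.
- **Condition comparison**: Welch's two-sample t-test (unequal
  variances) on per-run accuracies, sign convention `a - b`. Welch is
  chosen because the two conditions' run-to-run variances have no reason
  to be equal. With zero variance in both samples the statistic is
  undefined and reported as NaN.

## The synthetic stroke generator

No public corpus of marker-level tennis strokes exists, so the package
ships a generator that emulates the statistical structure the classifier
assumes. Its defaults are the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| counts | 197/212/180/180 | trials per class in class-id order (forehand, backhand, volley FH, volley BH) — i.e. backhand 212, forehand 197 |
| rate | 100 Hz | capture frequency |
| duration range | 60–180 frames | uniform; forces nontrivial padding |
| noise sd | 2 mm | i.i.d. Gaussian per coordinate (typical optical jitter) |
| subjects | 10, one left-handed | left-handed trials are mirrored (x-reflection + left/right label swap) |

Kinematics: a fixed standing pose whose dominant arm chain is re-posed
per frame along a smoothstep azimuth sweep with a height profile; the
backhand is two-handed. The racket is a rigid 7-point template moved by
one rigid transform per frame. Drives sweep with the shaft laid back and
roll the face over; volleys keep the head up with an open face. Per-trial
variability: amplitude scale ~ N(1, 0.05), azimuth offset ~ N(0, 0.03),
random duration, coordinate noise.

A structural subtlety worth recording: the racket markers are symmetric
about the shaft, so the cluster centroid lies *on* the roll axis. With
the complete racket subgraph and symmetric normalization, every racket
node's first-layer aggregate is a fixed combination of roll-invariant
quantities — a pure roll about the shaft is exactly invisible to the
graph convolution. The volley/drive contrast is therefore carried by the
shaft *tilt* (which displaces the whole cluster) in addition to roll;
this is also the biomechanically sensible encoding.

The flag `racket_informative` controls where the class signal lives, so
the with/without-racket ablation has a known ground truth:

- `both` (default): forehand-vs-backhand is in the body (which arm
  swings, sweep direction); drive-vs-volley is in the racket pose only —
  a drive and its volley share the body path exactly, mirroring how
  similar those movements are. Racket channels are genuinely informative.
- `body_only`: all four classes separable from the body (volleys use a
  shorter, higher sweep); the racket performs a generic pendulum whose
  transform is drawn independently of the class, so racket channels carry
  zero class information by construction.
- `racket_only`: the body performs a class-independent sway; only the
  racket follows the class-specific path.

What the generator does **not** emulate: validated joint biomechanics,
soft-tissue artefact, marker occlusion/swaps, ball contact dynamics,
inter-subject anthropometry. Passing tests on this data demonstrate that
the implementation learns and that the harness measures what it claims —
not that the architecture reaches any particular accuracy on real
recordings.

## Bundled experiments and their sizes

The reference experiments (`strokegcn.experiments`) run on one CPU in a
few minutes; the sizes are the package's demonstration conditions:

- **Gradient check**: 3-node path graph, 2 frames, batch 2, all
  parameters, central differences at 1e-6.
- **Learnability**: 15 trials/class, zero noise, durations 30–50 frames,
  all right-handed, model (F=12, Z=6, H=24, head 16→12), lr 3e-3, up to
  200 epochs. The right-handed cohort isolates optimization ability from
  the few-shot minority-handedness problem: with 1-in-10 left-handed
  trials, a left-handed validation trial often has a single left-handed
  training example of its class, and missing it is a data-scarcity
  failure, not an optimization one.
- **Racket ablation**: 12 trials/class, noise sd 10 mm, durations 25–40,
  model (F=8, Z=4, H=16), 60 epochs, 5 runs per condition. 10 mm noise is
  deliberately above realistic jitter: it makes the task imperfectly
  learnable at this size, so accuracies vary between runs and the Welch
  test on the body-only condition is informative rather than a degenerate
  0/0.
- **LOOCV demonstration**: 4 trials/class, zero noise, 80-epoch folds
  (lr 5e-3). With 12-trial training sets per fold this is intentionally
  austere; the reported RMSE reflects that scale, not the model's
  ceiling.

## C3D input/output

C3D files are read and written by a codec internal to the package
(`strokegcn.c3d`) covering 3D point data without analog channels: Intel
(little-endian, IEEE float) writing with `POINT:UNITS = "mm"`, reading of
Intel and SGI/MIPS byte orders with float or scaled-integer storage.
Metre-unit files are converted to millimetres on ingestion. Samples with
negative residuals are linearly interpolated across gaps of at most 10
frames; a longer gap rejects the trial (full capture-pipeline gap
filling — pattern fill, rigid-body fill — is out of scope). The legacy
DEC floating-point dialect is not supported.

## Known limitations

- The generator's class geometry is stylized; absolute accuracies on it
  say nothing about real strokes (see above).
- Padded frames are processed, not masked; attention must learn to
  down-weight them. This is faithful to the padding description but is
  not the strongest possible temporal model.
- The published gate convention (complement on the candidate memory)
  is kept as printed; swapping to the standard GRU convention changes
  nothing structurally but is not implemented as an option.
- Left-handed subjects are handled by mirroring at generation time; the
  graph's racket attachment defaults to the right wrist and is not
  switched per trial.
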