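# Methods

## Problem setting

A low-cost dataglove records 18 synchronized channels at 100 Hz over a fixed
1.5 s window (150 samples): five flex-sensor voltages (finger flexion),
triaxial body-frame acceleration, triaxial earth-frame (NED) linear
acceleration, triaxial angular velocity, and the orientation quaternion
stream produced by the IMU's motion processor. The task is closed-vocabulary
gesture classification under a leave-one-subject-out (LOSO) protocol: every
fold trains on all signers but one and tests on the unseen signer, which is
the demanding but honest measure of signer generalization.

Gestures split into *static* signs (a held finger posture, no hand motion)
and *dynamic* signs (a spatial hand trajectory plus a posture), and the two
kinds get different pipelines.

## Preprocessing model

The accelerometer measures motion plus gravity in a body frame fixed to the
glove. With a unit Hamilton quaternion q = (q_w, q_x, q_y, q_z) mapping the
body frame to the earth frame, the body-frame gravity vector is

    g = ||g|| * ( 2(q_x q_z - q_w q_y),
                  2(q_w q_x + q_y q_z),
                  q_w^2 - q_x^2 - q_y^2 + q_z^2 )

(the third row of the body-to-earth rotation matrix; ||g|| defaults to
9.81 m s^-2). Subtracting g from the raw reading gives body-frame linear
acceleration la; multiplying by the rotation matrix R(q) gives earth-frame
linear acceleration LA = R la. We use the standard orthonormal
Hamilton-convention matrix with R[0][2] = 2(q_x q_z + q_w q_y) and
R[2][0] = 2(q_x q_z - q_w q_y); orthonormality (R^T R = I, det R = 1 to
1e-9) is enforced by tests. Note the gravity formula above is exactly the
third row of this matrix, so the compensation and the rotation are mutually
consistent; quaternion sign (q vs -q) is irrelevant to both.

Filtering follows the recording realities of a hand-built ADC front end:
a 10-point rolling median removes isolated sampling spikes on the IMU
channels; sessions flagged as mains-contaminated get an extra 10-point
moving average (a 10-point mean at 100 Hz has a transfer-function null at
exactly 50 Hz, so it is the natural mains notch); a final 10-point moving
average smooths all signal channels. Filters are centered with
nearest-valid-value edge fill (gestures sit in the middle of the window, so
edge fill does not disturb morphology), length-preserving, and identity on
constant signals. Quaternion channels are never filtered — componentwise
smoothing would break unit norm.

Channels are then min-max scaled to [0, 1]. The scaling is fitted on the
training signers only (per LOSO fold), so the held-out signer cannot leak
into the statistics; values outside the fitted range map outside [0, 1]
without clipping, and a constant channel maps to 0 with a warning. A
per-recording mode exists but is not the default.

## Spatial projection images

A dynamic sign is defined by the spatial pattern the hand traces — not by
the signer's pace or hand size. Earth-frame linear acceleration is
double-integrated (cumulative trapezoid, zero initial velocity and position;
the protocol starts each window at rest) to a 3-D displacement path, which
is projected onto the XY, YZ and ZX planes, min-max normalized per axis, and
drawn as a stroked polyline (width 7 at the 224 px scale, round joins and
caps, rendered at 448 px and area-resampled to 224 x 224; ink = 1 on a 0
background so images are sparse-positive). Because the drawing depends only
on the set of visited points, any monotone time-reparameterization of a
noiseless trajectory gives the same image (verified: symmetric Hausdorff
distance between normalized paths at 2x speed ratio stays within 2% of the
unit diagonal), and uniform spatial scaling cancels exactly in the
normalization (verified bit-identical rasters at 2x size ratio).

Numerical choices that matter:

- *Degenerate axes.* An axis whose span is zero up to float rounding (e.g.
  the out-of-plane coordinate of a planar gesture after double integration)
  must not be min-max amplified into a spurious full-scale pattern. An axis
  is treated as degenerate — centered at 0.5 — when its span is below 1e-6
  of the larger axis span (absolute floor 1e-12 m).
- *Axis scope.* Each axis is normalized independently (a joint-axes mode
  preserving aspect ratio is available).
- *Drift.* No detrending is applied before integration by default; an
  optional endpoint zero-velocity detrend is not enabled anywhere in the
  shipped pipelines.
- *Static signs* produce no meaningful trajectory; the projection step
  raises for them by contract.

## Classifiers

Both classifiers are parallel-path networks: each input channel is processed
by its own convolutional block into a 50-d embedding, and the concatenated
embeddings feed one fully connected softmax head.

- **1-D ConvNet block** (per time-series channel): four convolutions
  (kernel 3, stride 1, padding 1; filter counts 32, 32, 64, 64), each pair
  followed by batch normalization and max pooling (pool 2), ReLU
  activations, then a dense layer to the 50-d embedding. A 150-sample input
  leaves a 37-step feature sequence after the two pool stages (floor
  division), asserted in tests.
- **Static model**: 8 channels (5 flex + 3 earth-frame linear acceleration;
  the channel set is configurable) -> 8 blocks -> 400-d concatenation ->
  head.
- **Dynamic model**: 8 paths — the 3 projection images through a
  MobileNetV2-style 2-D backbone (stem convolution with 32 filters,
  inverted-residual bottlenecks with 3 x 3 depthwise convolutions and ReLU6,
  final 1 x 1 expansion, global average pooling), plus the 5 flex channels
  through 1-D blocks. The backbone is *shared* across the three planes (a
  third of the parameters; a separate-backbones mode exists), with a
  per-image 50-d projection for symmetry with the 1-D paths. Backbone
  weights are randomly initialized; the width multiplier and an input
  average-pooling factor scale the backbone down for CPU-scale runs. The
  canonical bottleneck table (expansion/channels/repeats/stride:
  1/16/1/1, 6/24/2/2, 6/32/3/2, 6/64/4/2, 6/96/3/1, 6/160/3/2, 6/320/1/1)
  is the default and is configurable.

The network layers (1-D/2-D/depthwise convolution, batch normalization,
pooling, dense, ReLU/ReLU6, softmax cross-entropy, Adam) are implemented in
NumPy inside the package with hand-written backpropagation; every layer's
gradients are pinned against central-difference numerical derivatives at
1e-6. Layers are functional (forward returns a cache consumed by backward),
which is what lets one backbone object serve three input paths per step with
correctly accumulated gradients.

Training: sparse categorical cross-entropy, Adam with learning rate 1e-4,
at most 300 epochs, early stopping on validation loss with patience 30 and
best-weight restoration, batch size 32, validation split = stratified 10% of
the training signers' trials. These are the library defaults. The head's
final dense layer is initialized at small scale so the initial loss sits at
the uniform-softmax value log(K). All randomness flows through one seed;
histories are bit-reproducible on a single CPU thread.

**Desk-scale configuration** (used by the end-to-end tests and the
acceptance script, chosen for a single-CPU budget): backbone width
multiplier 0.35, input average-pool factor 8 (224 -> 28 effective
resolution), learning rate 1e-3, batch 16, at most 12 epochs, patience 6.
On the well-separated synthetic templates training converges in 2–3 epochs,
so the tighter epoch cap changes wall time, not outcomes.

## Evaluation protocol and metrics

One fold per signer; the fold's test set is exactly that signer's
recordings. Per-class precision, recall and F1 (harmonic mean) come from
the pooled confusion matrix across folds (rows = true, columns =
predicted); macro metrics are unweighted class means; accuracy is
micro-averaged precision, trace over total — which equals macro recall
*exactly* when class counts are balanced, an identity the tests assert.
Zero-denominator classes score 0 with a warning. Pooled aggregation is the
default; a fold-averaged mode is provided because published per-class and
overall tables of this protocol are not always mutually consistent with
pooling. Baselines (logistic regression and random forest on flattened
normalized channels, and a single-path 18-channel 1-D CNN) run under the
identical protocol.

## Synthetic data: what it emulates and what it does not

The simulator inverts the preprocessing chain so that every stage is
testable without the real deposit. Dynamic templates are parametric curves
(circle, line sweep, zigzag, vertical arc) traversed with a quintic ease
(zero velocity and acceleration at the window edges, matching the recording
protocol); static templates command zero motion. Signer variability:
hand scale ~ U(0.8, 1.2) on displacement, speed factor ~ U(0.7, 1.4) as a
monotone time-warp exponent, per-finger flex gains/offsets, plus small
per-trial jitter. Orientation is a slow band-limited random-walk tilt
capped at 15 degrees, integrated to quaternions through the exponential
map — so the gyro channel and the quaternion stream satisfy the
finite-difference relation exactly. Body acceleration is R^T LA + gravity
plus Gaussian noise (defaults: accel sigma 0.05 m s^-2, gyro 0.01 rad s^-1,
flex 0.01 a.u. — small relative to signal, configurable); the earth-axis
channel is recomputed from the noisy body channel exactly as glove firmware
would. Flex channels are logistic transitions from a rest level (0.1) to
the class posture. Mains interference is modeled as an additive cosine on
all signal channels (a cosine so that injection at the Nyquist frequency is
the alternating sequence rather than identically zero).

What the simulator does *not* model: biomechanical hand/finger coupling,
sensor nonlinearity and hysteresis, orientation change correlated with the
gesture itself, accelerometer bias and scale error, inter-trial posture
drift, or the actual ASL vocabulary's fine-grained similarity structure
(e.g. near-identical letter handshapes). Consequently, passing the
end-to-end benchmark shows the pipeline is implemented coherently and that
the projection representation delivers its claimed invariances — it does
not certify real-data accuracy, where class overlap and sensor artifacts
dominate.

## Problem sizes used in tests and the acceptance script

Simulated cohorts are 5 signers x 4 gestures x 10 trials (200 recordings)
for the end-to-end LOSO benchmarks (dynamic and static), with the
desk-scale model configuration above; unit and property tests use smaller
cohorts and reduced layer widths. These sizes are the package's CPU-scale
study conditions; the full-scale configuration (width 1.0, no input
pooling, paper-default training schedule) is exposed through the same APIs
and the CLI for use with the real deposit.

## Known limitations

- No pretrained backbone checkpoint is bundled; transfer learning from
  ImageNet-scale weights is out of reach offline, and random initialization
  at reduced width is the supported desk-scale regime.
- The NumPy training loop is single-threaded and unsuited to the full
  25-signer, 40-class study; reproducing the published headline metrics
  additionally requires the public deposit itself.
- The CSV reader trusts the declared schema for units; flex channels are
  treated as arbitrary units throughout (min-max normalization makes the
  pipeline unit-free).
- Windows are fixed at 150 samples; longer recordings are truncated, not
  segmented.
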