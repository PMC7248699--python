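# Methods

This document describes the algorithms implemented in `simatch`: matching
silhouette-video clips of a person to the wrist-worn accelerometer stream of
the same person, with no visual appearance information.

## Problem setting

A monitored environment produces two synchronized, privacy-preserving
streams per person:

- **Video half**: binarized silhouette masks (no texture, no identity
  cues) plus the per-frame bounding box of the tracked person.
- **Wearable half**: the 3-axis acceleration of a wrist-worn device, in g.

Given `N` visible people and `M` wearables, the system must decide which
silhouette belongs to which wearable. Two tasks operationalize this:

- **Verification**: declare a (video clip, accelerometer clip) pair
  *matching* when their embedding distance is below a threshold `tau`.
  Quality is the area under the ROC curve (auROC) as `tau` sweeps.
- **Assignment**: with `N` people all visible and instrumented, assign each
  video to its minimum-distance accelerometer; quality is the fraction
  assigned correctly (chance level `1/N`).

## Embedding networks

Two encoders map the two modalities into a shared `D`-dimensional space
(default `D = 64`):

- `f(video) = f_sil(silhouette clip) + f_bb(bounding-box series)` — the
  elementwise sum of a 3-D convolutional encoder over the `L x H x W`
  silhouette clip and a 1-D convolutional encoder over the `L x 4`
  normalized box series.
- `g(accel)` — a 1-D convolutional encoder over the `L x 3` acceleration
  clip, mirroring `f_bb`.

All convolutions use kernel size 3 and ReLU activations, with optional
spatial (whole-channel) dropout. Three variants are implemented:

- **fully_conv**: alternating max-pool / convolution stages; channel count
  grows (8, 16, 32, 64) while every axis shrinks; a final convolution to
  `D` channels with tanh activation and a global max-pool. Each branch
  embedding lies in `[-1, 1]^D`.
- **lstm_tp**: the same stack, but temporal pooling stops after two stages
  and the remaining per-timestep features feed a single-layer LSTM whose
  final hidden state is the embedding.
- **lstm**: no temporal pooling; the full-length temporal features feed
  the LSTM.

Matching is scored with the squared Euclidean distance between `f` and `g`
embeddings. No L2 normalization is applied.

The final pre-tanh convolution is initialized with a damping gain (0.3 by
default). Without it, the global max over a He-initialized pre-tanh field
saturates every output channel at +1 early in training, which collapses all
embeddings to a constant and stalls learning.

## Triplet training

Each training example is a triplet: an anchor video clip, its own
time-synchronized acceleration (positive), and a non-matching acceleration
(negative). Two losses over squared distances `d+ = d(f(v), g(a+))`,
`d- = d(f(v), g(a-))`:

- **Standard triplet loss (STL)**: `max(d+ - d- + alpha, 0)` with margin
  `alpha = 0.2`. It saturates to zero once the margin is met and only
  constrains distance *differences*, so distances from different triplets
  need not share a scale.
- **Reciprocal triplet loss (RTL)**: `d+ + 1 / (d- + eps)`, margin-free.
  Its gradient never vanishes: it continuously pulls every positive
  distance toward zero and pushes every negative distance up, inducing a
  common scale that a single universal threshold can separate. This
  matters for verification, where one `tau` must serve all pairs.

## Negative taxonomy and sampling strategies

Negatives are classified by how hard they are to reject:

| type | definition | difficulty |
|------|------------|------------|
| DSDA | different subject, different activity | easy |
| DSSA | different subject, same activity | easy |
| SSDA | same subject, different activity | easy |
| SSSA | same subject, same activity, disjoint window | hard |
| OVLP | same stream, overlapping window shifted by 1-10 frames | very hard |

OVLP negatives are cut from the anchor's own accelerometer stream at a
nonzero offset of at most 10 frames — an "almost synchronized" signal.

Training strategies are probability mixtures over these types:

| strategy | DSDA | DSSA | SSDA | SSSA | OVLP |
|----------|------|------|------|------|------|
| easy | 1/2 | 1/2 | — | — | — |
| easy_hard | 1/4 | 1/4 | — | 1/2 | — |
| hard | — | — | — | 1 | — |
| hard_veryh | — | — | — | 1/2 | 1/2 |
| veryh | — | — | — | — | 1 |
| all | 1/9 | 1/9 | 1/9 | 1/3 | 1/3 |

Sampling draws the type first, then a uniform eligible candidate; if the
drawn type has no eligible candidate for that anchor the mixture is
renormalized over the remaining types (with a warning). At inference time
only DSDA and DSSA negatives can occur (one person cannot be in two
places), so evaluation negatives are drawn 50/50 from those types; SSSA and
OVLP scores are reported as diagnostics.

## Preprocessing

- Each silhouette frame is cropped to its bounding box, rescaled so the
  longer side equals `target_size` (aspect preserved, nearest-neighbour),
  and centred on a square zero canvas.
- Streams are cut into fixed-length clips (default 100 frames) with
  overlap (default 95%, i.e. stride 5).
- The accelerometer stream is subsampled to the video frame rate by
  nearest-timestamp selection.
- Bounding boxes are normalized by the frame extents to `[0, 1]^4`.
- Training-time augmentation on silhouette clips: joint horizontal flip
  (p = 0.5), dilation/erosion with a per-clip radius up to 5 px, and
  independent salt-and-pepper pixel flips (3%).

## Training protocol

Subject-disjoint three-way splits (train / validation / test). Per epoch,
triplets are resampled under the configured strategy (negatives drawn from
the full training pool) and optimized with Adam. After every epoch the
validation auROC of the inference-realistic types (DSDA, DSSA) is
monitored; training keeps the weights of the epoch with the best average
monitored auROC and stops early when no monitored score improves for
`patience` epochs.

## Evaluation

- **auROC by negative type** plus their unweighted mean (AVG).
- **Optimal threshold** `tau*` by the Youden criterion (max TPR - FPR).
- **Scenario experiments** build virtual multi-occupancy scenes by
  treating clips from different single-person recordings as simultaneous:
  - `fix_sync_vary_acc`: one visible instrumented person, `N` wearables
    (mean reciprocal rank of the true wearable, mAP);
  - `fix_sync_vary_vid`: one wearable, `N` visible people (mAP);
  - `all_sync`: `N` people all visible and instrumented (assignment
    accuracy).
- **Observation time**: assignment accuracy when per-clip distances are
  averaged over `k` consecutive clips before assigning; accuracy grows
  with `k` as independent per-clip errors average out.

## Baseline

A training-free comparison: the visible person's acceleration magnitude is
estimated from the second central finite difference of the bounding-box
centroid (edge-replicated moving-average smoothing, times fps²), and
compared by Euclidean distance against the z-scored magnitude of the
high-pass-filtered (zero-phase Butterworth, 0.5 Hz) wearable signal. The
high-pass removes gravity and posture DC; magnitudes sidestep the unknown
camera/IMU rotation; z-scoring reconciles pixel and g units.

## Synthetic benchmark

Since the package must run at desk scale without external data, it ships a
physically-consistent synthetic generator: each subject has persistent
motion traits (preferred frequency, amplitude, phase drawn from a
subject-keyed generator); activities are band-limited oscillations
("sweeping" 0.7-1.1 Hz, "waving" 1.6-2.2 Hz, "exercising" 2.6-3.2 Hz)
with a rest period; silhouettes are rendered as an ellipse-plus-arm figure
with tight boxes; the wrist acceleration is derived from the *same* motion
trace by double differentiation (plus gravity and sensor noise), so the
cross-modal correspondence that the model must learn genuinely exists in
the data, while different subjects doing the same activity differ in their
traits.
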