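# Methods

## Problem and model

The toolbox decides how many clusters (postures) a self-organizing map
should use when grouping per-frame skeleton feature vectors. A frame is a
flat vector of 3 × n_joints camera coordinates (57 for the default 19-joint
skeleton); a recording is an ordered sequence of frames at a nominal
15 fps. Two distances are supported throughout: cosine
(`1 − x·y/(‖x‖‖y‖)`, sensitive to the *direction* of the pose vector —
trunk inclination dominates) and Euclidean (sensitive to absolute joint
positions). Cosine is the package-wide default: it is the metric under
which a variable-size map adapts most flexibly, and the metric used for the
index protocol; Euclidean is selectable everywhere.

### The map

The SOM is a **1-D chain** of M neurons — the neuron count *is* the cluster
count, which is the quantity under study; a 2-D grid would decouple the
two. Training is the classic online rule: per sample, find the
best-matching unit (BMU) under the configured metric, then update every
neuron additively with a Gaussian neighborhood on the chain index. The
metric affects only BMU search; an additive update with cosine matching is
the conventional pairing. Learning rate and neighborhood radius decay
exponentially over the `epochs × N` steps:

| parameter | default | meaning |
|---|---|---|
| `epochs` | 50 | full passes over the data |
| `lr0 → lr_final` | 0.5 → 0.01 | learning-rate schedule |
| `sigma0 → sigma_final` | M/2 → 0.5 | neighborhood radius, neuron-index units |
| `init_scheme` | uniform | uniform in the data bounding box; per-dimension Gaussian and sample-row init available |
| `shuffle` | true | reshuffle sample order per epoch |

Every run is bit-reproducible from `seed`: one stream drives the
initialization, a decoupled stream (`seed + 1`) the shuffling.

**Quantization error** is the mean over samples of the squared distance to
the BMU under the model's own metric. The aggregation (mean) is a package
choice; a per-network error is conventionally a per-sample average.

### Validity indices

The four classical indices are implemented from their definitional sums
(the reference library serves only as a test oracle):

* **Silhouette**: `(b̄min − ā)/max(ā, b̄min)`. The orientation is the
  standard one (large = well placed, range [−1, 1]); samples in singleton
  clusters score 0 by convention.
* **Dunn, centroid variant**: numerator `min_{m≠m'} d(cc_m, cc_{m'})`
  between centroids — deliberately *not* the classical point-wise minimum —
  over the global maximum intra-cluster pairwise distance. Singletons
  contribute 0 to the denominator; an all-singleton clustering returns +inf
  with a degeneracy flag.
* **Davies–Bouldin, sum form** (default): `Σ_m max_{m'} (āv(m)+āv(m'))/d(cc_m,cc_{m'})`
  with no 1/M. The `mean` variant divides by M; at fixed M the two are
  proportional and rank identically, and the mean form is what reference
  implementations compute, so it is the cross-check variant.
* **Calinski–Harabasz**: between/within dispersion ratio with Euclidean
  norms regardless of the training metric (the index is defined that way).

Indices are computed on **data-mean centroids** of the SOM assignment, not
on the neuron weights (a switch allows neuron weights for sensitivity
checks). Empty clusters are kept with size 0 and an undefined centroid;
indices skip them and the report carries `empty_cluster` /
`singleton_cluster` / `*_degenerate` flags rather than renumbering or
silently dropping anything.

### Discriminant score

For frame f and centroids cc_1..cc_M with d_m = d(f, cc_m):

    DS_m = (1/d_m) / Σ_{m'} (1/d_{m'}),    DS_m = 1 if d_m = 0.

This normalized-inverse form is the only one consistent with all of the
score's required properties — values in [0, 1], rows summing to 1, and the
exact-coincidence branch as the continuous limit d_m → 0. Per frame the
argmax is the *winner*; an odd-width centered mode filter (default 5
frames ≈ 0.33 s at 15 fps, edge-replicated) removes single-frame winner
chatter; *transitions* are the frames where the smoothed winner changes.
Per cluster, the *peak* is the maximum DS over the frames the cluster wins
(0 if it never wins; the all-frames maximum is reported alongside for
transparency) and the *dwell fraction* is its share of frames won.

### Selection rule

A candidate k is accepted iff every cluster's peak ≥ `theta_peak` (default
0.5) and every dwell fraction ≥ `theta_dwell` (default 0.05); among
accepted candidates the default rule returns the **largest** k (avoid
omitting genuine postures), with `best_min_peak` as the alternative.
`theta_peak = 0.5` is the smallest round threshold that separates decisive
peaks (≈0.6–0.97 in worked examples of this kind) from the flat
trajectories of superfluous clusters (≈0.3–0.44); `theta_dwell = 0.05`
fails clusters that win under 5% of frames — transient or dead neurons.
The Calinski–Harabasz argmax over the same candidates is attached to every
recommendation; disagreement is flagged, not resolved, since the two
criteria weigh different evidence. When a printed peak table is scored
(no trajectories), the dwell check is skipped.

In `scan_k`, each candidate k trains independently with seed
`base_seed + k`; winner smoothing defaults to *off* there because a scan
may run on unordered data (e.g. the blob-recovery study below), where a
temporal mode filter is meaningless — temporal pipelines pass their window
explicitly. A cluster left empty by the map has no data mean; for DS
scoring its neuron weight — the only prototype a dead neuron has — stands
in as centroid. Its peak stays 0 unless it actually wins frames, so the
substitution cannot rescue a dead cluster.

## Synthetic data

Real recordings of this kind are not redistributable, so the generator
provides ground-truthed stand-ins at two levels of realism.

**Activity sequences**: five canonical poses of a ~1.75 m figure (upright
walking, deep-lean picking, moderate-lean placing, extended-hands walking,
squatting), scripted as dwell segments (default 100 frames) joined by
linear interpolation (default 10 frames), plus i.i.d. Gaussian keypoint
jitter (default sd 0.01 m, typical keypoint noise of depth-camera skeleton
tracking) and an antiphase fore-aft sinusoid on wrists/hands/ankles
(default amplitude 0.05 m, period 15 frames ≈ one stride at 15 fps). The
ground-truth label switches at the interpolation midpoint — a symmetric,
testable convention for boundary-tolerance measurements. The generator
emulates posture dwell, smooth transitions, jitter and gait periodicity; it
does **not** model bone-length constraints, occlusion, camera projection,
multi-person scenes or inter-subject variation, so passing tests show the
pipeline's correctness and temporal behavior, not robustness to real-world
artifacts.

**Gaussian blobs**: k isotropic clusters in D dimensions (default 57),
centroids at mutual Euclidean distance exactly `separation × sd` (scaled
orthogonal axes under a random rotation — hence k ≤ D — shifted away from
the origin so cosine distances stay well defined). This is the fully
controlled cluster-recovery setting: with separation 10, 100 points per
cluster and candidates 3–6, the CH argmax and the DS recommendation both
recover k = 4 in ≥ 90% of seeds.

## Numerical choices

* Distances below `1e-12` are treated as exact coincidence with a centroid
  (cosine self-distance is ~1e-16 by cancellation, never exactly 0);
  distinct centroids both within tolerance of a frame raise an error.
* Cosine distance is clipped to its analytic range [0, 2]; zero-norm data
  vectors are rejected (an all-zero skeleton frame is corrupt input), while
  a zero-norm *neuron* during training is scored as orthogonal (distance 1).
* All argmin/argmax ties (BMU search, winners, window modes) break to the
  lowest index — determinism over elegance.
* Cluster and neuron indices are 0-based everywhere; rendered labels may be
  1-based for display only.
* NaN coordinates are rejected, never imputed; files round-trip floats via
  shortest-repr serialization, so written sequences re-read bit-for-bit.

## Validation scale

The shipped suite validates at desk scale: oracle equivalence on 200 random
datasets (N ≤ 60, D ≤ 8, M ≤ 6) against brute-force loops and a reference
library; a 1000-dataset stress suite for the score's range contract;
50-seed blob recovery at N = 400, D = 57; 20-seed transition tracking on
430-frame activities (60 boundaries, ±5-frame tolerance). These sizes give
stable pass/fail behavior at interactive runtimes; the pipeline itself is
O(T·M·D) per scan and has no intrinsic size limit.

## Known limitations

* The centroid-variant Dunn index is not the classical Dunn; comparisons
  with other software must use the variant flag consciously.
* The sum-form Davies–Bouldin grows with M by construction; across-k
  comparisons should use the `mean` variant (reports carry the variant).
* The 1-D chain topology is the right inductive bias when neurons ≈
  clusters, but it is not a general-purpose SOM; no 2-D grids, batch or
  growing maps.
* The selection thresholds are calibrated for DS trajectories of sustained
  activities; very short recordings (dwell comparable to the smoothing
  window) will under-report dwell fractions.
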