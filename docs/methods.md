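# Methods

`masktrack` links time-lapse sequences of labeled segmentation masks into
global tracks with division and fusion lineages. It is deliberately
segmentation-independent: the only input contract is an integer image per
frame in which 0 is background and each positive value is one object. This
note records the model, the tunable parameters, the numerical choices, what
the synthetic-data generators do and do not emulate, and known limitations.

## Frame-to-frame linking model

For an object *i* at time *t* and an object *j* at time *t+1* the linking
cost is a weighted sum of three normalised terms:

```
Cost(i, j) = w_o · (1 − O_ij) + w_c · δ_c(i, j) + w_s · δ_s(i, j)
```

* `O_ij = |pixels(i) ∩ pixels(j)| / min(area_i, area_j)` — overlap fraction,
  normalised by the smaller object so that full engulfment of the smaller
  partner scores 1. This keeps the term meaningful when sizes change
  sharply, as they do around divisions and collisions.
* `δ_c = min(‖centroid_i − centroid_j‖, d_max) / d_max` — centroid
  displacement, saturating at the maximum plausible per-frame displacement
  `d_max`.
* `δ_s = |area_i − area_j| / max(area_i, area_j)` — relative size change.

Every term lies in [0, 1], so the weights are directly comparable and the
largest finite cost is `w_o + w_c + w_s`. A pair with zero overlap whose
centroids are farther apart than `d_max` is *infeasible* and can never be
linked; this bounds spurious long-range links and keeps the assignment
sparse. The term list is additive, so further criteria (shape, texture)
could be appended without changing the machinery; none are implemented.

Assignment between the remaining objects of a frame pair is a minimum-cost
bipartite matching (Hungarian algorithm, `scipy.optimize.
linear_sum_assignment`). Infeasible entries are encoded as a finite sentinel
strictly larger than any achievable matching sum and sentinel matches are
discarded afterwards, which preserves optimality over the feasible pairs at
maximum feasible cardinality. Equal-cost matchings are resolved by an
infinitesimal lexicographic (row, column) perturbation so runs are
reproducible. Linking is strictly consecutive-frame; there is no multi-frame
or multi-hypothesis optimisation.

Objects left unmatched are classified: at time *t* as mitotic mother,
left-field-of-view (the object touches the image border) or death; at time
*t+1* as daughter, entered-field-of-view or birth.

## Collision handling

A *collision* is two or more objects correctly segmented at *t* but merged
into one label at *t+1*. A *t+1* label is declared a collision cluster when
at least two *t* labels each have at least `min_collision_overlap` of their
own area inside it (default 0.5: each source must be majority-covered,
which distinguishes a genuine merge from grazing contact). The cluster is
split by a feedback loop into the mask: seeds are the intersections of the
cluster with each source's *t* footprint, and every remaining cluster pixel
joins the seed nearest by within-cluster geodesic distance, computed as a
level-synchronous multi-source breadth-first search with 8-connectivity.
Ties at equal distance go to the lower source label; cluster pixels
unreachable from any seed (disconnected debris) go to the lowest part. The
split conserves the cluster's pixel count exactly and each part is
non-empty. Watershed-based alternatives were rejected because their
tie-breaking is insertion-order dependent, which would break bit-exact
reproducibility.

With fusion tracking enabled (colony mode) the same many-to-one events are
treated as genuine merges: masks are never modified, the parents' tracks
end as `fused`, and a fresh child track starts with a fusion edge from all
parents.

Mitosis-versus-collision disambiguation: many→one is a collision (or
fusion), one→many is a division. Collision handling runs first on each
frame pair; objects it consumes are excluded from mitosis detection and
assignment.

## Mitosis detection

A mother *m* at *t* with candidates {d1, d2} at *t+1* is accepted as a
division when all four hold:

1. at least two *t+1* objects overlap *m* by ≥ `min_division_overlap` of
   their own area with *m* as their dominant source (if more than two, the
   two with the largest overlap are tested; the rest are new objects);
2. `circularity(m) ≥ min_mother_circularity` — mothers round up before
   dividing. This is evaluated on frame *t* only; a multi-frame roundness
   trend would need a look-back buffer and is not implemented;
3. the combined daughter overlap covers ≥ `min_division_overlap` of the
   mother's area — dividing cells barely migrate;
4. daughter min/max area ratio ≥ `min_daughter_size_similarity` and min/max
   aspect-ratio ratio ≥ `min_daughter_aspect_similarity` — daughters are
   similar in size and shape.

Each object joins at most one event, and raising any threshold can only
remove events (monotone filtering).

## Parameters

| name | default | meaning |
|---|---|---|
| `w_o` | 1.0 | overlap weight (dimensionless); overlap-dominant by default since overlap is the primary evidence for continuation, collision and division |
| `w_c` | 0.5 | centroid-displacement weight |
| `w_s` | 0.2 | size-change weight |
| `d_max` | 50 px | largest plausible per-frame displacement; feasibility gate and `δ_c` scale. Chosen as several cell diameters at typical live-cell frame rates; should be lowered for slow or small objects |
| `min_collision_overlap` | 0.5 | majority coverage of a source by a cluster |
| `min_division_overlap` | 0.2 | per-daughter and combined mother-overlap gate |
| `min_mother_circularity` | 0.3 | permissive roundness gate (circularity = 4πA/P², clipped to 1) |
| `min_daughter_size_similarity` | 0.5 | min/max daughter area ratio |
| `min_daughter_aspect_similarity` | 0.7 | min/max daughter aspect-ratio ratio |
| `min_track_lifespan` | 5 frames | lifespan gate of the confidence index |
| `enable_fusion` | false | colony mode: record fusions instead of splitting |

The mitosis defaults are permissive and were set against the simulator's
division scenarios; they are exposed per cell line.

## Confidence index

Per track, the average of four binary indicators: lifespan ≥
`min_track_lifespan`; never touches the image border; never involved in a
collision split or fusion; no frame-to-frame link cost above half the
maximum finite cost scale. The composition is this package's own
four-indicator construction covering track completeness, border effects,
contact events and link quality; users needing a different weighting can
recompute from the exported track table, which carries all four inputs.

## Evaluation metrics

Estimated tracks are paired with reference tracks either by gated centroid
distance (per frame, an optimal assignment forbidding pairs at distance ≥ ε;
ε defaults to 5 px) or by mutual maximum overlap between mask sequences
(each object must be the other's unique argmax). Assignment-based pairing,
rather than greedy nearest, makes the result order-independent.

With `D` the sum over reference positions of the paired gated distance (ε
for unpaired positions) and `D_dummy = ε ·` (number of reference
positions):

* `Alpha = 1 − D / D_dummy` — ignores false-positive tracks;
* `Beta = (D_dummy − D) / (D_dummy + ε · FP_positions)` — penalised by
  unpaired estimated positions; `Beta ≤ Alpha`, equal iff no false
  positives;
* `Jaccard = TP / (TP + FN + FP)` over frame-to-frame tracking decisions;
* `Jaccard Theta` — the same ratio over whole tracks: an estimated track is
  a true positive only if it pairs with one reference track over that
  track's complete lifetime, so a single broken link destroys a whole-track
  true positive.

All four lie in [0, 1]; 0 means all tracks missed, 1 all tracks perfect.
The empty-versus-empty Jaccard is defined as 1 and logged. The Alpha/Beta
closed forms are this package's construction from their verbal definitions
(distance-proportional, false positives ignored versus penalised), in the
style of particle-tracking-challenge scoring; they are not guaranteed to
match any specific external scoring plugin constant-for-constant.

## Synthetic data

`simulate_particles` renders rigid disks at any density with Brownian
(isotropic Gaussian steps), directed (constant heading plus noise) or
heading-switching motion, reflective boundaries and non-overlapping
placement; Brownian tracks satisfy MSD(t) = 2σ²t. `simulate_cells` renders
deformable blobs — disks with low-order radial Fourier perturbation, so
circularity and aspect ratio are controllable — with Brownian centroids
(default σ = 2 px/frame, i.e. displacement well under a cell radius, the
regime in which frame-rate selection makes overlap tracking meaningful),
scripted or random divisions that satisfy the four mitosis indicators with
margin (the mother's perturbation is annealed to a disk over the two frames
before the split; daughters are equal-area, similarly shaped and placed
inside the mother footprint), optional permanent fusion on contact, and an
optional degraded companion sequence in which touching cells are re-labeled
by per-frame connected components — exactly the collision failure mode of
real segmentation. True masks carry the ground-truth track labels, so a
perfect tracker reproduces them up to a label bijection and scores exactly
1.0 on all four metrics.

The generators emulate mask-level geometry only: no intensities, no point
spread function, no photometric noise, no segmentation boundary errors
other than contact merging, no 3D. A green test on simulated data therefore
establishes the correctness of the tracking logic and its bookkeeping, not
robustness to segmentation noise beyond the merge failure mode.

All randomness flows from one integer seed through NumPy's PCG64 generator;
sequences are bit-identical across runs and platforms.

## Numerical and degenerate-input choices

* Coordinates are (row, col), 0-based; centroids are unweighted means of
  pixel coordinates; connectivity is 8-connected throughout.
* Circularity is 4πA/P² with the scikit-image perimeter, clipped to 1.0
  where discretisation pushes it above; a single pixel has circularity 1.
* Aspect ratio is the moment-equivalent-ellipse major/minor axis ratio with
  the minor axis floored at one pixel-width equivalent, so 1-px-wide
  objects stay finite.
* Labels need not be consecutive or stable across input frames; global
  output labels are assigned in order of track creation (frame-major, then
  ascending frame label) for determinism.
* An empty frame is valid (zero objects); an empty input sequence is an
  error; frames of differing shape are an error.
* The tracker holds at most two frames of pixel data regardless of sequence
  length (`TrackingResult.peak_frames_held` audits this), so memory is
  independent of sequence length when masks are streamed.
* Frame numbering in all CSV outputs is 0-based and matches mask file
  order.

## Known limitations

* Linking is greedy in time: an error on one frame pair is never revised by
  later evidence (no global optimisation, no track smoothing).
* A collision can only be split if its sources were individually observed
  at the previous frame; merges present from frame 0 stay merged until the
  objects separate.
* If an object moves so fast that less than `min_collision_overlap` of it
  stays inside the merged cluster (per-frame displacement approaching the
  object radius), the collision is undetectable by overlap evidence and the
  identity may be lost until separation.
* Division into more than two fragments is reduced to the best daughter
  pair; the remainder become unrelated new tracks.
* 2D only; one label per object per frame; no intensity features.
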