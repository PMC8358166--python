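# Methods

This note documents the models and procedures implemented in
`phenorow`, the parameters that matter, the design choices made where
the design was genuinely open, what the synthetic fixtures emulate,
and the known limitations.

## Problem setting

A fixed camera faces each row of plants (e.g. maize) in a field trial
and takes side-view photos on a fixed schedule through the season.
The quantity of interest is each front-row plant's height over time,
from which a growth curve is fitted per plant. Two obstacles shape
the pipeline: field backgrounds are too heterogeneous for threshold
segmentation, and pixel-level training labels are too expensive to
produce by hand at scale.

## Self-supervised training set

Plant-class pixels come from greenhouse images, where a near-uniform
pale background makes the plant/background split trivial for K-means
on per-pixel RGB vectors (Euclidean metric, k-means++ with 10
restarts, fixed seed). Cluster identity is resolved without human
input: clusters are ranked by the green contrast (−R + 2G − B)/6 of
their centroids; the top cluster is plant body. With K = 3 the middle
cluster captures the blended boundary ("edge") between plant and
background and is discarded, keeping the plant class pure.
Background-class pixels are all pixels of field-image snippets that
contain only background. Features are the 27 RGB values of a pixel's
3×3 neighborhood in a fixed raster order (rows top→bottom, columns
left→right, channels R,G,B; features 12–14 are the center pixel);
border pixels replicate the image edge. The rationale for
neighborhood features is that plant and background pixels tend to be
surrounded by their own class, which suppresses salt-and-pepper noise
relative to single-pixel classifiers.

Key parameters: K ∈ {2, 3} (default 3); holdout fraction for
validation 0.01 (any positive fraction holds out at least one row).

## Pixel classifier

A fully connected network 27 → 1024 → 512 → 1 with ReLU hidden
activations and a sigmoid output, dropout 0.45 and 0.35 on the hidden
layers, binary cross-entropy loss, Adam (learning rate 0.001, β₁ 0.9,
β₂ 0.999), 20 epochs, batch size 1,024. A pixel is classified plant
iff its predicted probability is strictly greater than the 0.5
cutoff; ties go to background. The network is implemented directly on
numpy (He initialization, inverted dropout, numerically stable
softplus form of the loss); forward and backward passes are plain
matrix products, so training is reproducible for a fixed seed on a
given BLAS, and inference needs no deep-learning runtime. Weight
initialization and the remaining Adam constants are implementation
choices; training history (per-epoch loss and validation accuracy) is
recorded on the model so cross-backend float variation is visible.
Mask postprocessing (median blur, erosion, dilation, in any order,
odd kernels) is available but **off by default**: the core pipeline is
specified without it, and it is exposed as an explicit option only.

Images are normalized to [0, 1] by dividing 8-bit values by 255 on
read; optional rescaling (e.g. high-resolution field photos to
1000×750) uses bilinear interpolation.

## Front-row isolation

**Row-cut.** The mask's per-row plant fraction is smoothed by a loess
smoother — local quadratic regression with tricube weights over a
sliding window covering a `span` fraction of the profile (default
0.05; written in-house because the available lowess implementations
are locally linear). Peak segments are called by thresholding at
R_v = 10% of the global maximum; maximal above-threshold runs
separated by fewer than S_r = 10 below-threshold rows are merged
("≥ S_r apart" separates — the only reading under which S_r = 1 means
any gap separates). The bottom-most segment is the front row; from
its peak the band extends up to the first row whose smoothed value
falls below R_u = 7.5% of the peak and down to the first row below
R_l = 2.5%, clipped to the image. The pairing of R_u with the upper
boundary and R_l with the lower follows the order in which the two
thresholds are conventionally stated; it is a documented choice.

**Column-cut.** The per-column plant fraction inside the band is
squared (a quadratic power transform that magnifies peak maxima
relative to inter-plant troughs; it cannot move any argmax). Peaks
are called at C_h = 20% of the maximum with S_c = 50; each segment's
argmax (ties → smallest index) is a plant peak. Cuts between adjacent
plants sit at the floor of the midpoint of their peaks; the outer
margins sit D_I = max_j (I_p^(j+1) − I_p^(j))/2 columns outside the
first and last peaks, clipped to the band. Two deliberate choices:
the right margin is I_p^(m) **+** D_I (the mirror image of the left
margin — a minus sign here would place the right margin left of the
last peak, contradicting the geometry); and for a single plant, where
D_I is a maximum over an empty set, the margins sit one
above-threshold segment width away from the peak, a local analogue.
The column profile is not loess-smoothed; squaring only.

All profile-peak thresholds (R_v, S_r, R_u, R_l, C_h, S_c) are
exposed; their defaults suit ~1000-px-wide images and should be
scaled with image size (S_c in particular is a column distance).

## Height measurement

Within a plant's cut columns, the center part is the contiguous
column range around the column-mean peak whose means stay at or above
10% of the peak mean (the cut is the last column before the first
below-threshold column; if never reached, the image edge). Height is
the row-index difference between the first row from below and the
first row from above whose center-part row mean is strictly greater
than 2.5% of the maximal row mean. "Index difference" is implemented
literally: a solid band of n rows yields n − 1, and the fixtures
record ground truth in the same convention, so comparisons are
consistent. Heights are in pixels; no physical calibration is
applied.

## Time-series refinement

Four steps per camera: (1) row-cut every frame, track the band height
lower_row − upper_row, and detect a single upward mean shift — the
frame at which the front row begins to overlap the rows behind it;
frames from the changepoint onward are discarded. (2) Column-cut the
remaining frames, count plants, and keep only frames whose count
equals the modal count m (ties break toward a configured expected
count — the number of seeds planted — else toward the larger count).
(3) Stabilize peak columns against horizontal camera jitter:
Î_p^(i,j) = Ī_p^(j) + med_j I_p^(i,j) − med_j Ī_p^(j), with the lower
median for even m (determinism). Stabilized adjacent-peak spacings
are identical across frames by construction. Cuts are rebuilt from
the rounded stabilized peaks with the same midpoint/margin geometry.
(4) Re-measure each plant in every kept frame. Frames on which a
stage fails are skipped with a logged reason rather than aborting the
series.

The changepoint detector is an at-most-one-change mean-shift: the
split minimizing total within-segment squared error, accepted only if
the Normal log-likelihood improvement exceeds an SIC-style penalty
(default 2·log n — two extra parameters, the second mean and the
location). A smoothly *trending* series (plants growing, no overlap)
can legitimately exceed this penalty; where a series is known not to
overlap, the penalty can be set to infinity to disable truncation.
Multi-changepoint segmentation is out of scope.

## Growth curves

Time is rescaled to [0, 1]. The unconstrained curve μ̂ is a
Nadaraya–Watson estimate with the Epanechnikov kernel on the grid
i/N, i = 1..N (N = number of observations, at least 50); boundary
weights renormalize automatically. The smoothing bandwidth h_r is
chosen by leave-one-out least-squares cross-validation over a small
grid (0.03–0.25) unless given. Monotonization inverts an estimated
inverse growth function: inv(t) = N⁻¹ Σᵢ F((t − μ̂(i/N))/h_d), with F
the kernel CDF — a nondecreasing function of height t — evaluated on
512 points of the observed height range and inverted numerically at
the grid fractions i/N. The output is nondecreasing by construction
and clamps to the observed range (hence a constant input maps to
itself exactly, and a strictly increasing input is recovered as
h_d → 0 up to grid interpolation error). h_d defaults to 0.5× a
robust (MAD-based) residual-scale estimate from the unconstrained
fit. The fit is performed twice: observations whose first-fit
residuals lie strictly outside 3× the interquartile range around the
median residual are dropped (boundary values retained), and the curve
is refit on the remainder; R² = 1 − SSE/SST over retained points.
Shifting all heights by a constant shifts both curves exactly.

The monotonized curve tracks the pool-adjacent-violators (isotonic)
solution of μ̂ within about 2·h_d in sup norm on the test inputs; the
density-inversion estimator is preferred because it is smooth, while
isotonic regression produces flat steps.

## Synthetic fixtures

The fixtures render schematic but structurally faithful scenes, with
all randomness drawn from a single seed per scene (bit-identical
regeneration):

* **Greenhouse scenes** (default 200×200): a green stem-plus-leaf-
  ellipse silhouette on a pale noisy background, with a one-pixel
  blended ring just outside the silhouette emulating the soft
  boundary that K-means isolates as a third class. The truth mask is
  exactly the silhouette; the ring is background in truth.
* **Field scenes** (default 1000×750): a front row of plants on a
  common baseline (stems guarantee the recorded pixel height is the
  exact mask row extent; leaves are clipped to the stem's vertical
  extent and to a maximum half-width so plants remain separable), a
  back row of smaller plants above a clearance larger than the
  row-smoother's half window, and a textured background — sky band,
  dirt with patches, shadows, poles. Front-row heights default to
  0.85–1.0× the maximum: plants in one row are siblings of one
  genotype and grow alike, which also keeps every column peak above
  the 20% calling threshold. Field plant color is deliberately offset
  from greenhouse plant color (both far from all background colors in
  green contrast) to exercise the domain transfer.
* **Camera series**: per-plant logistic growth rounded and forced
  nondecreasing; whole-row integer horizontal jitter per frame;
  per-(frame, plant) dropout; from a configurable overlap-onset frame
  the back row is pulled down to touch the front row's top, so the
  band height jumps as the rows merge.
* **Height series**: a known nondecreasing curve (logistic by
  default) plus i.i.d. Gaussian noise and optional gross outliers at
  stated indices.

What the fixtures do **not** emulate: perspective, lighting and
weather variation, leaf texture, plant-on-plant occlusion within the
front row, weeds, and camera refocus — so passing tests demonstrate
the algorithms' correctness on color-separable, row-banded scenes,
not robustness to every field condition.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at reduced
scale chosen to exercise the same geometry cheaply: transfer
segmentation trains on ~60k pixels and evaluates on 20 scenes of
400×300; isolation runs at the full 1000×750 default; the end-to-end
run uses 16 frames of 320×240 with 3 plants. Peak calling is exact
integer logic verified against a brute-force oracle on 1,000 random
profiles. Ties everywhere resolve deterministically (argmax → smallest
index; lower median; strict threshold inequalities with ties going
away from the plant class). Degenerate inputs raise informative
errors: all-zero masks/profiles, single-class training tables, K = 1,
decreasing truth curves, too-short series, even morphology kernels.

## Known limitations

* After the front and back rows overlap, no heights are produced;
  separating overlapping rows would need a different segmenter.
* The mean-shift changepoint model reads a strong smooth trend as a
  change; band-height truncation should be disabled for series known
  to stay separated.
* The 7.5%/2.5% band boundaries can clip the very tip of a plant that
  is much taller than its neighbors, biasing its height low; with
  same-genotype rows this effect is ≤ a few pixels.
* Pixel heights are not calibrated to physical units.
* K-means labeling assumes the greenhouse background is unimodal in
  color; strongly bimodal backgrounds would need K > 3.
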