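# Methods

`enterogram` implements a quantitative-imaging pipeline for bowel
obstruction on CT: centerline annotations of the gastrointestinal tract are
rasterized into voxelwise label volumes, a multi-output 3D U-net learns to
predict those volumes from the CT intensities, and the predictions are
summarized as diameter-vs-longitude/length curves and threshold statistics.
This note records the model, its assumptions, the numerical choices, and
what the synthetic phantom does and does not establish.

## The longitude coordinate

The gastrointestinal tract is parameterized by a continuous, unitless
coordinate ("longitude") running from 10 at the esophagus to 150 at the
anus.  Each of 15 organs owns one decade (stomach 20–30, ligament-of-Treitz
jejunum 40–50, …, cecum 90–100); within an organ the coordinate grows
proportionally to arc length,

    longitude = L0 + 10 · s / S,

with `s` the cumulative arc length from the organ's proximal end and `S`
the organ's total annotated length.  A point 5 cm into a 25 cm stomach is
at 22; 5 cm before its end, at 28.  Two landmarks matter clinically: the
ligament of Treitz (40) and the ileocecal valve (80); diameters above 30 mm
between them define dilated small bowel.

Organs annotated as several discontiguous segments (typical for jejunum and
ileum) are chained before assignment by minimizing the total Euclidean gap
between consecutive segment endpoints — exhaustively over all permutations
(orientations resolved exactly by dynamic programming) up to 8 segments,
greedily beyond.  The chain is anchored at the previous organ's terminal
point so the traversal direction is well defined.  Inter-segment gaps
contribute no arc length: longitude measures along annotated bowel, and
anatomy that is continuous in longitude but discontiguous in space
(terminal ileum/appendix, ostomies) is expected.  Arc length is the
piecewise-linear point-to-point distance in mm.  Longitudes beyond 150
(distal anus) are clipped to 150.

## Embedding

Every voxel center is projected onto every segment's polyline (projections
clamp to the endpoints, so tubes end in hemispherical caps).  The segment
with minimum distance claims the voxel; ties break to the lower segment
index for determinism.  If the distance is within the radius — half the
diameter linearly interpolated at the projection foot — the voxel gets
segmentation 1 and the interpolated diameter (mm) and longitude; otherwise
all three volumes are 0.  The implementation is a vectorized version of
exactly this per-voxel/per-segment loop and is tested bit-identical to it;
no approximate acceleration is used.

A consequence of the support rule is that {diameter > 0} = {longitude > 0}
= {segmentation = 1} everywhere, which downstream code validates.

## Synthetic phantoms

The phantom generator stands in for the clinical cohort.  Each phantom is a
chain of smooth random tubes (one or two segments per organ) laid out in a
supine anatomic arrangement: each organ's random walk is attracted toward
its stereotyped region of the abdomen (stomach left-upper, cecum
right-lower, …).  This layout is not cosmetic: position relative to
anatomic landmarks is the information a network uses to infer longitude on
real CT, and a positionless phantom would make intra-small-bowel longitude
unlearnable in principle.

Per-organ lumen attenuation defaults to fluid (~10 HU) for the upper tract
and small bowel and gas (−1000 HU) for the colon, over a soft-tissue
background (40 HU) with additive Gaussian noise (σ = 10 HU, a typical
soft-tissue-kernel noise level).  In-lumen voxels additionally carry an
organ-specific periodic fold texture (prominent jejunal plicae circulares,
a comparatively featureless ileum, coarse colonic haustra, gastric rugae)
— the local cue radiologists themselves use to tell bowel segments apart.
Defaults: 32³ voxels at 5 mm (tubes span roughly 4–8 voxels, similar in
relative resolution to the full-scale resized data), organ lengths scaled
to the miniature field of view.

With an obstruction configured, small-bowel diameters upstream of a
transition longitude (drawn in 45–75) take a dilated value (default 40 mm)
and relax to the base calibre (16–24 mm) over a ~20 mm arc, so the
diameter-vs-longitude curve shows a realistic transition point.  Ground
truth is exact by construction: the stored label volumes are
`embed_annotations` applied to the generated centerlines, and query points
lie on the centerline with the annotated diameter as their measurement and
the organ midpoint (L0 + 5) as their presumed longitude — one point per
organ, four each for jejunum and ileum.

What the phantom does **not** model: bowel wall thickness (the tube is the
outer diameter, as in the embedding itself), peristalsis/deformation,
beam-hardening or scanner kernels, extraluminal pathology, and the
anatomic variability of real patients.  Passing the recovery experiment
therefore shows the pipeline is implemented correctly and the features are
learnable from realistic cues at desk scale — not that the shrunken network
would reach clinical performance on real scans.

## Preprocessing

Inference order is pad → resize → window/level; augmentation acts on padded
native-resolution volumes before resizing.  CT is window/leveled at 400/40
HU onto [0, 1]; padding appends −1000 HU (air) slices at the superior end
up to the next multiple of the axial quantum (default 192), labels pad with
0.  Resizing preserves world extent (trilinear for CT, nearest-neighbor for
all label volumes) and rescales the voxel spacing.  Augmentation applies
one rigid + isotropic-scale transform (|rotation| ≤ 15°, |translation| ≤
15 mm, scale within 15%), about the volume center, identically to CT
(trilinear, −1000 fill) and labels (nearest, 0 fill).  Diameter maps are
converted mm → voxel units (mean in-plane voxel size) before training and
back after prediction.

## Network

A 3D U-net with one input channel (CT) and three parallel single-channel
heads (segmentation logits, longitude, diameter) attached to the final
intermediate layer, not to each other.  Each level is two 3³ convolutions,
each followed by batch normalization and ReLU, then dropout (rate 0.1);
2× max-pooling descends, nearest-neighbor 2× upsampling ascends, with skip
concatenations between encoder and decoder layers of equal spatial shape.
The default ladder is 16 → 512 channels over 7 levels (a 256×256×192 input
reaches a 4×4×3 bottleneck) and counts 36.6 M trainable parameters — the
deepest skip (pre-bottleneck encoder into the first decoder layer) is
disabled by default because the published 37 M total matches the
architecture without it (40.1 M with it); a flag restores it.  The network
is fully convolutional, so the parameter count is independent of input
shape.

Because training uses batch size 1 (whole volumes), batch normalization is
effectively instance normalization; the implementation deliberately uses
the sample's own statistics at inference too.  With running-average
statistics instead, the regression heads were systematically compressed
toward zero by the train/inference normalization mismatch.

The loss is `w_seg·BCE + w_long·MSE + w_diam·MSE` over all voxels, BCE on
logits in the numerically stable form, regression targets zero outside the
mask.  The regression weights default to 1 / mean(target²) over the
training set, which puts every term near 1 (the loss of an all-zero
prediction) at the start of training so all three are optimized; fixed
weights can be supplied.  Optimization is Adam at 1e-3 (default); the
desk-scale recovery configuration uses 2e-3, where the shrunken network is
otherwise still under-fitted at its epoch budget.  Prediction thresholds
the sigmoid at 0.5 and applies the mask to the diameter and longitude
outputs (their support may otherwise differ), clamping in-mask values to
their physical ranges (diameter > 0; longitude in [10, 150]) and
converting diameter back to mm.

## Curves and decision rule

Masked volumes are binned into 1-unit longitude intervals over [10, 151):
per bin, V = mask-voxel count × voxel volume (conserved exactly across
bins) and D = unweighted mean of the voxels' diameters.  Assuming each bin
is a cylinder, L = 4V/(πD²) converts to physical length; diameter against
cumulative length is the obstruction curve, annotated at longitudes 40/80
and the 30 mm threshold.  A query point is *dilated small bowel* when the
nearest voxel is in the mask with D > 30 mm and 40 < longitude < 80
(strict inequalities; exactly 30 mm is neither dilated nor nondilated).

## Statistics

Dice per scan is computed on three randomly selected axial slices
constrained to contain stomach, small bowel and colon respectively
(exhaustive manual segmentation being the time-prohibitive alternative the
protocol mirrors).  Agreement at query points uses ICC(A,1) — two-way,
single measurement, absolute agreement, computed from the mean squares —
with an F-test (MSR/MSE) against zero correlation; absolute agreement
penalizes systematic bias, unlike Pearson correlation.  Threshold tasks
(diameter > 30 mm; longitude < 40; > 80) use ROC/AUROC with the
Mann–Whitney tie-handling convention (the < 40 task negates the predicted
longitude so larger scores mean positive).  AUROC comparisons use DeLong's
structural-components variance — paired with covariance, or summed
variances across independent cohorts.  Joint dilated/nondilated calls are
summarized by sensitivity/specificity with McNemar's test on the
discordant pairs (continuity-corrected χ², exact binomial below 25
discordant pairs); group comparisons of Dice use Welch's unpaired t-test.
ROC and McNemar go through scikit-learn and statsmodels; ICC and DeLong
are implemented here (tested against pingouin and against brute-force
pair-counting/bootstrap oracles).

## The scaled-down recovery experiment

`enterogram.experiments.scaled_down_recovery` mirrors the full study at
desk scale: 25 phantoms at 32³ (20 train / 5 held out), obstruction
stratified at prevalence 0.5 on both sides of the split (a Bernoulli draw
can otherwise leave the 5-scan test set without a single obstructed
phantom, making sensitivity undefined), a base-8-channel 3-level U-net,
50 epochs of Adam at a constant 2e-3, then the full statistical battery on
the held-out scans.  Problem sizes were chosen so the whole experiment
runs in minutes on one CPU.

The experiment is stochastic; with the seed fixed it is reproducible, but
across seeds the held-out metrics vary noticeably because the test side is
only 5 scans and ~10 dilated query points: over three seeds we measured
Dice 0.71–0.79, diameter ICC 0.51–0.60, longitude ICC 0.43–0.65 and
dilated sensitivity 0.67–1.0.  Train-time augmentation was evaluated for
this experiment and rejected: at 4–8-voxel tube calibres the
nearest-neighbor label warping and the ±15% scale transforms (which the
diameter labels do not track) degrade the dilated-diameter regression more
than the extra data helps.  Augmentation remains part of the preprocessing
module for full-scale use.

## Numerical and degenerate-input choices

- Closest-segment ties: lowest segment index.  Chain-orientation ties:
  unflipped, lower input index.
- Zero-length polyline edges (coincident points) project with t = 0.
- Empty masks: Dice of two empty masks is 1; bins with no voxels carry
  V = 0 and undefined (NaN) diameter and are excluded from curves;
  L = 4V/(πD²) is 0 when V = 0 and rejected when V > 0 with D ≤ 0.
- ICC requires ≥ 3 pairs and non-degenerate variance; single-class label
  vectors are rejected by ROC/DeLong.
- NIfTI affines must be axis-aligned up to permutation/flip (supine axial
  geometry); volumes are reoriented to a canonical axis order on read.
  Gzip output carries a zero mtime so rewrites are bit-identical.
- Identity augmentation parameters short-circuit to exact copies.

## Known limitations

- The numpy network engine is single-threaded BLAS-bound; full-scale
  (256×256×192, 37 M parameters, 222 epochs) training is out of reach and
  out of scope — the architecture is validated structurally (ladder,
  bottleneck shape, parameter count) and functionally at desk scale.
- Longitude ICC at query points is bounded below 1 even for a perfect
  model because the reference longitude is presumed (organ midpoint), not
  measured.
- The greedy chaining used above 8 segments per organ is not guaranteed
  optimal (exhaustive search is, and covers the annotation sizes seen in
  practice).
- Overlapping tubes (adjacent loops) resolve by closest-centerline, which
  can reassign boundary voxels of one organ to a neighbor; query points in
  heavily overlapped regions inherit that ambiguity.
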