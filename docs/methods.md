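# Methods

`strokeface` re-implements a facial-image pipeline for recognizing acute
ischemic stroke: 3D scan preprocessing, CNN classification with
AUC-weighted ensembling, statistical interpretation maps, and
clinical-marker association/causal analysis.  Because the clinical scans
that motivated the method cannot be shared, the package is organized
around a synthetic-face generator with *planted* stroke effects, so that
every stage has a known ground truth to recover.  This note records the
models, the conventions the original description leaves open, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Synthetic faces and planted effects

Faces are built on a fixed 73 x 73 parametric template (5329 vertices
over a 14 x 18 cm frontal patch): an ellipsoidal head surface, Gaussian
soft-tissue features (brows, forehead, chin, mouth ridge, eye sockets),
a faint sinusoidal skin ripple, and a protruding near-spherical nose cap
(radius 1.4 cm).  Two deliberate geometric properties serve the
preprocessing stage:

* the nose cap is an exact sphere apart from a small 4th-order radial
  taper (0.04 d^4 cm), so the sphere-fit loss has a unique, strictly
  separated minimum at the apex — at the apex the loss is limited only
  by vertex noise, while every other region (including near-umbilic
  points of the head ellipsoid, which would otherwise fit a sphere
  almost perfectly) carries measurable asphericity from the ripple;
* the head ellipsoid is narrow (semi-axis 9.5 cm horizontally vs 17 cm
  vertically) and centered 2 cm above the nose, which makes the
  principal axes and the up/down vertex-count asymmetry of the 5-cm nose
  region deterministic — the pose-correction sign conventions below rely
  on this.

Stroke samples receive two planted effects with recorded ground truth:
a blue-channel shift of `blue_effect` (default 30 on the 0–255 scale)
over a central-face vertex mask (ophryon + mouth ellipses), emulating
central cyanosis, and a smooth downward displacement of the lower face
by `droop_effect` cm (default 0.3; mouth corners get ~0.7 of it, the
chin ~1.0).  Per-vertex color noise (sd 8) and positional noise
(sd 0.003 cm, scanner-level) are added, then a random rigid pose
(rotation up to 15 degrees, translation up to 2 cm).  All randomness
flows from one `numpy` generator per cohort; identical seed and
configuration give byte-identical output.

The base blue channel is spatially constant, so the planted in-mask
minus out-of-mask blue contrast equals `blue_effect` exactly in
expectation; the generator calibration test verifies this on 200 faces.

Clinical markers are drawn from declared linear structural chains
driver → mediator → stroke score.  Generation is conditional on the
realized score (mediator = beta * z(score) + noise; driver =
beta * z(mediator) + noise), which realizes exactly the
conditional-independence structure of a chain with the driver at the
far end.  With the default beta = 0.8 and noise sd 0.6 the implied
driver–score correlation is beta^2 ~ 0.64.  At least one declared null
marker is always present.

What the generator does **not** emulate: real scanner artifacts
(holes, specularity, hair), morphological variation between subjects
(every face is the same template plus noise), age/sex dependence of the
signal, and any physiologic coupling beyond the two planted effects.
Passing benchmarks therefore demonstrate that the pipeline recovers
signals of the stated kind and size under controlled conditions — not
clinical performance.

## Preprocessing

1. **Nose tip.**  For every vertex with at least 10 neighbors within
   1.5 cm, a sphere is fitted to the neighborhood by the algebraic
   least-squares formulation (expanding |v − O|² = r², a 4-parameter
   linear system; the radius is free).  The reported loss is the
   geometric mean squared radial residual, and the tip is the exhaustive
   argmin over candidates.  The batched solver adds a 1e-9 ridge so
   exactly coplanar neighborhoods stay solvable (their loss is large and
   never wins).
2. **Pose correction.**  PCA of all vertices within 5 cm of the tip.
   Axis convention (the description leaves eigenvector order and sign
   open): eigenvalues descending → largest-spread axis is face-up **Y**,
   smallest-spread axis is the viewing normal **Z**, X = Y x Z closes a
   right-handed frame.  Signs: +Z makes the nose tip extremal toward the
   viewer relative to the region centroid; +Y points toward the side of
   the nose with more vertices (the upper face); exact ties break
   lexicographically.  The rotation is iterated 3 times (convergence is
   monotone; one iteration is already within numerical noise on clean
   scans).  The nose tip is translated to the origin.
3. **Z-buffer projection.**  0.1 cm grid over the X–Y bounding box,
   image convention (row 0 at top, X → columns, Y → rows); each cell
   keeps the vertex with the largest Z (larger Z = closer to viewer).
   The depth pixel is exactly that vertex's Z — asserted as an invariant.
   Unmapped cells within 3 cells of a mapped one copy their nearest
   mapped neighbor (the mapping entry follows, so the depth invariant is
   preserved); farther cells are background (0 intensity, mapping −1).
4. **Crop / resize.**  The unmapped margin is cropped to the face
   bounding box, the box is padded symmetrically with background to a
   square (aspect preserved), then bilinearly resized to 224 x 224.
   The pixel→vertex mapping is resized with nearest-neighbor; after
   interpolation the final depth image is no longer bit-exact per pixel
   (the exactness invariant applies at native resolution).  Each pair
   carries the composed affine from pose-corrected (x, y) cm to
   (row, col) pixels, which is how ground-truth 3D landmarks obtain
   their 2D coordinates.

## Classification

The dataset layer performs a stratified random 10-fold split
(stratification guarantees both classes in every test fold at small n),
then replicates stroke samples three times and adds a left–right
mirrored copy of every image.  Replication happens after splitting, so
all replicates of a sample share its fold.  Flipped replicates are used
in training and in test-time averaging (a sample's probability is the
mean over all of its augmented replicates).

The trainable backbone is `tiny`: a numpy CNN
(conv3x3 → ReLU → maxpool2 → conv3x3 → ReLU → flatten → dense-2) with
softmax cross-entropy and Adam.  Inputs in [0, 1] are average-pooled
224 → 28 and centered; at that scale the planted signal (a smooth color
shift over face regions) is fully preserved.  The head is dense rather
than globally pooled so localized evidence reaches the logits at full
strength — with global average pooling the mask signal is diluted by
the face area and training at these sample sizes stalls.  The tiny
profile is 5 epochs, learning rate 1e-3, batch 16; the four named
backbones (Xception, ResNet50, VGG19, EfficientNetB1) are optional
plugins behind the same interface that require a deep-learning
framework and pretrained weights (epochs 20, lr 1e-4 defaults follow
the original protocol).  Training is seeded and single-run
deterministic.

Ensembling: per fold, each backbone's held-out AUC weights its
probability, `final = Σ (AUC_i / Σ AUC_j) p_i` — a convex combination.
The weighting AUC is computed on that fold's held-out predictions (the
original description does not say which data the weights come from; a
training-data variant would be the alternative).  A fold AUC of exactly
0, possible at very small fold sizes, is floored at 1e-3 so weights stay
defined.  Classification threshold: probability ≥ 0.40 is stroke (the
boundary itself is assigned to stroke; the original wording leaves 0.40
unassigned).

The binomial confidence half-width is `Int = z sqrt(Accu(1−Accu)/N)`.
The default z is 1.96: the printed intervals this formula reproduces
(0.088 at Accu 0.73, N 97; 0.025 at Accu 0.86, N 736) are consistent
with 1.96 and not with 1.64, although the prose states 1.64; both are
selectable.  AUC uses the rank (Mann–Whitney) formulation with midrank
ties.

## Interpretation

* **Differential maps**: per-pixel two-sided Mann–Whitney U between
  groups on one channel; Bonferroni by default (BH selectable), sign
  from the group-mean difference; constant pixels record p = 1.  The
  Mann–Whitney p is asymptotic, so at very small group sizes (~12 vs
  12) no pixel can clear a 50k-test Bonferroni bar even under perfect
  separation — the planted-recovery benchmark therefore runs at
  100 vs 100.
* **Correlation maps**: per-pixel Spearman rho against the ensemble
  probability with the t approximation for p, BH-FDR masked.
* **Grad-CAM**: maps from the last conv layer, channel weights = spatial
  mean of the class-score gradient, rectified, bilinearly upsampled,
  averaged over correctly-predicted samples and over models.  For the
  two-class softmax head the class-score gradient is the logit contrast
  (class minus rival) up to a positive per-sample factor; using a single
  logit instead loses whatever evidence the net encodes in the rival
  logit.  Single tiny models localize unreliably (a random-init CNN can
  separate the classes without its rectified map concentrating on the
  planted mask); the mask-focus property is asserted for the
  model-averaged map, which is also how the method is used (four CNNs
  averaged).
* **Landmarks**: 72 named template points; 3D coordinates from the
  pose-corrected cloud, 2D through the recorded raster affine.  Pairwise
  3D Euclidean distances are Spearman-correlated with probability;
  the −log10 p matrix is ordered by hierarchical clustering (average
  linkage on Euclidean row distances — linkage unstated in the original,
  chosen here and fixed).  Landmark detection on real images is a
  pluggable interface; synthetic runs use generator ground truth.
* **PLSR**: 2-component partial least squares regression of probability
  on the flattened (n_vertices x 3) registered coordinates; synthetic
  faces share topology so registration is the identity.  The planted
  droop appears as negative Y coefficients at mouth corners and chin.

## Clinical analysis

Markers observed for more than 40 subjects enter analysis (a marker
with exactly 40 observations is excluded).  Group comparisons use
Mann–Whitney at the 0.40 probability threshold; correlations use
Spearman; both are BH-corrected, and uncorrected p < 0.05 is reported
alongside q, matching the exploratory stance of the original analysis.

The causal inference test for an ordered triple (driver L, mediator M,
outcome Y = stroke probability) combines four component p-values, with
the omnibus p their maximum:

1. F test of L in Y ~ L;
2. F test of L in M ~ Y + L;
3. F test of M in Y ~ L + M;
4. an equivalence test of L ⊥ Y | M whose null hypothesis is
   *dependence*: surrogate outcomes Y* = fit(Y~L) + permuted residuals
   keep the direct L→Y association at its observed strength while
   destroying mediation; p4 is the fraction of surrogate conditional F
   statistics (for L in Y* ~ M + L) at or below the observed one, with
   the +1 correction.  1000 permutations by default, seeded.

Under a true chain the surrogate F is at the marginal-association level
while the observed conditional F is central, so p4 is small; under the
reversed triple or full independence the two distributions coincide and
p4 is uniform.  Networks are built with significant markers as drivers
(network 1) and as mediators (network 2), BH-FDR across all tested
triples at q < 0.20, edges annotated with pairwise Pearson correlations
and kept only when both adjacent pairs have PCC p < 0.05.  Triples need
at least 50 complete cases; constant variables skip the triple with a
log entry.  Whether the original used linear or rank-based component
tests is unstated; linear is implemented, matching the Pearson
annotations.

The forward-risk quantity from follow-up counts is the
incidence-proportion ratio (a/n1)/(b/n2) — for the recorded counts
(3 of 57 false positives vs 1 of 92 true negatives) this is 4.84,
which is the printed value; the classical 2x2 odds ratio of the same
table is 5.06 and is reported alongside.  Zero reference events return
infinity with a warning.

Saturation analysis retrains the backbone at increasing stroke counts
(default sizes 35…185 with 3:1 matched controls, mirroring the original
cohort design) and evaluates each on a fixed independent cohort.

## Benchmark problem sizes

The standard self-validation conditions, used by both the test suite
and `scripts/acceptance.py`:

* geometry oracle suite — 20 posed faces (detector vs brute-force
  argmin; 25-degree pose recovery below 0.1 cm RMSD; exact depth
  round-trip);
* planted classifier benchmark — n = 60/60, 10-fold CV, tiny backbone,
  5 epochs; blue shift delta = 40 (droop off, so the color effect alone
  carries the signal) over 3 seeds, and delta = 0 over 5 seeds for null
  calibration;
* differential-map recovery — n = 100/100, delta = 40, Bonferroni;
  label-shuffled null on the same cohort;
* CIT — chains with beta = 0.8 at n = 500 over 20 seeds for
  directionality; 200 independent triples at n = 150 for the null
  retention rate.

## Known limitations

* The tiny backbone is a deliberately small CPU model; it demonstrates
  the pipeline's mechanics and planted-signal recovery, not the
  representational capacity of the pretrained ensemble.
* Grad-CAM localization is a property of model averages, not of every
  individual tiny model (see above).
* The synthetic shared-topology shortcut removes the dense-registration
  step entirely; PLSR results on real scans would depend on the quality
  of an external registration.
* CIT component tests are linear; strongly nonlinear marker relations
  would call for rank-based variants.
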