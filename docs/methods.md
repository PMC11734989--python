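# Methods

This note records the models and procedures behind `wildagree`, the
defaults and the reasoning for them, and what the synthetic tests do and do
not establish.

## Annotation model and geometry conventions

Coordinates are 0-based with the origin at the image top-left. A box
(x, y, w, h) covers the half-open region [x, x+w) × [y, y+h); intersection
and union areas, and hence IOU, follow from plain interval arithmetic under
this convention. Polygon annotations (as experts often draw) are reduced to
their axis-aligned envelopes on ingestion, because every downstream
operation — center clustering, the coordinate-wise median box, IOU — is
box-based. The class scheme is closed: labels outside it are rejected at
read time with a logged count rather than silently retained, since a single
stray label would otherwise distort vote tallies.

**Tiling.** Large frames are sliced into a row-major, non-overlapping grid.
The row/column count is the rounded ratio of image to tile size, and the
final row/column is clipped or extended to the image edge. A trailing
remainder smaller than half a tile is therefore absorbed into the last
row rather than forming a sliver tile: a 5472 × 3648 frame with 684 × 521
tiles yields exactly 8 × 7 = 56 tiles, the last row being 522 px tall.
Every pixel belongs to exactly one tile, so annotation assignment by box
center conserves the annotation multiset; boxes straddling a tile edge are
clipped to their assigned tile.

## Consensus aggregation

Clustering is standard DBSCAN (scikit-learn) on box centers, strictly per
image frame. Defaults are a neighborhood radius ε = 15 px and a minimum
cluster size of 5 with the point itself counted; the alternative reading
(five *other* neighbors) is exposed as `--min-neighbors`. DBSCAN's
classical ambiguity — border points reachable from two clusters — is
resolved by sorting input deterministically (observer id, then x, then y)
before clustering, so reruns are bit-stable.

Each cluster's aggregate box takes the median of each coordinate
independently (mean of the two central order statistics for even counts).
The consensus class is the strict plurality of member votes; ties yield a
`NO_CONSENSUS` marker. At species level, a tie whose candidates all share
one morphological class records that class as a fallback, since such ties
carry usable coarse information. One box = one vote: an observer who drew
two boxes in one cluster contributes two votes, keeping aggregation
observer-agnostic.

`estimate_epsilon` locates the knee of the sorted k-th-nearest-neighbor
distance curve (maximum perpendicular distance to the chord joining the
normalized curve's endpoints). It is a tuning aid for choosing ε on new
data, not part of the default pipeline.

## Agreement metrics

An observer's annotation scores 1 when its label matches its cluster's
consensus class at the evaluation level, 0 otherwise. Discarded (noise)
annotations score 0 unconditionally — they represent detections the group
did not corroborate. Members of `NO_CONSENSUS` clusters are excluded from
agreement scoring entirely (there is no defined agreeing class), at the
overall level as well as per class. Per-class summaries key on the
*consensus* class of the cluster, so a goose vote inside a duck-consensus
cluster counts against duck's agreement.

Summary tables report annotation-weighted means by default (each annotation
contributes equally), with the observer-weighted mean (each observer
contributes equally) emitted alongside, since the two differ when
annotation volume varies across observers. Standard deviations use the
n−1 denominator.

The Pielou evenness of a vote tally is −(Σ pᵢ ln pᵢ)/ln S over the classes
actually voted for; S = 1 is re-scored to exactly 0. The index is invariant
to scaling the tally, 0 iff unanimous, and 1 iff uniform over S ≥ 2.

**Between-group matching** is greedy on descending IOU with a 0.5 default
threshold, one-to-one, ties broken by reference order. Greedy matching is
the detection-evaluation standard and deterministic; it can fall short of
the optimal assignment on adversarial overlap patterns, which the test
suite bounds against a maximum-cardinality oracle. **Count comparison**
uses per-tile totals and Student's pooled two-sample t with
df = n₁ + n₂ − 2 (Welch available via `ttest="welch"`); identical constant
counts return t = 0, p = 1 rather than the 0/0 NaN. Aggregates without a
consensus class still count as generic detections in count ratios.

## Image-attribute covariates

Geometry covariates per aggregate: box area as a percent of image area,
count of other aggregates within a radius of twice the larger box
dimension, Euclidean distance from the image center in pixels, and the
density / same-class / rarity counts, all excluding the focal annotation.

GLCM texture features (contrast Σ P(i−j)², dissimilarity Σ P|i−j|,
homogeneity Σ P/(1+(i−j)²), energy √(Σ P²)) are computed on a symmetric,
normalized co-occurrence matrix of gray levels quantized to 32 bins
(ITU-R 601 luma for RGB input), averaged over pixel offsets 1, 3, 5 at
eight 45° angles. Diagonal offsets use the round(d·sin θ), round(d·cos θ)
convention shared with scikit-image, against which the rectangular case is
verified exactly. 32 levels balances matrix sparsity for bird-sized boxes
(tens of pixels) against intensity resolution; both levels and offsets are
arguments. The "donut" transition region — the box grown by 20 px minus
the box shrunk by 20 px, clipped to the image, hole omitted when the box is
too small to shrink — is a non-rectangular mask, so co-occurrence pairs are
accumulated under the mask directly rather than approximated by a bounding
rectangle.

## Reliability model

Each decided aggregate contributes a binomial response: votes for the
consensus class out of total votes. This preserves the information a plain
proportion regression would lose and weights well-supported clusters
appropriately. `NO_CONSENSUS` aggregates are excluded. Covariates are
screened by iterative VIF removal: VIFⱼ = 1/(1−R²ⱼ) from regressing column
j on the others (intercept included), dropping the single worst column
while any VIF exceeds the threshold (default 5); exact collinearity and
constant columns get infinite VIF and go first; ties resolve by column
order, making the filter deterministic and idempotent. The logit fit is
maximum likelihood via IRLS (statsmodels GLM), with Wald standard errors
and p-values; separation surfaces as a non-convergence flag. Class
indicator variables drop the most frequent class as reference.
`odds_change(β, δ) = exp(βδ)` converts coefficients to multiplicative odds
factors per δ-unit increase and composes multiplicatively in δ.

## Synthetic data

The generator emulates the conditions of a redundant aerial-survey
annotation campaign: frames the size of a presentation tile (684 × 521 px)
holding ~12 birds (the per-tile density observed in such campaigns), boxes
lognormal around 40 px (a duck-sized bird at sub-centimeter ground
resolution), and crowds of ~10–15 observers. The default observer errs
realistically: detection probability 0.9, isotropic Gaussian center jitter
σ = 3 px, lognormal size jitter (log-sd 0.1), 10% class-confusion mass
spread over the off-diagonal, and Poisson(0.5) spurious boxes per image
with uniform positions and labels. Target placement is rejection sampling
with a minimum center separation of 60 px (4ε), so ground-truth clusters
are unambiguous. Per-observer seeds derive from the master seed by SHA-256
hashing of the observer id: adding an observer never perturbs the others,
and every generator is bit-reproducible under a fixed seed. Rendered
images are stationary correlated-Gaussian textures per class over a
textured background — sufficient for exercising GLCM covariates, with no
pretense of photorealism.

What passing the synthetic suite shows: the pipeline recovers known target
counts within 2%, classifies ≥ 99% of consensus classes correctly, and
maintains member IOU ≥ 0.6 under the stated noise regime — the qualitative
regime a real campaign with comparable redundancy reports. What it does
not show: robustness to spatially correlated observer errors (observers
confusing the same ambiguous animal), heterogeneous per-observer skill,
occlusion and lighting effects, or boxes of wildly varying size; real
imagery also presents vegetation clutter whose spurious boxes may be
spatially clustered rather than uniform, which would challenge the
noise-rejection rule more than the simulation does.

## Numerical choices and degenerate inputs

Median of an even-sized cluster is the mean of the two central order
statistics. IOU of disjoint or zero-union pairs is 0. The knee estimator
returns the first curve value when all k-distances are equal. Empty
annotation sets aggregate to empty results; empty tallies, single-pixel
GLCM regions, boxes outside the image, and observers absent from an
aggregation all raise immediately with named errors. GLM convergence is
declared at statsmodels' IRLS tolerance (1e-10, 100 iterations max).
Problem sizes in the test suite (scenes of 12–50 targets, crowds of 10–15
observers, 20 replicates for recovery checks, logit recovery at n = 5000
aggregates × 10 votes) were chosen to make Monte-Carlo bands tight enough
to detect implementation errors while keeping the default run fast.

## Known limitations

- Aggregation is the cluster–median–mode scheme only; no probabilistic
  (EM-style) fusion of annotator reliability.
- IOU is box-based; polygon geometry is discarded at ingestion.
- Greedy matching does not claim to reproduce optimal-assignment match
  rates on dense, heavily overlapping scenes.
- No chance-corrected agreement coefficients (kappa-family); agreement here
  is raw proportion agreement with the consensus.
- The CLI reads PNG imagery; other raster formats should be converted or
  passed as arrays through the library API.
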