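# Methods

This note documents the models, conventions and design decisions behind
`fmclass`, in the order data flows through the package.

## Detection data model

A detection is one timestamped record of a tag heard by a georeferenced
receiver belonging to a named installation. Ingest applies the quality-
control filter (flags 1 and 2 retained by default; the flags are treated
as opaque pass values) and validates coordinates and timestamps row by
row — malformed rows are returned in a rejection report, never silently
dropped. Timestamps are stored at second resolution in UTC: inter-
detection intervals are analysed in minutes, so sub-second precision adds
nothing. Simultaneous detections are ordered lexicographically by
receiver name; the tie-break is arbitrary but fixed, making consecutive-
detection distance sequences reproducible. Duplicate rows are kept:
detection counts are a clustering covariate, so silent deduplication
would change results. Installation membership comes from the membership
table, not from coordinates.

## Movement covariates

Seven per-tag covariates: number of installations, number of detections,
mean time between consecutive detections (minutes), and the 25/50/75/99%
quantiles of great-circle distance (km) between consecutive detections.
Conventions that matter:

- **Distances use receiver coordinates** (the actual detection
  locations), not installation centroids, and include within-installation
  receiver-to-receiver hops — a literal reading of "distance between
  consecutive detections". A centroid-based variant would zero out all
  within-installation structure; the choice is isolated in
  `compute_covariates` if a user needs to switch.
- **Quantiles interpolate linearly** between order statistics at
  positions `1 + (n−1)p` (R type 7, numpy default). Quantile dialects
  differ enough to change the 99% value on short tracks, so the
  convention is fixed and tested.
- **Haversine distance** with Earth radius 6371.0 km; adequate because
  the analysis uses distances comparatively, not geodetically.
- **Minimum detections = 2**: the gap and distance covariates are
  undefined below that. Excluded tags are reported with reasons.
- The transform is `sqrt` → centre → scale, column-wise, with the sample
  (n−1) standard deviation. The square root tames the right skew of
  count-like covariates; scaling gives each covariate equal leverage in
  Euclidean space. A zero-variance column after `sqrt` raises an error
  naming the column rather than silently producing NaNs.

## Gap-statistic k-means

k-means uses Lloyd iterations, best of `n_init = 25` seeded restarts
(k-means is sensitive to initialisation on noisy telemetry covariates);
`k = 1` is handled in closed form (total sum of squares about the mean).
The gap statistic compares `log W_k` against `B = 50` reference datasets
drawn **uniformly over each column's observed range** — the simple
reference — clustered under the identical restart policy, over
`k = 1..k_max = 10`. Selection uses the one-standard-error rule
(`s_k = sd_k √(1+1/B)`, population SD over reference sets); if the rule
never fires the largest k is returned with a warning. All of B, k_max,
n_init and the reference are configurable.

Two calibration properties are enforced by tests: a single uniform blob
yields k = 1 in ≥ 90% of seeded runs, and four well-separated
equal-sized Gaussian clusters yield k = 4.

**A caution on class imbalance.** With the uniform-box reference and the
one-standard-error rule, strongly unequal cluster sizes bias the
selection upward: splitting a dominant cluster keeps reducing the data's
`log W_k` faster than the reference's, so the rule tends to fire one or
more steps late (or not at all) even when the clusters are widely
separated. We verified this on idealized data: four isotropic Gaussian
clusters of sizes 60/120/25/45 at n = 250 are typically reported as 5+
clusters, while the same geometry with equal sizes yields 4. On the
default synthetic cohort (which is deliberately imbalanced, as real
multi-species telemetry cohorts are) the gap statistic therefore
over-selects k even though a forced four-class solution recovers the
simulated archetypes almost perfectly (accuracy 0.99). Users applying
the gap statistic to imbalanced cohorts should read the whole gap curve,
not just the selected k.

**Class naming** (k = 4 only) is a deterministic heuristic on cluster
means of the *raw* covariates: Roamers take the largest mean 99% distance
quantile; of the rest, Occasionals the largest mean gap; of the remaining
two, Residents the larger detection count; the last class are Irruptors.
Exact ties abort with a request for manual naming. The heuristic
operationalises a-posteriori descriptions and is overridable.

**PCA** for visualisation is an eigendecomposition of the sample
covariance; percent variance is eigenvalue over trace; the largest-
magnitude loading of each component is made positive so coordinates are
sign-stable. Tests cross-check against an independent SVD route.

**Sensitivity analysis** re-runs the gap statistic after removing 1, 10
and 100 random tags, 20 iterations per removal size (sizes treated
separately), reporting the per-size mean selected k and the full lists.

## SIMPER with Euclidean distance

Squared Euclidean distance decomposes additively over covariates, so the
contribution of covariate v to the dissimilarity of classes A and B is
the mean of `(x_iv − x_jv)²` over all cross pairs, and percent
contributions sum to 100 per comparison. (Euclidean distance itself does
not decompose additively; the squared-term convention is the standard
one for Euclidean SIMPER.) The implementation uses the exact closed form
`E[a²]+E[b²]−2E[a]E[b]` per covariate and is tested against brute-force
pair accumulation at 1e-10. Both all pairwise class comparisons and
one-vs-rest summaries are emitted, because single per-class percentages
are the common reporting style.

Before SIMPER, raw covariates are **dispersion weighted**: each covariate
is divided by the average over classes of its within-class index of
dispersion (sample variance / mean), then `log(x+1)` transformed.
Degenerate indices — zero class mean, zero variance, single-member
classes — contribute 1 (no evidence for reweighting). This simplified
recipe replaces permutation-tested dispersion indices used by some
commercial implementations; with only seven covariates the difference is
immaterial for ranking contributions.

## Relative-movement networks

A movement is a pair of consecutive detections of one tag at two
different installations. Edge weight a→b = count(a→b) / total movements,
pooled over all individuals (the literal reading of relative movement);
a per-individual normalisation (each tag's matrix normalised, then
averaged) is available behind a flag. Subsetting to IMOS or non-IMOS
installations filters detections *first*, so a tag passing through an
excluded installation contributes a "skip" transition between the
surviving detections. Installations with no retained transitions are
dropped. Zero transitions overall is a warning plus an empty network,
not an error — strongly resident classes legitimately produce it.

The 14-metric summary: network level — node count, edge count, density
`E/(n(n−1))`, diameter and average path length (unweighted directed
shortest paths on the largest weakly connected component, reachable
ordered pairs only), number of communities, modularity, reciprocity,
transitivity (on the undirected projection); installation level —
in-degree, out-degree, strength (sum of in+out weights), eigenvector
centrality (leading eigenvector of the symmetrised weighted adjacency,
normalised to max 1 — computed directly by eigendecomposition so it
always converges), betweenness (directed, unweighted). Communities are
greedy modularity maximisation on the symmetrised weighted graph with
nodes inserted in sorted order for determinism; isolated installations
form singletons.

## Synthetic detection simulator

The simulator exists so the full analysis is testable without any real
data access. It emulates a coastal receiver network abstractly: 12
installations placed uniformly along a 2000 km meridian arc, five
receivers each scattered within 1.5 km of the centroid, a third of
installations labelled IMOS. Animals follow four movement archetypes on
a daily loop (relocate with probability `p_move`, destination weighted
`exp(−d/kernel_scale_km)`, optional long-distance excursion kernel and
forced return home), and are detected on occupied days via a Poisson
count with silent days. Within an installation each individual keeps a
fixed activity centre and is heard at receivers with weight
`exp(−d/activity_scale_km)` — site-attached archetypes use a scale far
below receiver spacing (a home range within one receiver's detection
radius), wide-ranging ones approach uniform receiver use. Randomness is
split into per-individual substreams keyed by (seed, index), so datasets
are byte-reproducible and invariant to individual ordering.

Default archetypes (rates per day, scales km; 365-day tracks):

| archetype | p_move | kernel | excursion | rate | silent | activity |
|---|---|---|---|---|---|---|
| RESIDENT | .005 | 10 | — | 12 | .10 | 0.02 |
| OCCASIONAL | .02 | 20 | — | 1.5 | .70 | 0.02 |
| IRRUPTOR | .12 | 10 | p=.3, 300 km, return | 8 | .10 | 0.02 |
| ROAMER | .30 | 400 | — | 4 | .30 | 2.0 |

These values are artefact constructs calibrated to reproduce the
qualitative covariate signatures of the four classes: residents maximal
detections and minimal 99% distance quantile; occasionals maximal mean
gap; roamers maximal 99% quantile and installation count; irruptors
detection counts comparable to residents with the 99% quantile strictly
between residents and roamers. The irruptor parameters matter most: the
99% distance quantile only registers excursions when transit pairs
exceed 1% of a tag's consecutive pairs, which couples the excursion
frequency to the detection rate (hence a moderate rate of 8/day and
~44 relocations/year with forced return home).

Two desk-scale artifacts shaped the detection model and are worth
knowing about. With *uniform* receiver use, a heavily detected tag's
distance quantiles converge to values fixed entirely by its home
installation's discrete receiver geometry — every such tag at the same
installation collapses onto the same point in covariate space, and the
cohort fragments into per-installation atoms that clustering happily
"discovers". With an *intermediate* activity scale, whether a tag's 25th
or 50th percentile hop is exactly zero becomes a near-coin-flip
threshold, splitting archetypes bimodally. The fixed-centre,
small-scale model avoids both: site-attached tags have all lower
quantiles exactly zero (a class property, not an installation property)
and their 99% quantile reflects actual movements.

What the simulator does **not** emulate: tides, diel cycles,
detection-range decay with distance and range testing, tag battery
expiry, receiver outages, species identity, and continuous off-array
space (movement is installation-to-installation; off-array time is
observationally identical to a silent day). Passing tests therefore
demonstrate the correctness and calibration of the *analysis* under a
known four-class generative structure — not that real detection data
contain four classes.

## Pipeline, seeds and problem sizes

The eight-stage pipeline (covariates; gap + k-means; naming + PCA;
SIMPER; three subset networks; subset gap re-evaluation; forced-k subset
clustering with contingency, best-bijective-match accuracy — solved by
the Hungarian algorithm — and silhouettes; per-class networks) derives
one named seed per stage from the master seed in a fixed order, writes
one CSV per artifact and a JSON manifest (config echo, stage seeds,
input hash, versions, timings). Any stage failure aborts with the stage
name; earlier artifacts remain on disk.

Subset covariates are recomputed from the subset's detection stream
rather than re-filtering the Full covariate table, because removing
installations changes which detections are consecutive. A subset whose
covariates degenerate (for example a constant covariate when only one
installation of a type exists) is reported as not clusterable rather
than failing the run.

Problem sizes: the default cohort is 250 tags / ~370k detections
(~2 s to simulate); a gap-statistic run at B = 50, k_max = 10,
n_init = 25 takes ~12 s on one CPU; the full pipeline ~50 s. The test
suite uses a reduced cohort (36 tags, 6 installations) where the full
size adds nothing, and the default cohort where calibration is the
point; null-calibration checks use 250×5 uniform blobs.

## Known limitations

- The gap statistic's upward bias under class imbalance (above) is a
  property of the uniform-box reference and the one-SE rule, both kept
  deliberately as the canonical method; a PCA-aligned reference box
  would be the natural extension.
- The exact metric set and community algorithm used in comparable
  network analyses vary; ours is documented above and swappable.
- Dispersion weighting is the simplified (non-permutation) recipe.
- The naming heuristic assumes the four archetypes are present; unusual
  cohorts may need manual naming.
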