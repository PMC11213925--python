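# Methods notes

This note records the modelling assumptions, parameter choices and numerical
conventions behind the package, in the spirit of a statistical software
vignette. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

All coordinates are 0-based pixels at 0.50 µm/px (≈20× magnification),
origin top-left, x rightward, y downward. Layer masks use the fixed codebook
0 = background, 1 = other/connective tissue, 2 = basal, 3 = epithelial,
4 = keratin; the mask may be stored at a different resolution than the
nuclei, in which case footprints are rescaled with nearest-cell indexing.
The nuclear segmentation model emits three classes only
(basal-epithelial, epithelial, other); "keratin nuclei" and "basal nuclei"
appearing in the explainability analyses are *layer-derived* composition
classes obtained by intersecting epithelial-family nuclei with the mask.

## Tessellation

Tiles are 512 px squares on a 256 px stride (50 % overlap). The last
row/column is snapped inward so tiles never extend past the slide; no
padding is used because all features are geometric and padding would distort
densities. A tile is retained when ≥ 50 % (inclusive) of its footprint is
intra-epithelial; keratin counts as epithelium since it is an
intra-epithelial layer. Nuclei belong to a tile when their centroid falls in
its half-open footprint, so statistics never double-count a nucleus within a
tile while overlapping tiles may share nuclei by design.

## Shape descriptors

The 13 per-nucleus scalars are computed analytically from the contour
polygon: area by exact polygon integrals, perimeter as edge-length sum,
convex area from the convex hull, extent and aspect ratio from the
axis-aligned bounding box, solidity = area / hull area, equivalent diameter
= √(4A/π), radius = mean centroid-to-vertex distance, and
eccentricity / orientation / major / minor axes from the ellipse with the
same normalised second central moments as the polygon region (regionprops
convention: axis length = 4√λ). Orientation is the angle of the major axis
from +x in (−π/2, π/2]; it is intrinsically undefined for circular nuclei.
Lengths are reported in µm and areas in µm² (px × 0.5).

Numerical care: second moments are evaluated in a vertex-mean local frame
and the minor eigenvalue as det/λ₁ rather than (trace − discriminant)/2.
Both choices avoid catastrophic cancellation — naively, a nucleus 500 px
from the origin loses ~9 significant digits in its central moments.

## Spatial features

For each nucleus the number of epithelial and "other" neighbours within
100, 200, 300 and 400 px (50–200 µm) is counted (Euclidean centroid
distance, boundary inclusive, no self-neighbours, confined to the tile).
Tile summaries take mean/min/max/SD over the reference nuclei of each
directed (reference, neighbour) class pair, giving 4 pairs × 4 radii × 4
statistics = 64 features. The first pair in the published four-count list
("epithelial nuclei around another nucleus") is interpreted as the
other→epithelial directed pair so that the four counts form the full
{epithelial, other}² cross; this is an interpretation, not a printed fact.
Basal-epithelial nuclei are merged into the epithelial feature class
throughout, since tile features are defined per "epithelial vs other" type.

Empty classes produce zeros (not NaN) so the network always receives finite
inputs; the standard deviation is the population SD (single nucleus → 0).

## The weakly supervised classifier

The MLP has 168 inputs, one 64-unit hidden layer with leaky ReLU (slope
0.01) and dropout 0.2, and a 2-unit softmax output. It is trained with the
symmetric cross-entropy loss `α·CE + β·RCE` with α = β = 1 and the reverse
term's log 0 clamped at −6 — the referenced loss's common defaults, since
only the loss family is prescribed. The optimiser is Adam at learning rate
1e-3 (the usual Adam default for small dense networks; it converges within
100 epochs at the cohort sizes this package targets, which slower rates do
not), batch size 256, 100 epochs. The network is implemented directly in
NumPy (forward, backward, Adam); at this size that is faster than any
framework overhead and makes bit-level determinism under a single seed
trivial.

IDaRS sampling: per epoch each training slide contributes its k = 5 tiles
with highest current positive probability (ties broken toward the lowest
tile index) plus r = 45 tiles drawn uniformly without replacement from the
remainder. The first epoch draws all 50 at random (no rankings exist yet);
slides with fewer than k + r tiles contribute every tile. Rankings are
refreshed after each epoch with dropout disabled. Features are z-scored per
feature with statistics fitted on the pooled training tiles; constant
features pass through unscaled. All of these fill gaps the published
protocol leaves open and are exposed in `ModelConfig`.

The slide score is the mean positive-class probability over *all* retained
tiles (not only sampled ones). The decision threshold maximises F1 over
candidate midpoints of sorted unique validation scores, with ties broken
toward higher recall and then lower threshold; inside cross-validation the
threshold is selected on the training folds' slide scores.

## Validation protocol

Internal validation is patient-grouped 5-fold cross-validation repeated
with different seeds: patients are shuffled per repeat and dealt round-robin
so fold patient counts differ by ≤ 1, and all slides of a patient share a
fold. Summaries report the mean and SD of each metric across folds ×
repeats, plus pooled confusion counts. External validation trains on the
full discovery cohort (one model per repeat seed), selects τ on discovery
scores, and evaluates once on the disjoint external cohort. Degenerate
metric denominators yield 0 with a `degenerate` flag rather than NaN.

## Survival analysis

Transformations are right-censored at 8 years; zero times after censoring
are clamped to 1e-6 y with a warning. Kaplan–Meier, log-rank, Harrell's C
and the Cox PH model are delegated to `lifelines`; Efron tie handling (the
lifelines default) is used because annual follow-up produces tied event
times. The OMT risk group enters the Cox model as the thresholded binary
prediction; WHO grade is coded ordinally 0/1/2, binary grade 0/1, and site
as an integer category entered linearly — single-HR-per-variable reporting
implies scalar coding.

## Explainability

Group comparisons use Welch's two-tailed t-test (unequal variances are
expected between TP and TN patch populations), Benjamini–Hochberg FDR across
the tested family, and Cohen's *d* with pooled SD. The Random Forest uses
500 trees, default depth and a fixed seed; MDI importances are normalised to
sum to 1. Partial dependence sweeps one feature over 100 equally spaced
values from its observed min to max, overwriting it in every evaluation tile
and averaging the model probability; a constant feature yields a single
point. Heatmaps average the probabilities of all tiles covering each pixel;
uncovered pixels are NaN.

## Synthetic cohort

The generator emulates the geometry and statistics the pipeline assumes:
horizontal tissue bands (80 px background margin, 80 px keratin, 440 px
epithelium, 60 px basal, connective below) with sinusoidal boundary
undulation (amplitude 40 px, period 512 px) on 1280 × 1280 px slides;
homogeneous Poisson nuclei per (class, region) — epithelial 2500/mm² in the
epithelial band, basal-epithelial 4000/mm² in the basal band, "other"
800/mm² in connective tissue and 120/mm² intra-epithelially — rendered as
32-vertex ellipses with class-specific mean radii (3.5 / 2.8 / 2.2 µm) and
lognormal axis ratios. These are plausible oral-mucosa magnitudes chosen
once as the package's study conditions.

Transforming slides (prevalence 0.5) receive the planted signal the
published analyses found discriminative: "other"-nucleus intensities × 4 in
both compartments (peri-/intra-epithelial lymphocyte excess) and
epithelial-family nuclear size × 1.25. Transforming slides draw exponential
event times (baseline 0.05/yr × hazard ratio 8) truncated to the 10-year
follow-up; non-transforming slides draw uniform censoring times. Because the
cohort schema stores a single `transformed` field serving as both the
classification label and the survival event indicator, a textbook
proportional-hazards simulator (`simulate_survival`: Bernoulli covariate,
exponential baseline, administrative censoring) is provided separately for
hazard-ratio recovery checks.

What the generator does **not** emulate: stain/scanner variation, nuclear
clustering and crowding (points are Poisson, nuclei may overlap), irregular
lesion geometry, segmentation errors, or label noise. Passing tests
therefore demonstrate correctness of the pipeline's computations and its
ability to recover a strong planted signal under clean segmentations — not
clinical performance on real WSIs, whose underlying cohorts are not
redistributable.

## Problem sizes in the packaged experiments

The test-suite and acceptance-script experiments use 60-slide cohorts of
1280 × 1280 px slides (~16 tiles, ~600–1500 nuclei per slide), single-repeat
5-fold CV, n = 500 survival simulations and ≥100-instance oracle sweeps —
sizes at which every experiment is exact or tightly concentrated while the
whole suite runs in well under a minute per stage. With the strong default
effect the cross-validated AUROC saturates at 1.0; the permuted-label
control stays near 0.5, confirming the signal is carried by the features
rather than the protocol.

## Known limitations

- Neighbourhood counts are confined to each tile, so spatial features have
  symmetric edge effects; cross-tile neighbourhoods are not computed.
- The MLP trains full-batch-per-epoch at desk scale; very large cohorts
  would warrant minibatch streaming and a framework backend.
- Site enters the Cox model linearly; with many sites a categorical
  encoding may be preferable.
- The synthetic generator's Poisson placement permits overlapping nuclei;
  morphology statistics are unaffected but packing realism is limited.
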