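# Methods

This note documents the models, procedures, defaults and design choices
behind `treerisk`, and what the synthetic test bed does and does not show
about behavior on real data.

## Problem setting and assumptions

The pipeline approximates IUCN Red List categories for tree species from
georeferenced occurrence records alone. The working assumption is the one
underlying the Red List's own criteria: threat status correlates with
geographic range size, occurrence density and exposure to human pressure.
No trait, phylogeny or population-trend data enter the model; species
whose status is driven by factors invisible in occurrence data (e.g.
widely cultivated but wild-rare species) will be systematically
misclassified, and that limitation is inherent to the approach.

## Occurrence cleaning

Raw aggregated occurrence data carry characteristic errors. The cleaning
cascade applies, in order: basis-of-record filter (human observations,
preserved specimens, literature records kept), coordinate-uncertainty
filter, exact-duplicate removal, suspicious-coordinate tests, and a
per-species spatial-outlier test. Choices worth noting:

- **Coordinate uncertainty** uses a strict `< 100 km` rule. Records with
  *missing* uncertainty are kept by default: aggregator records very
  commonly omit the field, and dropping them would discard most
  observation data. A strict mode (`drop_missing_uncertainty=True`)
  exists for sensitivity analysis. The count of kept-but-missing records
  is reported.
- **Duplicate key**: (species, lon, lat) rounded to 6 decimal places
  (~0.1 m), so only true duplicates collide; the first record in input
  order is kept.
- **Suspicious coordinates**: the 0/0 test uses ε = 1e-5 degrees; the
  lat = lon test compares at the duplicate precision; sea points are
  tested against the land/sea mask; capitals, country centroids and
  biodiversity institutions are unified as a gazetteer of points with
  per-type exclusion radii (defaults: capitals 10 km, centroids 1 km,
  institutions 100 m). Each flagged record carries the first matching
  reason in that priority order.
- **Spatial outliers**: a record is an outlier if its minimum
  great-circle distance to any other conspecific record exceeds
  Q3 + 5 × IQR of those minimum distances; species with fewer than 7
  records are not tested. These defaults mirror common practice in
  occurrence-cleaning tools. The rule is a statistical test and has a
  small false-positive rate on genuinely clumped clean data (empirically
  ~0.2% of records on the default synthetic conditions); removal is
  single-pass, not iterated to a fixpoint, so repeated cleaning is stable
  for every step except (possibly) this one.

The `QcReport` reconciles exactly: input − Σ per-step removals = output.
A hash of the cleaning configuration is logged with every report because
the cascade is order-sensitive.

## Features

- **EOO** is the convex-hull area of the species' cleaned records,
  computed in a per-species cylindrical equal-area projection with the
  standard parallel at the records' mean latitude. The projection is
  exactly area-preserving on the sphere, so the planar hull area equals
  the spherical area of the hull region; the test suite checks this
  against an independent geodesic (solid-angle) computation to < 1%.
  Hulls with fewer than 3 unique points or collinear points are
  undefined; such species are dropped (with reasons) unless the optional
  EOO→AOO fallback is enabled — it is off by default, so the default
  behavior is to omit species with incomplete features.
- **AOO** counts occupied 2 × 2 km cells (the IUCN standard cell) of a
  grid *centered* on the projection origin. AOO is origin-sensitive at
  the ±1 cell level by nature; fixing the origin to the points' centroid
  makes it deterministic and keeps a tight cluster in one cell.
- **Climate** summaries are the mean and population SD of each provided
  layer sampled at the nearest raster cell of each record.
- **Human footprint** exposure is the fraction of records in four
  pressure classes with bin edges (0, 1, 10, 20, ∞), the conventional
  four-category split of footprint indices.
- **Normalization**: log10(x+1) on occurrence count, EOO and AOO, then
  per-column z-scoring using statistics from training rows only (each CV
  fold re-fits them); binary columns pass through; zero-variance columns
  are centered and left unscaled.

## Model

Both heads share a fully connected ReLU network (hidden sizes 100, 60,
20) with dropout 0.1 on the hidden activations:

- *Classifier*: softmax output, cross-entropy loss; argmax prediction
  with ties broken toward the less-threatened class (deterministic and
  conservative).
- *Regression*: one linear output trained by squared error against the
  ordinal class index; prediction rounds half-up and clips to the valid
  class range.

The network is intentionally implemented in plain numpy: at this problem
scale (thousands of species, a few dozen features) it trains in seconds,
and every arithmetic step is seedable and inspectable.

Optimization uses Adam (learning rate 1e-3, batch size 64), at most 1000
epochs, early stopping when the validation loss has not improved for 100
epochs, restoring the best-epoch parameters. The long patience matters
for the regression head: its validation loss exhibits extended plateaus
before the output scale finishes converging, and an aggressive stopping
rule leaves predictions shrunk toward the class mean (dropout acts as
multiplicative noise, which biases an under-trained squared-error fit
toward zero). Cross-validation is stratified fivefold; within each fold
the held-out 20% doubles as the early-stopping validation set, i.e. the
80/20 usage described for this kind of pipeline. This conflation slightly
optimistically biases the accuracy estimate; an inner split could remove
it but is not used by default, for fidelity to the procedure being
reproduced.

No class weighting or resampling is applied: class imbalance is handled
by the binary grouping (possibly threatened = VU ∪ EN ∪ CR), which is the
scheme of record for downstream summaries.

## MC-dropout uncertainty and threshold calibration

Prediction-time dropout (100 replicates by default) yields a predictive
distribution per species. Confidence is the mean softmax probability of
the predicted class (classifier) or the fraction of replicates agreeing
with the modal rounded class (regression) — the natural reading of "MC
dropout probability" for each head.

`find_threshold` scans the sorted unique confidences ascending and
returns the smallest t\* whose retained set (confidence ≥ t\*, ties
retained) reaches the target accuracy; if the overall accuracy already
meets the target, t\* is the minimum confidence and nothing is
unclassified; if even the most confident subset fails, the result is
flagged unattainable. Calibration uses pooled out-of-fold MC predictions
from cross-validation (each fold's model predicts its own held-out rows),
then the threshold is applied to unlabeled species. The retained-set
accuracy guarantee holds by construction on the calibration set and is
checked as a soft property on held-out generator data.

## Reporting conventions

- Official Red List labels always override predictions; DD species count
  as unlabeled and receive predictions when features exist; species with
  neither label nor features are "not evaluated".
- Percentage denominators are per column: RL percentages over all
  RL-labeled species, prediction percentages over all predicted species,
  merged percentages over all assessed species; not-evaluated species are
  reported without a percentage. Reported percentages round to one
  decimal, half away from zero.
- Family rankings come in two forms: by threatened count, and by
  threatened proportion restricted to families with more than 10 assessed
  species (tiny families trivially reach 100%). Ties break on group name.
- A species counts in every country and biome where it has at least one
  cleaned record, so per-group species counts may exceed the species
  total by design.
- Per-country prediction accuracy is the fraction of labeled species
  occurring in the country whose pooled cross-validation prediction was
  correct.
- Bias diagnostics summarize the distribution of assessed fractions
  across genera/families/orders/countries/biomes (quantiles and a 95%
  range) plus the Spearman correlation between group size and assessed
  fraction; systematic assessment bias would appear as bimodality or a
  strong size correlation.

## Synthetic test bed

The generator fabricates a toy world — biomes as latitudinal bands and
countries as longitudinal strips exactly partitioning a
60°W–60°E × 56°S–60°N extent at 1° resolution, a smooth-field land/sea
mask (70% land), a footprint raster spanning the four pressure bins, a
temperature raster with a 0.45 °C/degree-latitude lapse, and a gazetteer
on land-cell centers — and species whose threat class drives their
spatial structure:

- class mix defaults to the five-class composition of tree species on
  the Red List (53.6/6.4/15.9/15.9/8.2% for LC/NT/VU/EN/CR);
- range radius is log-normal with class medians 500/200/80/30/10 km
  (LC→CR) and shared σ = 0.5 on the natural-log scale — overlapping but
  separable distributions, so the classifier is accurate but imperfect;
- record count is log-normal with class medians 120/80/50/30/15 and
  σ = 0.6, floored at 2;
- occurrences are isotropic Gaussian on the local tangent plane (SD =
  radius/2) truncated at the range radius, rejected off land and out of
  gazetteer zones.

Contamination injects each error class at configurable per-record rates
(defaults total ~20% of records). Injected errors are constructed to be
unambiguous for the deterministic cleaning steps (e.g. 0/0 points are
jittered within ε but kept unique at the duplicate precision), so the
per-step removal counts reconcile exactly against the hidden sidecar for
disallowed basis, inflated uncertainty, duplicates, 0/0 and lat = lon.
Sea points, gazetteer hits and especially injected spatial outliers can
interact with the statistical outlier rule, so only aggregate behavior
is asserted for those.

What passing tests on this bed shows: the bookkeeping, geometry,
training, calibration and reporting machinery are correct, and the
pipeline recovers a planted range-size signal at realistic class
imbalance. What it does not show: performance on real occurrence data,
whose sampling biases, spatial autocorrelation, taxonomic error and
non-range-driven threat mechanisms the generator deliberately does not
simulate. Cross-validated accuracies on the synthetic defaults (~96%
binary, ~83% five-class at n = 1000) are therefore upper bounds tied to
the planted signal strength, not forecasts for real assessments — on
real data this family of methods reports substantially lower accuracy.
The qualitative orderings, however, reproduce the expected pattern:
binary beats five-class, the classifier matches or beats the regression
head, and five-class confusion concentrates in adjacent classes.

## Numerical and degenerate-input conventions

- Distances are great-circle on a sphere of authalic radius 6371.0088 km;
  at EOO/AOO scales the spherical approximation is well below the 1%
  test tolerance.
- A standard parallel at a pole degenerates the projection; it falls back
  to the equator.
- Softmax is computed with max-subtraction; probabilities sum to 1 within
  1e-9.
- Empty validation sets, non-finite losses, unknown Red List categories,
  predictions outside the species universe, and invalid generator
  configurations raise immediately with informative messages rather than
  propagating NaNs.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  generator output, fold assignments, trained parameters and MC
  predictions.

## Problem sizes

Default test and acceptance runs use n = 1000 species (~100k occurrence
records) for the model-grid comparison, 300–500 species for repeated-seed
stability checks, and 50–1000 random instances for oracle-equivalence
checks — sizes at which every stage completes in seconds on one CPU while
leaving the planted signal clearly detectable.
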