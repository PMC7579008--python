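# Methods

This note documents the models, conventions and numerical choices behind
`ashazard`, and what the synthetic validation does and does not demonstrate.

## Grids and rasters

All rasters live on one geographic grid: lower-left origin, square cells in
degrees (default 1/120° = 30 arc-seconds, ~1 km at the equator — no
reprojection; "% of land area" uses plain cell counts, acceptable over the
latitude span of a single study region, with the equal-area error growing
toward high latitudes). Cell membership is half-open:
`col = floor((lon − lon0)/cell)`, with points on the outer max boundary
assigned to the last cell, so the closed extent is fully covered and every
point falls in exactly one cell. In memory row 0 is the southern row and
nodata is NaN; on disk rasters are ESRI ASCII grids (north-up, explicit
`NODATA_value`). Nodata always propagates — a cell missing any predictor is
nodata in the probability map and contributes nothing to exposure sums.

## Data preparation

Aggregation averages all concentrations inside a cell (arithmetic mean) and
places the representative point at the cell center; any in-cell location
would retrieve identical predictor values at matching resolution.
Aggregation is idempotent and order-invariant (rows are canonically ordered
by cell index). Recoding to the binary exceedance label happens strictly
*after* averaging: a cell holding {0, 30} µg/L has mean 15 and label 1.
Exactly 10 µg/L recodes to 0 — the guideline value itself is acceptable.
Points outside the grid and rows hitting nodata in any predictor are
dropped with logged counts; zero surviving rows is an error, never an empty
model.

## The random forest

The classifier is scikit-learn's `RandomForestClassifier` behind the
package's own schema-checked surface. Defaults follow the standard workflow
for this problem: stratified 80/20 split (per-class rounding, so each part's
class-1 share is within one row of the overall share), 10,001 trees, and
`mtry` tuned by out-of-bag accuracy over candidates between 1 and the
number of encoded predictors, ties resolved to the smallest value
(parsimony). Tuning runs may use a reduced tree count (default 501; the
pipeline exposes it) because tuning needs a stable *ranking*, not the final
fit's precision. Categorical predictors are one-hot encoded with levels
frozen at fit time; an unseen category at prediction time encodes as all
zeros rather than an error. `mtry` therefore counts encoded (dummy)
columns, not raw variables. The predicted probability is the fraction of
trees voting for exceedance, which makes the cutoff grid directly
interpretable. No class weighting is applied. The OOB accuracy reported is
that of the final fit.

## Evaluation statistics

All 2×2 statistics are computed from first principles with exceedance
(label 1) as the positive class: sensitivity = n11 / (reference-1
marginal), specificity = n00 / (reference-0 marginal), PPV/NPV on the
prediction marginals, prevalence = reference-1 share, balanced accuracy =
mean(sensitivity, specificity), Cohen's κ = (p_o − p_e)/(1 − p_e) with
p_e from the row×column marginals, and the accuracy-vs-NIR p-value as a
one-sided *exact* binomial tail (no normal approximation). A statistic with
an empty denominator is reported as `None`, never as a silent NaN or 0.
AUC is pairwise concordance with ties counted ½, computed via the rank-sum
identity — equivalent to trapezoidal ROC integration and invariant under
strictly monotone transforms of the scores.

Cutoff selection evaluates both curves of the chosen criterion at 100
evenly spaced probabilities spanning [0, 1] *inclusive*, classifies with
`probability > c`, and returns the grid point minimizing |curveA − curveB|
— a nearest-grid minimizer rather than an interpolated root, reproducible
and faithful to a 100-point curve. The two grid endpoints are excluded from
selection (they classify everything into one class); among ties the lowest
probability wins. Following the source workflow, the pipeline applies
cutoff selection to the predictions on the *full* dataset (train + test).
Note the accuracy reported at these cutoffs is computed on data the forest
has partly memorized and is therefore optimistic relative to the held-out
confusion matrix; the package reproduces the computation as defined and
reports both numbers.

## Variable diagnostics

Permutation importance shuffles each *raw* predictor column in turn
(categoricals as whole columns, before encoding), recomputes accuracy at
the 0.5 cutoff, and reports baseline minus the mean over repeats. It is
evaluated on the held-out test set by default; the evaluation set is a
parameter. Gini importance sums the forest's recorded impurity decreases
over the one-hot columns of each raw variable. Max-normalization divides
each measure by its own maximum (which must be positive; the pipeline falls
back to raw values otherwise) so the top variable scores exactly 1 and
negative importances keep their sign.

The binned correlation diagnostic sorts a predictor (stable sort; ties may
straddle bin boundaries — equal counts take priority over tie integrity),
splits it into equal-count bins (sizes differ by at most one, remainder in
the first bins; default bin count from Sturges' rule ⌈1 + log₂ n⌉), and
computes Kendall τ_b (tie-corrected) between per-bin predictor means and
per-bin exceedance proportions, with a two-sided p-value and a significance
flag at the 95% level. Pearson's r over the same summaries is reported
alongside, since both conventions are in circulation for this diagnostic;
τ_b is the headline number. Two consequences of the tie correction are
worth knowing: a hard-threshold relationship (proportions jumping 0 → 1)
yields τ_b ≈ 0.73, not 1, because tied proportions are corrected for; and
with ~15 binned summaries the exact permutation null is discrete, making
the 5% significance flag mildly conservative (empirical type-I error ≈
3–5%). A constant predictor has no defined correlation and is flagged
(`defined=False`) rather than reported as 0.

## Exposure

Hazard cell: probability strictly greater than the cutoff. Per-cell
exposure: probability × population × use rate (0.637 rural / 0.238 urban —
nationwide household rates for untreated groundwater), summed over hazard
cells only; populations in cells below the cutoff contribute nothing, which
biases the total downward wherever contamination is localized. The product
order is irrelevant (scalars), so it is implemented as a single per-cell
product. Regional summaries assign each cell to the region polygon
containing its center (no area-fraction splitting); per-region exposures
are additive and sum to the national total when the polygons partition the
extent. Ranges across the two cutoffs are ordered low–high; monotonicity
of the hazard set in the cutoff guarantees the low figure comes from the
higher cutoff.

## The synthetic study region

Continuous predictor fields are Gaussian-filtered white noise (filter scale
= the configured correlation length in cells; reflect boundary),
standardized to mean 0, sd 1 — chosen over spectral synthesis for
simplicity and an obvious single parameter; tests constrain only the
measured lag-1 autocorrelation, not the method. Categorical layers take the
argmax of several independently smoothed fields, producing contiguous
patches; the population surface is exp(1.5 × smoothed noise) scaled to a
median of ~200 people per cell, giving a heavy right tail; the urban mask
is the top population decile, mirroring a rural/urban split without
external data; regions are a rectangular tiling of the extent.

The exceedance mechanism is logistic: intercept + linear terms on named
fields + Gaussian-bump "peaked" terms (center, width, amplitude) for
non-monotone effects. Each sampled point's indicator is Bernoulli at its
cell's probability, and its concentration is lognormal around the 10 µg/L
guideline on the side selected by the indicator — heavy-tailed like real
concentration data, and never in conflict with the label. Sampling
clustering uses a symmetric Dirichlet over cells with concentration
1/(1 + clustering_factor), plus a configurable fraction of points confined
to a small hotspot sub-region.

The frozen full-size scenario uses a 240×240 grid, 18 continuous + 2
categorical predictors (20 raw variables), five linear effects (|b| from
0.6 to 1.6) and two peaked effects, with 60,000 points at clustering factor
2 and a 35% hotspot share. The intercept (−1.95) is calibrated so the
*aggregated* exceedance fraction is ≈ 0.42: cell-mean averaging pulls the
fraction above the raw Bernoulli rate because arithmetic means are
dominated by the high-concentration side. This yields ~18,800 occupied
cells, held-out AUC ≈ 0.9, OOB accuracy ≈ 0.82, and cutoffs near 0.43/0.54
with full-data accuracy ≈ 96% — the same qualitative regime as real
national-scale arsenic models.

What the synthetic validation shows: the pipeline's statistics are computed
correctly, the diagnostics recover the direction and ranking of known
effects, and the exposure arithmetic is exact. What it does not show:
performance on real data, where predictors are cross-correlated, the
mechanism is not logistic in the measured covariates, measurement error and
field-kit/lab mixing add label noise, and sampling is biased toward known
problem areas in ways a hotspot fraction only caricatures.

## Problem sizes and determinism

Default tree counts for the synthetic scenario runs are reduced (tuning
101–501 trees, final 401) — the probability estimates stabilize well below
the canonical 10,001, which remains the `ForestSpec` default for real-scale
use. One master seed deterministically derives per-stage seeds via a
4-byte BLAKE2 hash of `"<seed>:<stage>"` (kept below 2³¹), so a rerun with
the same configuration reproduces every artifact checksum exactly.

## Known limitations

Depth and time of sampling are not modeled (surface predictors only);
sub-national groundwater-use rates are not supported; cell areas are not
cosine-weighted by latitude (an option exists but is off by default);
region assignment is by cell center only. The two-cutoff range is a
sensitivity band, not a confidence interval — no uncertainty is propagated
from the forest to the exposure totals.
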