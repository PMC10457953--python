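# Methods

## Scope and model

`tomatoq` evaluates fruit quality across a panel of tomato varieties
organised in groups (by default regular, tasty and cherry types). The
pipeline has five analytical stages; each is a pure function of its
input tables, so every reported number is traceable to one operation.

### Physical indices

Moisture content is `(W1 − W2)/W1 × 100` from the fresh (W1) and
oven-dry (W2) mass of the same aliquot; it is undefined for `W1 ≤ 0` or
`W2 > W1` and those inputs raise. The fruit shape index is the ratio of
longitudinal to transverse diameter; when a caliper re-measurement in
the perpendicular direction is supplied, the repeated readings are
averaged before the ratio is taken. The surface colour index is
`2000·a* / (L*·√(a*² + b*²))` from CIELAB readings — positive for red
fruit, negative for green, undefined at zero chroma. Replicates are
summarised as mean ± SE with the sample (n−1) standard deviation;
SE is 0 for a single replicate.

### Internal-standard quantification

Concentrations come from the peak-area ratio against a spiked internal
standard: `c = (A1/A2)·(M1/M2)·1000`. The unit contract is fixed: M1 in
µg (for the default 2-octanol protocol, 10 µL of an 8.82 mg·L⁻¹ stock =
0.0882 µg), M2 in g (default 8.0 g homogenate), so the ×1000 converts
per-gram to per-kilogram and c is in µg·kg⁻¹. Identification quality is
enforced by a spectral match-score filter, strict `> 80%` by default
(configurable); duplicate compound rows within one run are treated as a
co-eluting peak split and summed with a logged warning. Replicate runs
of a variety are averaged before OAV scoring.

### OAV profiling

`OAV = c / threshold` with compound-specific odor thresholds in
µg·kg⁻¹; compounds without a threshold are skipped with a warning
rather than silently given one. Characteristic compounds are those with
OAV strictly `> 1` in at least one variety (strict comparison, so a
printed OAV of exactly 1.00 does not qualify; rounding of published
OAVs can flip such boundary cases, which the tests cover). A group's
shared set is the intersection of its varieties' characteristic sets;
an OAV of 0 means "not detected" and never qualifies.

Descriptors are free text ("Citrus, floral, sweet"). A descriptor map
folds each token onto the 13 canonical aroma types; the shipped map
covers the reference panel (citrus/banana/melon/citral → fruity,
rose → floral, mushroom → mushroom-like, plus spelling variants) and is
an editable CSV. The map is implemented as descriptor → *set* of types
so that a fused token carrying two types ("fruity sweet") resolves
without editing the source table; any unmapped descriptor raises,
naming itself. Aroma-type profiles credit a compound's full group-level
OAV to every type it maps to (the multi-type duplication rule) and sum
over compounds per type. Group aggregation uses the **mean** OAV across
the group's varieties by default so groups of unequal size stay
comparable; `agg="sum"` is available.

### Composite quality scoring

Each indicator is min–max normalised over the panel,
`u = (x − min)/(max − min)`, inverted (`1 − u`) for indicators where
smaller is better. The per-variety composite score is the mean of its
memberships; varieties are ranked by descending score with ties broken
by input order (stable). Which indicators are smaller-is-better is
driven by a direction-config CSV; the shipped default marks moisture,
both firmness measures and oxalic acid negative (moisture and firmness
correlate negatively with flavor in such panels; oxalic acid is an
anti-nutritional factor) and treats everything else as positive. A
degenerate indicator (max = min) carries no discriminating information:
it is excluded from the average with a logged warning and the divisor n
adjusts; scoring fails only if every indicator is degenerate.

### Correlation, PCA, ellipses

Pearson r uses the product-moment formula; two-sided p-values come from
`t = r·√((n−2)/(1−r²))` on n−2 df, with stars at p < 0.05 (\*) and
p < 0.01 (\*\*). Constant columns make r undefined for their pairs —
those entries are NaN and the columns are reported, not dropped. PCA
standardises columns to zero mean and unit (population) variance and
decomposes by singular values; explained fractions are
eigenvalue/total. Each component is flipped so its largest-magnitude
loading is positive, making outputs reproducible across BLAS builds; a
zero-variance column raises, naming the indicator (the pipeline
pre-filters such columns with a warning before its 2-component run).
The 95% confidence ellipse of a group's PC1–PC2 cloud uses the sample
covariance scaled by the χ²(2) 95% quantile (≈5.991); under a bivariate
normal, coverage approaches 95% as n grows.

The pipeline's indicator matrix combines per-variety means of the
physical indices, colour index, composition assays, sensory scores and
the characteristic volatiles' concentrations — mirroring how
multi-indicator quality panels are assembled in this field.

## Synthetic studies

The generator emulates the study design the analysis assumes: 3 groups
× 5 varieties × 3 replicates and ~110 volatile compounds by default.
Group effects are multiplicative on trait-family baselines; the default
multipliers reproduce the group contrasts characteristic of such panels
— tasty highest in soluble solids (~60% above regular), sugars,
vitamin C, lycopene, total volatiles and flavor score; regular highest
in moisture (~3%), firmness and oxalic acid (~55%); cherry intermediate
with the smallest fruit. Variety means scatter multiplicatively around
their group mean (`variety_cv`, default 0.08) and replicates add
truncated multiplicative Gaussian noise (`noise_cv`, default 0.05, mean
1, floored at 0). Within-variety variances are free parameters of the
generator, not calibrated to any instrument.

Volatile ground truth is constructed per variety: compound abundance
weights are lognormal, rescaled so aldehydes + alcohols carry a fixed
share (default 0.6) of the total; per-group detection probabilities
(defaults 0.50/0.63/0.54 for regular/tasty/cherry) thin the compound
list per variety so detected-compound counts vary realistically, and
weights renormalise over the detected set so variety totals keep their
configured group ordering. Peak areas invert the quantification
formula, so at `noise_cv = 0` quantification recovers the configured
concentrations to machine precision — the round-trip the tests assert.
Sensory scores are clamped to the 1–5 scale. Dry weight is derived from
the drawn moisture, so the moisture round-trip is exact by
construction. Each run also carries two low-confidence "artifact" peaks
that the match-score filter must remove.

What the generator does **not** emulate: chromatograms or mass spectra
(only peak-area tables), between-replicate correlation structure,
instrument drift or batch effects, and any real covariance between
traits beyond their shared group effect. Passing tests therefore
demonstrate the pipeline's arithmetic, invariances and ordering
recovery under the configured effects — not performance on real
instrument data.

## Packaged reference panel

Four CSV fixtures carry the printed tables of a published 15-variety
panel verbatim (including 0.00 OAV entries meaning "not detected"):
physical traits, the 34-compound OAV matrix with thresholds and
descriptors, sensory scores, and membership scores with ranks. Strict
recomputation from the rounded OAV matrix yields 11 compounds shared by
all regular varieties and 21 by all tasty varieties — slightly more
than the counts quoted alongside the original table, which derive from
pre-rounding values — so fixture tests assert supersets, and the
regular-group membership mean recomputes to 0.132 against a printed
0.12; only the tasty (0.42) and cherry (0.23) means are used as exact
checks.

## Problem sizes and numerical choices

The test suite and the acceptance script run the reference panel
(instant) plus synthetic studies at 12–30 compounds and 2 replicates
for the 100-draw ordering check, one full-size default study for the
PCA separation check, and n = 10,000 points for ellipse coverage —
sizes chosen so the whole suite completes in well under a minute while
keeping Monte-Carlo standard errors far below the asserted margins.
Round-trip assertions use relative 1e-12 (floating-point arithmetic
only), orthonormality/reconstruction 1e-10, ellipse coverage ±2
percentage points at n = 10,000 (binomial SE ≈ 0.2 points).

## Known limitations

- Descriptor normalisation is exact-match on lowercased tokens; no
  fuzzy matching of novel descriptor vocabularies.
- The composite score weights all indicators equally; no
  importance weighting or entropy weighting is provided.
- Duncan's multiple range test lettering is out of scope; group
  contrasts are reported as percent differences plus the
  correlation/PCA machinery.
- p-values assume bivariate normality via the t transform; no
  permutation alternative.
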