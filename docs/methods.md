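# Methods

## Uncertainty model

All quantities are modelled as lognormal.  An estimate is a pair
`(value, ferror)` with `value` the median and `s = ln(ferror)` the shape
parameter; `ferror = 1` marks an exact quantity.  An exact zero
(`value = 0, ferror = 1`) is a first-class sentinel, needed for cell types
absent from a tissue; a strictly positive domain would make such entries
unrepresentable.

**Fitting.** Measurements reported as mean ± SE are converted by moment
matching: the fitted lognormal reproduces the normal's mean and variance
exactly (`s² = ln(1 + CV²)`), and the reported point value is the fitted
*median* `mean·e^{−s²/2}`.  Moment matching is closed-form and
parameter-free; a maximum-likelihood fit would need the raw data, which
literature values do not provide.  Fits with CV > 3 are rejected as
ill-posed — a normal that wide is bimodal-in-log territory and no
lognormal approximates it usefully.

**Products** propagate by root-sum-of-squares of shape parameters; this is
exact, not an approximation, for lognormals.

**Sums** have no closed form, so totals are propagated by parametric
bootstrap (default 1,000 draws, seed fixed in the configuration, default
2023).  The point value of a sum is the sum of member point values
(medians), with the 2.5/50/97.5 percentiles of the draws as the interval.
Members of a correlation group — pairs filled from the same extrapolation
evidence — share one standard-normal deviate per draw, i.e. are treated as
perfectly correlated.  That is the conservative choice: it maximises the
variance contribution of extrapolated blocks.  Deviates are assigned one
per correlation unit in order of first appearance, which makes a
fully-correlated group bit-identical to the equivalent single scaled
estimate under the same seed — a property the tests assert exactly.

**Combination** across methods is fixed-effect inverse-variance weighting
in log space, `w_i = m_i/ln²(f_i)` with optional multipliers `m_i`.  An
exact estimate carries infinite weight; two disagreeing exact estimates
raise an error rather than average.  The multiplier for multiplexed
imaging defaults to 1 (pure inverse-variance): the method's extra weight
in lymphoid organs emerges naturally from its smaller error factors, and
the multiplier is exposed only for sensitivity analysis.

**Analytic intervals** use z = 1.96 on the log scale
(`value·f^±1.96`); one sigma is `value/f` to `value·f`.

## From evidence to densities

All lengths are handled in centimetres internally; readers convert μm
columns.  The stereological (Abercrombie-type) correction
`ρ = n/(A·(T+D))` converts section counts to volumetric density,
compensating for cells cut by the section faces; multiplexed-imaging
planes use the `T = 0` limit.  Volumetric densities become cells/gram by
*division* by specific gravity (1.03 g/mL; 0.91 adipose): dimensional
analysis requires division even where source texts loosely say
"multiplying by a reference-specific density"; the discrepancy is ≤3% and
the choice is recorded here rather than silently absorbed.

Evidence tables carry one row per record with a declared `value_kind`
(`per_gram`, `per_cm3`, `areal_count`, `fraction`, `total_count`).  The
single uncertainty column `ferror_or_se` is disambiguated by an optional
`error_kind` column (`ferror`, the default, or `se`); `se` rows are
moment-matched, so their point value becomes the fitted median.  Fraction
rows need a reference nucleated-cell density (`ref_value`/`ref_ferror`
columns).  Unit conversions are linear, so uncertainty is resolved on the
stated scale and the whole estimate rescaled.

Non-human records are retained, flagged, and widened by a ×1.5 error
penalty (configurable) rather than excluded: rodent and monkey densities
are informative but less certain for humans.  Repeated records per
(tissue, cell type, method) merge by geometric mean with
`s² = mean(s_i²)/n + var(ln v)/n` — the declared per-record error shrunk
as an average, plus the between-record spread as the standard error of the
geometric mean.

Compartment-resolved records (e.g. epithelium vs rest) are folded into
whole-tissue densities by mass-fraction-weighted arithmetic mean, with
uncertainty from a bootstrap over the parts; compartments without evidence
contribute zero density.

## Multiplexed imaging

Samples are screened once per tissue stratum: total cell counts are
z-scored against the stratum mean and *population* SD (ddof = 0), and
samples with |z| > 1.96 are removed.  Strata with fewer than three samples
pass through with a warning.  Note the screen's resolution limit: the
maximum attainable population z in a stratum of n samples is √(n−1), so a
five-sample stratum can only just reach 2.0.

Aggregation is hierarchical: geometric mean over a patient's
positive-count fields, then over patients; zero-count fields are excluded
(no pseudo-count floor, which would bias rare types upward) and their
fraction is reported.  The combined log-variance is
`s² = s²_between/k + mean(within)/n̄`.  Because k is typically ~3
patients, the plug-in SE is itself noisy and a ±1.96 interval undercovers
(measured ~88% instead of 95% on synthetic data); the reported shape
parameter is therefore calibrated by a Satterthwaite-style t correction,
`s ← s · t_{0.975,df}/1.96` with df pooled across the two variance
components, making the generic ±1.96 log interval a proper t interval
(measured coverage 94%).  A tissue with a single field from a single
patient gets a default twofold error factor: no replication can constrain
variation.

Per-type cell diameters for the `T = 0` correction default to 7.5 μm for
lymphocytes, 10–12 μm for granulocytes and monocytes, and 17 μm for
macrophages and dendritic cells, overridable per sample.

## Deconvolution (validation only)

Relative fractions become absolute counts through an anchor cell type:
`N_im = P_im·N_an/P_an`, with the anchor's error factor propagated and
fractions treated as exact unless an SE is supplied.  Samples are grouped
by declared tissue label (no unsupervised clustering — the criterion is
not identifiable from fraction tables alone) and combined by geometric
mean, with between-sample log-SE pooled with the anchor error.  The
comparison table reports per-(tissue, group) log10 ratios and an agreement
flag at the combined 95% interval.  Deconvolution-derived counts never
enter the census; the tests assert bit-identical census output with and
without fraction tables present.

## Extrapolation

Pairs without human evidence are filled by the geometric mean of two
routes where available: cross-species (non-human records for the same
pair, error-penalized) and within-group (human densities of the tissue's
similarity group, error from between-tissue spread, floored at ferror
1.5 so extrapolated values are always down-weighted).  Routes disagreeing
by more than a factor of two are flagged.  Filled pairs are marked
`extrapolated`, share a correlation group keyed by their evidence route
and cell type, and are listed in an audit table.  Tissue-restricted types
are never extrapolated: eosinophils outside the GI tract and
lymphoid/marrow organs, mast cells outside connective tissue, barrier
epithelia and marrow, basophils outside marrow and blood.  Extrapolated
records carry species `rodent` (cross-species route) or `mixed` — never
`human`, since the evidence came from other tissues or species.

## Cell mass

Cells are modelled as spheres; diameter ranges reduce to the geometric
mean of their endpoints (sizes treated as lognormal).  Blood-smear
measurements are deflated by 0.7 for flattening; which records receive the
correction is an input property (the `context` column), not a code
constant.  Volumes pool by geometric mean with the log-space SE as
uncertainty (a single record falls back to a 1.3 error factor), then
convert at 1.07 g/mL; the ~0.02 g/mL variation between cell types is
negligible against volume uncertainty.  Macrophages resolve
tissue-specifically, then by whether the tissue's macrophage population is
continuously replenished from monocytes (gut, dermis, adipose, ...) or
locally self-renewing (microglia, Kupffer cells, alveolar macrophages),
then body-wide.

## Census assembly

Counts are density × organ mass per (tissue, cell type); margins by
tissue, by type, and the grand total are bootstrap sums honoring the
extrapolation correlation groups, and the point margins equal the sums of
member point values to 1e-9 relative tolerance by construction.

The mass census multiplies counts by per-type representative masses with a
*two-factor* bootstrap: count errors resample per entry, while each
distinct mass estimate gets one shared deviate across all tissues it
applies to — one representative mass multiplies a type's count everywhere,
so its error must not average out in sums.

Reference persons (73-kg male, 60-kg female, 32-kg child) differ only in
organ masses; densities are assumed age- and sex-independent, so scaling
is exactly linear in the masses.  The lymph-node mass, tabulated only for
the adult male, is filled for other persons by linear body-mass scaling
(the interpolation variable is not uniquely determined by the source
tables; body mass is the documented choice).

The scenario engine perturbs organ masses (optionally only a mass
fraction: enlarging a fraction `f` of lymph nodes by volume factor `v`
scales the tissue by `1 + f·(v−1)`; diameter ratios cube to volume
factors) or individual densities, and reports relative margin changes.
Lymph-node volumes are taken as explicit inputs rather than derived from
nominal node diameters, whose published arithmetic is not internally
consistent.

Reported totals round to one significant digit in printed summaries; CSVs
keep full precision.

## Synthetic data: what it emulates and what it does not

The generator draws true per-(tissue, type) densities from per-group
log10 scales calibrated to the published census structure (marrow 10^8.8,
lymphoid 10^9.3, epithelia ~10^7.5, muscle/fat 10^5.55 cells/g) with
0.25 log-e per-tissue jitter, fixed per-group type compositions, and true
cell diameters back-solved from the published per-type count and mass
totals.  Around this truth it emits: 3 lognormal literature records per
pair at declared ferror 1.8 (typical of between-study spread in such
evidence bases); Poisson multiplexed counts per 400×400 μm field for the
lymphoid organs with a 0.2 log-e between-patient random effect (3
patients × 4 fields); deconvolution fractions consistent with the true
compositions (0.3 log-e noise, T-cell anchor at ferror 1.2); and 3 size
records per type with 0.15 log-e volume scatter, one of them a blood-smear
record pre-inflated so the 0.7 correction recovers truth.  A quarter of
the pairs in the data-poor groups (muscle, fat, CNS, connective, ECF) lose
their human evidence — half of those get rodent records instead — to
exercise extrapolation, mirroring where real evidence is thin.  All
randomness flows from one seed; the zero-noise configuration disables the
count-based channels (Poisson discretisation is itself noise) and is
recovered exactly by the pipeline.

What the generator does **not** emulate: systematic inter-method biases
(e.g. dissociation losses in flow cytometry), non-lognormal outliers,
correlated biases across tissues within one study, or body-wide
covariation of organ masses.  Passing recovery tests therefore shows the
estimator machinery is calibrated under the declared error model, not that
the published census is correct.

## Numerical choices and known limitations

* Bootstrap seeds: every stochastic operation takes an explicit seed;
  reported CIs use the config seed (2023).  Problem sizes in the shipped
  tests and acceptance script (100/200-replicate recovery loops, 50
  acceptance replicates, 10⁶-draw oracles) were chosen to make the checks
  statistically meaningful while keeping a full run around half a minute.
* Whether published point values are medians or means of the fitted
  lognormals is not stated in the sources; medians are used throughout,
  which can shift totals by a few percent.
* Summing many median-unbiased lognormal estimates is *mean*-biased
  upward (each entry's expectation is `truth·e^{s²/2}`).  On the default
  synthetic conditions this inflates the grand totals by ~10%; the count
  census absorbs it (95% CI coverage 94/100 replicates) but the mass
  census, whose interval is relatively tight at the low end, covers only
  ~85/100.  The bias is inherent to the median-point/sum-of-points
  estimator and is documented rather than corrected; a smearing-style
  debias would trade it for sensitivity to the estimated shape parameters.
* Restriction lists, similarity groups, tissue masses, and macrophage
  replenishment classes ship as editable tables/constants, not hard-coded
  behaviour.
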