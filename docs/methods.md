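# Methods

This note documents the models behind each nitriflux stage, the
defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical conventions that make the
results deterministic.

## Tracer-rate model

Gross ammonia and nitrite oxidation rates are estimated by isotope
dilution. A ¹⁵N-labeled substrate spike raises the substrate pool's
¹⁵N atom fraction to the *labeled fraction*

    f = (C_tracer · AF_purity + C_ambient · AF_natural) / (C_tracer + C_ambient),

and product formed during the incubation carries ¹⁵N in proportion to
f. The estimator is

1. calibrate each measured δ¹⁵N with the measured-versus-assigned
   standards regression (inverted: δ_true = (δ_meas − b)/a); the fit
   must reach R² ≥ 0.999 or it is rejected outright, since a drifting
   instrument invalidates every downstream number;
2. convert δ to atom fraction, AF = R/(1+R) with
   R = R_ref·(1+δ/1000) and R_ref = 0.0036765 (¹⁵N/¹⁴N of atmospheric
   N₂, the scale δ¹⁵N is reported against; configurable);
3. excess ¹⁵N per bottle = (AF − AF_t0) × product-pool concentration,
   where AF_t0 is the mean atom fraction of the bottles filtered
   immediately after tracer addition (the blank). Using the measured
   blank rather than an assumed natural-abundance constant absorbs any
   ambient ¹⁵N offset of the product pool;
4. ordinary least squares of excess ¹⁵N (nmol L⁻¹) on time (h) over
   all timepoint × replicate points — the regression uses all six
   bottles of the standard 0/6/12 h duplicate design rather than a
   two-point difference, which both uses the replication and yields a
   slope standard error;
5. rate = slope / f × 24/1000 (µmol L⁻¹ d⁻¹).

Assumptions: ¹⁵N accumulation is linear over the (short) incubation;
the product pool concentration is constant at its initial value (the
tracer-level conversions are small relative to ambient NOₓ);
isotope fractionation during oxidation is ignored (second-order at
tracer enrichments); substrate drawdown is not modelled. Negative
rates are legitimate noise outcomes at low activity and are returned
with a `negative_rate` warning, never truncated — truncation would
bias any downstream averaging of rates.

Defaults: tracer purity 0.99 atom fraction (typical commercial label),
ambient substrate at natural abundance AF. Both are fields of
`SubstratePool` and freely settable.

## Abundance normalizations

* `rpm` — per sample, `10⁶·(count/length)/Σ(count/length)` over the
  whole catalog. Columns sum to 10⁶ by construction (relative
  tolerance 10⁻⁹ is asserted in tests); RPM is invariant to uniform
  scaling of a sample's counts. The denominator spans the full
  catalog, not only annotated genes.
* `rpkm` — `(count/(length/10³))/(total_mapped_reads/10⁶)`.
* `rpkg` — `(count/(length/10³))/metagenome_gb`, the read-recruitment
  currency for genome abundance; features may be genomes or genes.
* `dna_yield_normalize` — RPM × µg DNA per liter of seawater, a
  semi-quantitative volumetric proxy. It is defined for RPM input only
  and rejects other currencies, since mixing it with per-kilobase
  units would produce numbers with no interpretation.
* `zscore` — per feature across samples with the n−1 denominator,
  because the display it supports compares one gene's profile across
  the 9 depth × fraction samples. Constant features map to all-zero
  rows with a warning.

Zero denominators (a function absent from a sample, a clade whose
*amoA* recruits no reads) propagate as missing values, never as
zeros: a zero would manufacture evidence where there is none.
Unannotated genes are retained under an explicit `unassigned` label in
roll-ups so per-sample totals are conserved exactly.

`amoa_normalized_ratio` divides the summed RPKG of a target function
within a clade by the clade's summed *amoA* RPKG. Because ammonia
oxidizers carry amoA as a single-copy core gene, the ratio estimates
gene copies per cell and is comparable across clades of different
abundance. Summaries report mean ± sd (n−1) over non-missing samples;
outlier exclusions must be passed explicitly and are logged.

## Genome catalog

Quality filtering uses inclusive comparisons (completeness ≥ floor,
contamination ≤ ceiling) so records exactly at (50, 10) count as
medium quality. Dereplication consumes a precomputed pairwise ANI
table — ANI computation itself is upstream tooling — and clusters by
single-linkage connected components over pairs at or above the
threshold (95% default, the conventional species boundary). The
representative maximizes completeness − 5 × contamination, with ties
broken by genome length and then lexicographic id; the weighting
follows dRep's scoring concept, and the deterministic tie-breaks exist
so that repeated runs and tests always agree. Novelty against a
reference set is strict (`< threshold`), and a missing query-reference
pair means no detectable similarity, i.e. counts as below threshold.

## Inferential statistics

`two_way_anova` implements the classical balanced fixed-effects
decomposition in closed form. Balance is *required*: with unequal cell
counts the SS partition depends on a sums-of-squares-type choice the
caller never made, so the function raises with the offending cell-count
table instead of silently picking one. With one observation per cell
the interaction is the error stratum and is omitted with a warning. A
constant response yields zero SS everywhere and missing F/p values
(flagged), since 0/0 has no sampling interpretation. The
implementation is cross-checked against statsmodels' `anova_lm` in the
test suite.

`holm_sidak` is the step-down Šidák adjustment
(adj₍ᵢ₎ = 1 − (1−p₍ᵢ₎)^(m−i+1), running maximum, capped at 1),
delegated to statsmodels with input validation; the closed form is
frozen in tests as an independent oracle.

`wilcoxon_rank_sum` uses the midrank sum of the first group as the
statistic. For n+m ≤ 20 (configurable) the two-sided p-value is exact:
all C(n+m, n) assignments of pooled midranks are enumerated, the
smaller tail is doubled and capped at 1 — enumeration over midranks
handles ties without any approximation. Beyond the cutoff a normal
approximation applies the standard tie correction to the variance and
a 0.5 continuity correction. The doubling convention (rather than
summing both tails' achievable mass) was chosen for determinism and
agreement with the common two-sided definition; it matches scipy's
exact Mann-Whitney on tie-free data, which the tests verify.

## Synthetic data generators

All generators are pure functions of (spec, seed) with no global
random state, so identical calls are bit-for-bit reproducible.

**Tracer incubations** follow the estimation model exactly in reverse:
excess(t) = rate·f·t, AF(t) = AF₀ + excess/pool, δ(t) by the exact
inverse transform, plus Gaussian noise on the δ scale (instrument
noise is conventionally quoted as a per-mil sd). Defaults mirror the
standard field design: 0/6/12 h, duplicate bottles, a 500 nmol L⁻¹
spike into 4500 nmol L⁻¹ ambient substrate (≈10% labeled), a
5 µmol L⁻¹ product pool, and 0.2‰ δ-noise — a typical
denitrifier-method precision, used because no instrument sd accompanies
most published rate tables. The generator refuses specs that would
push the product pool's atom fraction to 1 (pool overflow).

**Community counts** sample a fixed library size per sample
(multinomial), with expected gene reads proportional to genome weight
× gene length and genome weight = base abundance × a multiplicative
enrichment factor per (depth, fraction, clade). Multinomial rather
than independent Poisson sampling keeps per-sample read totals exact,
matching the fixed-total structure RPM assumes. The default community
has three ammonia-oxidizer clades (two Nitrosomarinus-like genomes,
one WCA-like, one Nitrosopumilus-like) carrying an amoA/amt/nirK/
ureC/pst/pit/phn/sod panel with clade-specific copy numbers (4 amt
copies per amoA in the Nitrosomarinus-like clade versus 2 elsewhere,
echoing the kind of transporter-dosage divergence seen between
coastal AOA clades), over ten heterotrophic background genomes. The
planted niche signal is a 10× enrichment of all AOA clades on large
particles at 50 m (3× on the intermediate fraction, 2× on large
particles at 25 m), with DNA yields rising with depth in the particle
fractions.

One deliberate scaling choice: AOA base weights are trace-level
(~0.1% of catalog weight). Because the library size is fixed,
relative abundances are compositional — enriching a clade deflates
everything else — so a planted fold change E appears in the LPA/FL
RPM ratio only attenuated by the closure factor Z_FL/Z_LPA. In a real
metagenome the non-redundant catalog is enormous and any one
functional panel is a trace of it, making the attenuation negligible;
keeping the simulated panel at trace weight reproduces that regime
(closure bias ≲2%, well inside sampling error at the default 10⁶
reads per sample). Metagenome size is reads × 150 bp read length.

**Genome tables** draw within-cluster ANI uniformly from a range
entirely at or above the dereplication threshold and between-cluster
ANI from a range entirely below it; a spec whose ranges straddle the
threshold is rejected because the planted partition would be
ambiguous. Quality metrics are uniform in their ranges.

What the generators do **not** emulate — and hence what passing
recovery tests do not establish about field data: sequencing error,
mapping ambiguity and catalog redundancy; genome-coverage variation
along the chromosome; substrate drawdown, nonlinear tracer
accumulation or bottle effects; correlated community structure across
samples beyond the planted enrichment factors; chimeric or
contaminated bins. Recovery results demonstrate the correctness of
the estimators under their stated models, not robustness to upstream
artifacts.

## Problem sizes and determinism

The validation suite runs everything at desk scale, chosen to keep
Monte-Carlo error far below the tested tolerances: 200 noisy
incubations for RMSE/bias, 50 random matrices for RPM conservation,
100 random ANI matrices (n ≤ 12) against the brute-force oracle, 2000
null datasets for ANOVA type-I calibration (sampling sd ≈ 0.005 around
0.05), and 100 seeded pipeline runs at 10⁶ reads per sample for
enrichment detection. `scripts/acceptance.py` derives every random
stream from its `--seed` argument via numpy's `default_rng`.

## Known limitations

* The ANOVA handles balanced layouts only, by design.
* Exact rank-sum enumeration is O(C(n+m, n)); the default cutoff of
  20 keeps it under ~2·10⁵ arrangements.
* `ANIMatrix` is dense; it targets hundreds of genomes, not hundreds
  of thousands.
* DNA-yield normalization inherits all caveats of extraction
  efficiency; it is a comparative proxy, not an absolute abundance.
* The rate estimator treats the product pool as constant; incubations
  long enough for substantial pool turnover violate the model.
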