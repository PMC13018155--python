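# nitriflux

Quantitative tools for studying **nitrification under coastal
deoxygenation**: estimating gross ammonia- and nitrite-oxidation rates
from ¹⁵N-tracer incubations, normalizing size-fractionated metagenomic
read counts into comparable abundance currencies, filtering and
dereplicating metagenome-assembled genomes (MAGs), and testing for
niche partitioning between particle-associated and free-living
microbial lifestyles across an oxygen (depth) gradient.

The package is aimed at biogeochemists and microbial ecologists who
have already produced the upstream derivatives of a field campaign —
δ¹⁵N time courses from isotope-ratio mass spectrometry, mapped-read
count tables from a gene catalog, MAG quality/ANI tables — and need the
downstream quantitative pipeline in one tested, scriptable place. A
seeded synthetic-data module generates all of these inputs with known
ground truth, so every stage can be validated by parameter recovery.

## The quantities it computes

**Tracer rates.** After spiking a ¹⁵N-labeled substrate (¹⁵NH₄⁺ or
¹⁵NO₂⁻) into seawater, ¹⁵N accumulates linearly in the product pool
(NO₂⁻+NO₃⁻, or NO₃⁻ after sulfamic-acid nitrite removal). With
measured δ¹⁵N calibrated against isotope reference materials and
converted to atom fractions (AF = R/(1+R), R = R_ref·(1+δ/1000)), the
gross oxidation rate is

    rate = (d[¹⁵N-product]/dt) / f,     f = [¹⁵S]·AF_tracer + [¹⁴S]·AF_nat
                                            ───────────────────────────────
                                                    [¹⁵S] + [¹⁴S]

where the slope comes from ordinary least squares over all
(timepoint, replicate) excess-¹⁵N values relative to the t = 0 blank,
and f is the labeled fraction of the substrate pool. Rates are reported
in µmol L⁻¹ d⁻¹; negative estimates are flagged, never clipped.

**Abundance currencies.** RPM (reads per million, length-corrected,
columns sum to 10⁶), RPKM (reads per kilobase per million mapped
reads), RPKG (reads per kilobase of genome per gigabase of metagenome),
DNA-yield-normalized RPM (× µg DNA L⁻¹ seawater), and per-feature
z-scores, plus taxon contributions to a function's abundance, grouped
roll-ups, and per-clade functional gene dosages normalized to *amoA*
copies.

**Genome catalog.** CheckM-style quality filters (medium ≥50%/≤10%,
high ≥90%/≤5%), species-level dereplication at 95% ANI by
single-linkage connected components with dRep-style representative
scoring (completeness − 5×contamination), and novelty flags (best
reference ANI < 95%).

**Niche statistics.** Balanced two-way fixed-effects ANOVA
(depth zone × lifestyle) with interaction, Holm–Šidák step-down
adjustment, and two-sided Wilcoxon rank-sum tests with exact enumerated
p-values at small n (ties handled by midranks).

## Worked example

```python
import nitriflux as nf

# a simulated 0/6/12 h incubation, duplicate bottles, 0.2 permil noise
spec = nf.TracerSimSpec(true_rate=1.0, delta_noise_sd=0.2, seed=42)
series, truth = nf.simulate_incubation(spec)
est = nf.estimate_rate(series)
print(f"rate = {est.rate:.4f} umol/L/d  (f = {est.labeled_fraction:.4f}, "
      f"R2 = {est.r_squared:.5f}, n = {est.n_points})")
```

prints

```
rate = 0.9999 umol/L/d  (f = 0.1023, R2 = 1.00000, n = 6)
```

i.e. the estimator returns the planted 1.0 µmol L⁻¹ d⁻¹ rate to within
instrument noise; `f` is the labeled fraction of a 500 nmol L⁻¹ spike
at 0.99 atom-fraction purity into 4500 nmol L⁻¹ ambient ammonium.

The same round trip holds for the metagenomic side:

```python
gene_cm, genome_cm, samples, truth = nf.simulate_counts(
    nf.default_community_spec(seed=3))
rpm = nf.rpm(gene_cm)
clades = {g: c for g, c in truth.params["clades"].items() if g.startswith("AOA")}
ratios = nf.amoa_normalized_ratio(nf.rpkg(gene_cm), clades, "amt")
print(nf.ratio_summary(ratios).round(2))
```

```
                     mean    sd  n  n_excluded
clade
Nitrosomarinus_like  4.09  0.76  9           0
Nitrosopumilus_like  2.14  0.82  9           0
WCA_like             1.67  0.29  9           0
```

recovering the planted clade-specific *amt*-per-*amoA* copy numbers
(4, 2 and 2) from multinomially sampled reads.

Every stage is also reachable from the shell via the `nitriflux` CLI
(`calibrate`, `rates`, `normalize`, `ratios`, `filter-mags`, `derep`,
`anova`, `ranksum`, `simulate`, `classify-oxygen`); all tables are
plain TSV with `NA` for missing values.

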