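"""Normalization of mapped-read counts into comparable abundance currencies.

Size-fractionated metagenomes are compared through several complementary
normalizations of mapped-read counts:

* **RPM** — reads per million over a non-redundant gene catalog:
  per sample, ``10⁶ · (count/length) / Σ(count/length)``; columns sum to
  one million, so RPM is a length-corrected relative abundance.
* **RPKM** — reads per kilobase per million mapped reads:
  ``(count / (length/1000)) / (total_mapped_reads/10⁶)``.
* **RPKG** — reads per kilobase of genome per gigabase of metagenome,
  the read-recruitment currency for genome (MAG) abundance:
  ``(count / (genome_length/1000)) / metagenome_gb``.
* **DNA-yield normalization** — RPM × extracted DNA per liter of
  seawater (µg L⁻¹), a semi-quantitative volumetric abundance proxy for
  comparing size fractions.
* **z-score** — per-feature standardization across samples, used to
  display depth × fraction profiles of individual genes.

On top of these sit taxon partitions of a function's abundance
(:func:`taxon_contribution`), grouped roll-ups (:func:`aggregate_by`) and
per-clade functional gene dosages relative to the ammonia monooxygenase
marker *amoA* (:func:`amoa_normalized_ratio`): because every archaeal
ammonia oxidizer carries amoA, the ratio of a gene's summed RPKG to the
clade's amoA RPKG approximates gene copies per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import log
from .exceptions import DesignError, InputError, MetadataError, NormalizationError

FRACTIONS = ("FL", "LFL_SPA", "LPA")
METHODS = ("RPM", "RPKM", "RPKG", "DNA_YIELD", "ZSCORE")

GENE_COLUMNS = ("length_bp", "function_label", "taxon_label", "genome_id")
SAMPLE_COLUMNS = (
    "depth_m",
    "fraction",
    "dna_yield_ug_per_l",
    "total_mapped_reads",
    "metagenome_gb",
)

#: ORFs shorter than this are flagged (catalog construction drops them upstream).
MIN_ORF_BP = 100


@dataclass
class CountMatrix:
    """Mapped-read counts over features (genes or genomes) × samples.

    ``genes`` is a feature table indexed by feature id with at least a
    ``length_bp`` column (plus ``function_label`` / ``taxon_label`` /
    ``genome_id`` for gene catalogs); ``samples`` is indexed by sample id
    with the metadata columns in :data:`SAMPLE_COLUMNS`; ``counts`` is a
    non-negative integer frame aligned to both indexes.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self):
        if "length_bp" not in self.genes.columns:
            raise InputError("feature table requires a length_bp column")
        if not self.counts.index.equals(self.genes.index):
            raise InputError("counts rows must match the feature table index")
        if not self.counts.columns.equals(self.samples.index):
            raise InputError("counts columns must match the sample table index")
        if (self.genes["length_bp"] <= 0).any():
            raise InputError("feature lengths must be positive")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise InputError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise InputError("counts must be integral")
        short = self.genes["length_bp"] < MIN_ORF_BP
        if short.any():
            log.warning(
                "%d features shorter than %d bp (below the ORF filter)",
                int(short.sum()), MIN_ORF_BP,
            )


@dataclass
class AbundanceMatrix:
    """Normalized abundances tagged with the method that produced them."""

    values: pd.DataFrame
    method: str
    feature_kind: str = "gene"
    genes: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    warnings: tuple = field(default=())

    def __post_init__(self):
        if self.method not in METHODS:
            raise InputError(f"unknown method {self.method!r}; expected {METHODS}")


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def rpm(counts: CountMatrix) -> AbundanceMatrix:
    """Reads per million over the gene catalog; columns sum to 10⁶."""
    lengths = counts.genes["length_bp"].to_numpy(dtype=float)
    rate = counts.counts.to_numpy(dtype=float) / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        bad = counts.counts.columns[zero].tolist()
        raise NormalizationError(f"all-zero count column(s): {bad}")
    values = pd.DataFrame(
        1e6 * rate / colsum,
        index=counts.counts.index,
        columns=counts.counts.columns,
    )
    return AbundanceMatrix(values, "RPM", "gene", counts.genes, counts.samples)


def rpkm(counts: CountMatrix) -> AbundanceMatrix:
    """Reads per kilobase per million mapped reads."""
    if "total_mapped_reads" not in counts.samples.columns:
        raise MetadataError("samples table lacks total_mapped_reads")
    total = counts.samples["total_mapped_reads"].to_numpy(dtype=float)
    if np.any(~np.isfinite(total)) or np.any(total <= 0):
        raise MetadataError("total_mapped_reads must be positive for every sample")
    lengths_kb = counts.genes["length_bp"].to_numpy(dtype=float) / 1000.0
    values = (
        counts.counts.to_numpy(dtype=float) / lengths_kb[:, None]
    ) / (total[None, :] / 1e6)
    values = pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns)
    return AbundanceMatrix(values, "RPKM", "gene", counts.genes, counts.samples)


def rpkg(genome_counts: CountMatrix) -> AbundanceMatrix:
    """Reads per kilobase of genome per gigabase of metagenome.

    ``genome_counts`` is a :class:`CountMatrix` whose features are genomes
    (``length_bp`` holds the genome length) or genes of those genomes;
    the formula is the same either way.
    """
    if "metagenome_gb" not in genome_counts.samples.columns:
        raise MetadataError("samples table lacks metagenome_gb")
    gb = genome_counts.samples["metagenome_gb"].to_numpy(dtype=float)
    if np.any(~np.isfinite(gb)) or np.any(gb <= 0):
        raise MetadataError("metagenome_gb must be positive for every sample")
    lengths_kb = genome_counts.genes["length_bp"].to_numpy(dtype=float) / 1000.0
    values = (
        genome_counts.counts.to_numpy(dtype=float) / lengths_kb[:, None]
    ) / gb[None, :]
    values = pd.DataFrame(
        values, index=genome_counts.counts.index, columns=genome_counts.counts.columns
    )
    kind = "genome" if "function_label" not in genome_counts.genes.columns else "gene"
    return AbundanceMatrix(values, "RPKG", kind, genome_counts.genes, genome_counts.samples)


def dna_yield_normalize(abundance: AbundanceMatrix, samples: pd.DataFrame) -> AbundanceMatrix:
    """Scale RPM by per-sample DNA yield (µg per liter of seawater).

    Only defined for RPM input — the volumetric proxy is specifically
    RPM × µg DNA L⁻¹. Other methods are rejected.
    """
    if abundance.method != "RPM":
        raise InputError(
            f"DNA-yield normalization applies to RPM only, got {abundance.method}"
        )
    if "dna_yield_ug_per_l" not in samples.columns:
        raise MetadataError("samples table lacks dna_yield_ug_per_l")
    missing = [s for s in abundance.values.columns if s not in samples.index]
    if missing:
        raise MetadataError(f"no DNA yield for sample(s): {missing}")
    yields = samples.loc[abundance.values.columns, "dna_yield_ug_per_l"].astype(float)
    if yields.isna().any():
        raise MetadataError("DNA yield missing (NA) for some samples")
    warns = []
    if (yields == 0).any():
        warns.append("zero_dna_yield")
        log.warning("zero DNA yield for %s", yields.index[yields == 0].tolist())
    values = abundance.values * yields
    return AbundanceMatrix(
        values, "DNA_YIELD", abundance.feature_kind,
        abundance.genes, samples, tuple(warns),
    )


def zscore(abundance: AbundanceMatrix) -> AbundanceMatrix:
    """Standardize each feature across samples: (x − mean)/sd, sd with n−1.

    Constant features (zero sd) map to all-zero rows with a warning —
    they carry no contrast but must not break the display.
    """
    values = abundance.values
    if values.shape[1] < 2:
        raise DesignError("z-scoring requires at least 2 samples")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    flat = sd == 0
    warns = []
    if flat.any():
        warns.append("zero_sd_features")
        log.warning("%d constant feature(s) z-scored to zero", int(flat.sum()))
    z = values.sub(mean, axis=0).div(sd.where(~flat, 1.0), axis=0)
    z[flat] = 0.0
    return AbundanceMatrix(
        z, "ZSCORE", abundance.feature_kind,
        abundance.genes, abundance.samples, tuple(warns),
    )


# ---------------------------------------------------------------------------
# partitions and roll-ups
# ---------------------------------------------------------------------------

def _require_genes(abundance: AbundanceMatrix) -> pd.DataFrame:
    if abundance.genes is None:
        raise InputError("operation requires gene annotation attached to the matrix")
    return abundance.genes


def taxon_contribution(
    abundance: AbundanceMatrix, function_label: str, taxon_label: str
) -> pd.Series:
    """Fraction of a function's abundance contributed by one taxon, per sample.

    ``Σ abundance(function ∧ taxon) / Σ abundance(function)`` — e.g. the
    AOA share of total *nirK*. Samples where the function is absent
    (zero denominator) yield NaN, not 0: absence of the function is not
    evidence that the taxon contributes nothing.
    """
    genes = _require_genes(abundance)
    in_fn = genes["function_label"] == function_label
    if not in_fn.any():
        raise InputError(f"function {function_label!r} not present in the catalog")
    denom = abundance.values[in_fn.to_numpy()].sum(axis=0)
    numer = abundance.values[
        (in_fn & (genes["taxon_label"] == taxon_label)).to_numpy()
    ].sum(axis=0)
    frac = numer / denom.where(denom != 0)
    frac.name = f"{taxon_label}:{function_label}"
    return frac


def aggregate_by(abundance: AbundanceMatrix, key) -> AbundanceMatrix:
    """Sum abundances within groups of one or more gene-annotation keys.

    ``key`` is ``"function_label"``, ``"taxon_label"``, ``"genome_id"``
    or a tuple of those. Missing labels are pooled under ``"unassigned"``
    rather than dropped, so per-sample totals are conserved exactly.
    """
    genes = _require_genes(abundance)
    keys = [key] if isinstance(key, str) else list(key)
    for k in keys:
        if k not in genes.columns:
            raise InputError(f"gene table has no column {k!r}")
    labels = genes[keys].astype(object).fillna("unassigned").replace("", "unassigned")
    values = abundance.values.groupby([labels[k] for k in keys], sort=True).sum()
    if keys == ["function_label"]:
        kind = "function"
    elif keys == ["genome_id"]:
        kind = "genome"
    else:
        kind = "taxon_function"
    return AbundanceMatrix(values, abundance.method, kind, None, abundance.samples)


def amoa_normalized_ratio(
    gene_abundance: AbundanceMatrix,
    clade_map: dict,
    target_function: str,
    amoa_label: str = "amoA",
) -> pd.DataFrame:
    """Per-clade functional gene dosage relative to amoA, per sample.

    For each clade (genomes grouped via ``clade_map``), the summed RPKG
    of ``target_function`` genes divided by the summed RPKG of amoA
    genes. Since amoA is the single-copy marker of ammonia oxidizers,
    the ratio estimates gene copies per amoA copy (per cell). Samples
    where a clade's amoA abundance is zero yield NaN.

    Returns a clades × samples frame.
    """
    if gene_abundance.method != "RPKG":
        raise InputError("amoA-normalized ratios are defined on RPKG gene abundances")
    genes = _require_genes(gene_abundance)
    if "genome_id" not in genes.columns:
        raise InputError("gene table requires genome_id to map genes onto clades")
    clades = genes["genome_id"].map(clade_map)
    rows = []
    index = []
    for clade in sorted(set(clade_map.values())):
        in_clade = (clades == clade).to_numpy()
        amoa_mask = in_clade & (genes["function_label"] == amoa_label).to_numpy()
        if not amoa_mask.any():
            raise InputError(f"clade {clade!r} has no {amoa_label} annotation")
        target_mask = in_clade & (genes["function_label"] == target_function).to_numpy()
        amoa_sum = gene_abundance.values[amoa_mask].sum(axis=0)
        target_sum = gene_abundance.values[target_mask].sum(axis=0)
        rows.append(target_sum / amoa_sum.where(amoa_sum != 0))
        index.append(clade)
    out = pd.DataFrame(rows, index=pd.Index(index, name="clade"))
    out.columns.name = "sample_id"
    return out


def ratio_summary(ratios: pd.DataFrame, exclude: dict | None = None) -> pd.DataFrame:
    """Per-clade mean ± sd (n−1) of amoA-normalized ratios across samples.

    ``exclude`` maps clade → iterable of sample ids to drop (e.g. a
    documented outlier); every exclusion is logged. NaN ratios (clade
    amoA absent in a sample) are ignored. A clade with no usable values
    is an error; n=1 yields sd = NaN.
    """
    exclude = exclude or {}
    records = []
    for clade, row in ratios.iterrows():
        dropped = [s for s in exclude.get(clade, ()) if s in row.index]
        if dropped:
            log.warning("clade %s: excluding sample(s) %s from summary", clade, dropped)
            row = row.drop(dropped)
        vals = row.dropna()
        if len(vals) == 0:
            raise InputError(f"clade {clade!r} has no non-missing ratios to summarize")
        records.append(
            {
                "clade": clade,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "n": int(len(vals)),
                "n_excluded": len(dropped),
            }
        )
    return pd.DataFrame.from_records(records).set_index("clade")
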