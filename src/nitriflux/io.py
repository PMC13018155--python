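"""Tab-separated table readers and writers for every pipeline stage.

One interchange dialect everywhere: UTF-8, tab-delimited, one header
row, ``NA`` for missing values, and ``#``-prefixed comment lines
(preserved as metadata, e.g. ``#method=RPM`` on abundance tables). No
delimiter sniffing — determinism over convenience.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abundance import CountMatrix, AbundanceMatrix, SAMPLE_COLUMNS
from .catalog import ANIMatrix, GenomeRecord
from .exceptions import SchemaError
from .isotope import IncubationSeries, IsotopeStandard, SubstratePool

NA = "NA"

SCHEMAS = {
    "standards": ["standard_id", "assigned_delta_permil", "measured_delta_permil"],
    "incubations": [
        "series_id", "process", "timepoint_h", "replicate", "delta15N_permil",
        "product_pool_nmol_per_L", "ambient_14N_nmol_per_L", "tracer_15N_nmol_per_L",
    ],
    "rates": [
        "series_id", "rate_umol_per_L_per_d", "slope_nmol_per_L_per_h",
        "labeled_fraction", "slope_stderr", "r_squared", "n_points", "warnings",
    ],
    "samples": [
        "sample_id", "depth_m", "fraction", "dna_yield_ug_per_L",
        "total_mapped_reads", "metagenome_gb",
    ],
    "genomes": [
        "genome_id", "completeness", "contamination", "length_bp", "taxonomy", "source",
    ],
    "ani": ["genome_id_1", "genome_id_2", "ani_percent"],
    "observations": ["response", "factor_a", "factor_b", "replicate"],
    "groups": ["value", "group"],
}

GENE_COUNT_FIXED = ["gene_id", "length_bp", "function_label", "taxon_label", "genome_id"]


# ---------------------------------------------------------------------------
# generic reader / writer
# ---------------------------------------------------------------------------

def read_table(path, required=None, numeric=()) -> pd.DataFrame:
    """Read one TSV table; comments land in ``df.attrs["comments"]``.

    ``required`` columns must be present; ``numeric`` columns are parsed
    as floats with a :class:`SchemaError` naming the row and column on
    failure. ``NA`` parses to NaN.
    """
    comments = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            comments.append(line.rstrip("\n"))
        else:
            body.append(line)
    if not body:
        raise SchemaError(f"{path}: no header row")
    from io import StringIO

    df = pd.read_csv(
        StringIO("".join(body)), sep="\t", dtype=str, na_values=[NA],
        keep_default_na=False,
    )
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in numeric:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row + 2}"
            )
        df[col] = parsed
    df.attrs["comments"] = comments
    return df


def write_table(df: pd.DataFrame, path, comments=(), index=False, float_format="%.10g"):
    """Write one TSV table with optional leading ``#`` comment lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(c if c.startswith("#") else f"#{c}")
            fh.write("\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index=index, float_format=float_format)


# ---------------------------------------------------------------------------
# typed readers
# ---------------------------------------------------------------------------

def read_standards(path) -> list:
    df = read_table(
        path, SCHEMAS["standards"],
        numeric=["assigned_delta_permil", "measured_delta_permil"],
    )
    return [
        IsotopeStandard(r.standard_id, r.assigned_delta_permil, r.measured_delta_permil)
        for r in df.itertuples(index=False)
    ]


def read_incubations(path) -> list:
    """Read a long-format incubation table into one series per series_id."""
    numeric = [
        "timepoint_h", "delta15N_permil", "product_pool_nmol_per_L",
        "ambient_14N_nmol_per_L", "tracer_15N_nmol_per_L",
    ]
    df = read_table(path, SCHEMAS["incubations"], numeric=numeric)
    series = []
    for sid, grp in df.groupby("series_id", sort=True):
        process = grp["process"].iloc[0]
        if grp["process"].nunique() > 1:
            raise SchemaError(f"{path}: series {sid!r} mixes processes")
        pool = SubstratePool(
            ambient_14n=float(grp["ambient_14N_nmol_per_L"].iloc[0]),
            tracer_15n=float(grp["tracer_15N_nmol_per_L"].iloc[0]),
        )
        series.append(
            IncubationSeries(
                process=process,
                measurements=grp.rename(
                    columns={"delta15N_permil": "delta15n_permil"}
                )[["timepoint_h", "replicate", "delta15n_permil"]].reset_index(drop=True),
                product_pool_conc=float(grp["product_pool_nmol_per_L"].iloc[0]),
                substrate=pool,
                nitrite_removed=(process == "nitrite_oxidation"),
                series_id=str(sid),
            )
        )
    return series


def write_rates(estimates, path):
    rows = [
        {
            "series_id": e.series_id,
            "rate_umol_per_L_per_d": e.rate,
            "slope_nmol_per_L_per_h": e.slope_15n,
            "labeled_fraction": e.labeled_fraction,
            "slope_stderr": e.slope_stderr,
            "r_squared": e.r_squared,
            "n_points": e.n_points,
            "warnings": ";".join(e.warnings) if e.warnings else NA,
        }
        for e in estimates
    ]
    write_table(pd.DataFrame(rows, columns=SCHEMAS["rates"]), path)


def read_count_matrix(counts_path, samples_path) -> CountMatrix:
    """Read gene counts + sample metadata into a :class:`CountMatrix`."""
    samples = read_table(
        samples_path, SCHEMAS["samples"],
        numeric=["depth_m", "dna_yield_ug_per_L", "total_mapped_reads", "metagenome_gb"],
    ).rename(columns={"dna_yield_ug_per_L": "dna_yield_ug_per_l"}).set_index("sample_id")
    counts_df = read_table(counts_path, GENE_COUNT_FIXED, numeric=["length_bp"])
    sample_cols = [c for c in counts_df.columns if c not in GENE_COUNT_FIXED]
    if not sample_cols:
        raise SchemaError(f"{counts_path}: no sample count columns")
    unknown = [c for c in sample_cols if c not in samples.index]
    if unknown:
        raise SchemaError(f"{counts_path}: sample column(s) {unknown} absent from metadata")
    genes = counts_df[GENE_COUNT_FIXED].set_index("gene_id")
    counts = counts_df.set_index("gene_id")[sample_cols].apply(
        pd.to_numeric, errors="raise"
    )
    return CountMatrix(genes=genes, samples=samples.loc[sample_cols], counts=counts)


def write_count_matrix(cm: CountMatrix, counts_path, samples_path):
    out = cm.genes.reset_index().merge(
        cm.counts.reset_index(), on="gene_id", how="left"
    )
    write_table(out, counts_path)
    samples = cm.samples.rename(
        columns={"dna_yield_ug_per_l": "dna_yield_ug_per_L"}
    ).reset_index()
    write_table(samples, samples_path)


def write_abundance(ab: AbundanceMatrix, path):
    """Write an abundance matrix with its method recorded as ``#method=``."""
    df = ab.values.copy()
    df.index.name = df.index.name or "feature_id"
    write_table(df.reset_index(), path, comments=[f"#method={ab.method}"])


def read_genomes(path) -> list:
    df = read_table(
        path, SCHEMAS["genomes"],
        numeric=["completeness", "contamination", "length_bp"],
    )
    return [
        GenomeRecord(
            genome_id=r.genome_id,
            completeness=r.completeness,
            contamination=r.contamination,
            length_bp=int(r.length_bp),
            taxonomy="" if pd.isna(r.taxonomy) else r.taxonomy,
            source="study" if pd.isna(r.source) else r.source,
        )
        for r in df.itertuples(index=False)
    ]


def write_genomes(genomes, path):
    rows = [
        {
            "genome_id": g.genome_id,
            "completeness": g.completeness,
            "contamination": g.contamination,
            "length_bp": g.length_bp,
            "taxonomy": g.taxonomy or NA,
            "source": g.source,
        }
        for g in genomes
    ]
    write_table(pd.DataFrame(rows, columns=SCHEMAS["genomes"]), path)


def read_ani(path, ids=None) -> ANIMatrix:
    df = read_table(path, SCHEMAS["ani"], numeric=["ani_percent"])
    return ANIMatrix.from_pairs(df, ids=ids)


def write_ani(ani: ANIMatrix, path):
    write_table(ani.to_pairs(), path)


def write_clusters(result, novel_flags, path):
    """Write the dereplication outcome (and optional novelty flags)."""
    rows = []
    for cid, members in result.clusters.items():
        for g in members:
            rows.append(
                {
                    "genome_id": g,
                    "cluster_id": cid,
                    "is_representative": g == result.representatives[cid],
                    "score": result.scores[g],
                    "novel_flag": bool(novel_flags[g]) if novel_flags is not None and g in novel_flags else NA,
                }
            )
    df = pd.DataFrame(rows).sort_values("genome_id").reset_index(drop=True)
    write_table(df, path)


def fasta_lengths(path) -> dict:
    """Sequence id → length (bp) from a FASTA file (convenience reader)."""
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
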