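import numpy as np
import pandas as pd
import pytest

import nitriflux as nf


@pytest.fixture
def anova_2x2_data():
    """Hand-checked balanced 2x2 design with 2 replicates per cell.

    Cell values {(1,3),(2,4),(5,7),(6,8)}; by hand: SS_A=32, SS_B=2,
    SS_AB=0, SS_E=8, so F_A=16, F_B=1, F_AB=0 with df (1,4).
    """
    return pd.DataFrame(
        {
            "response": [1.0, 3.0, 2.0, 4.0, 5.0, 7.0, 6.0, 8.0],
            "factor_a": ["a1"] * 4 + ["a2"] * 4,
            "factor_b": ["b1", "b1", "b2", "b2"] * 2,
            "replicate": [1, 2, 1, 2] * 2,
        }
    )


@pytest.fixture
def four_genomes():
    """Worked MAG-filter example: (completeness, contamination) quartet."""
    return [
        nf.GenomeRecord("g_high", 95.0, 2.0, 3_000_000),
        nf.GenomeRecord("g_med", 60.0, 8.0, 2_000_000),
        nf.GenomeRecord("g_incomplete", 45.0, 3.0, 2_500_000),
        nf.GenomeRecord("g_contaminated", 70.0, 15.0, 1_000_000),
    ]


@pytest.fixture
def two_gene_counts():
    """Two genes (100 and 200 bp) with 10 reads each in one sample."""
    genes = pd.DataFrame(
        {
            "length_bp": [100, 200],
            "function_label": ["amoA", "nirK"],
            "taxon_label": ["AOA", "AOA"],
            "genome_id": ["g1", "g1"],
        },
        index=pd.Index(["gene_a", "gene_b"], name="gene_id"),
    )
    samples = pd.DataFrame(
        {
            "depth_m": [50],
            "fraction": ["FL"],
            "dna_yield_ug_per_l": [2.0],
            "total_mapped_reads": [1_000_000],
            "metagenome_gb": [5.0],
        },
        index=pd.Index(["s1"], name="sample_id"),
    )
    counts = pd.DataFrame({"s1": [10, 10]}, index=genes.index)
    return nf.CountMatrix(genes=genes, samples=samples, counts=counts)


def random_count_matrix(rng, n_genes=None, n_samples=None):
    """Random small CountMatrix for property tests."""
    n_genes = n_genes or int(rng.integers(2, 15))
    n_samples = n_samples or int(rng.integers(2, 6))
    genes = pd.DataFrame(
        {
            "length_bp": rng.integers(100, 5000, n_genes),
            "function_label": rng.choice(["amoA", "nirK", "amt", "sod"], n_genes),
            "taxon_label": rng.choice(["AOA", "NOB", "other"], n_genes),
            "genome_id": rng.choice(["g1", "g2"], n_genes),
        },
        index=pd.Index([f"gene{i}" for i in range(n_genes)], name="gene_id"),
    )
    sample_ids = [f"s{i}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "depth_m": rng.choice([5, 25, 50], n_samples),
            "fraction": rng.choice(["FL", "LFL_SPA", "LPA"], n_samples),
            "dna_yield_ug_per_l": rng.uniform(0.2, 3.0, n_samples),
            "total_mapped_reads": rng.integers(10_000, 1_000_000, n_samples),
            "metagenome_gb": rng.uniform(0.5, 10.0, n_samples),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    counts = pd.DataFrame(
        rng.integers(0, 500, (n_genes, n_samples)), index=genes.index, columns=sample_ids
    )
    # guarantee the no-all-zero-column precondition
    counts.iloc[0, :] += 1
    return nf.CountMatrix(genes=genes, samples=samples, counts=counts)
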