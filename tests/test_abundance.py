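"""Abundance normalizations, conservation laws, taxon partitions, ratios."""

import numpy as np
import pandas as pd
import pytest

import nitriflux as nf
from nitriflux.exceptions import (
    DesignError,
    InputError,
    MetadataError,
    NormalizationError,
)

from conftest import random_count_matrix


def make_cm(lengths, counts_by_sample, **meta):
    n = len(lengths)
    genes = pd.DataFrame(
        {
            "length_bp": lengths,
            "function_label": meta.get("functions", ["fn"] * n),
            "taxon_label": meta.get("taxa", ["tx"] * n),
            "genome_id": meta.get("genomes", ["g"] * n),
        },
        index=pd.Index([f"gene{i}" for i in range(n)], name="gene_id"),
    )
    sample_ids = list(counts_by_sample)
    samples = pd.DataFrame(
        {
            "depth_m": [50] * len(sample_ids),
            "fraction": ["FL"] * len(sample_ids),
            "dna_yield_ug_per_l": meta.get("yields", [1.0] * len(sample_ids)),
            "total_mapped_reads": meta.get("totals", [1_000_000] * len(sample_ids)),
            "metagenome_gb": meta.get("gbs", [5.0] * len(sample_ids)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    counts = pd.DataFrame(counts_by_sample, index=genes.index)
    return nf.CountMatrix(genes=genes, samples=samples, counts=counts)


class TestRPM:
    def test_hand_worked_two_genes(self, two_gene_counts):
        vals = nf.rpm(two_gene_counts).values["s1"]
        assert vals.iloc[0] == pytest.approx(666666.6667, rel=1e-8)
        assert vals.iloc[1] == pytest.approx(333333.3333, rel=1e-8)

    def test_single_gene_catalog(self):
        cm = make_cm([500], {"s1": [7]})
        assert nf.rpm(cm).values["s1"].iloc[0] == pytest.approx(1e6)

    def test_scale_invariance(self):
        cm1 = make_cm([100, 300, 900], {"s1": [3, 5, 7]})
        cm7 = make_cm([100, 300, 900], {"s1": [21, 35, 49]})
        pd.testing.assert_frame_equal(nf.rpm(cm1).values, nf.rpm(cm7).values)

    def test_column_sums_on_random_matrices(self):
        for seed in range(20):
            cm = random_count_matrix(np.random.default_rng(seed))
            sums = nf.rpm(cm).values.sum(axis=0)
            assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_all_zero_column_raises(self):
        with pytest.raises(NormalizationError, match="s2"):
            nf.rpm(make_cm([100, 200], {"s1": [1, 1], "s2": [0, 0]}))


class TestRPKM:
    def test_hand_worked(self):
        cm = make_cm([2000], {"s1": [100]}, totals=[1_000_000])
        assert nf.rpkm(cm).values["s1"].iloc[0] == pytest.approx(50.0)

    def test_zero_count_zero_rpkm(self):
        cm = make_cm([2000, 100], {"s1": [0, 5]})
        assert nf.rpkm(cm).values["s1"].iloc[0] == 0.0

    def test_inverse_linear_in_library_size(self):
        cm1 = make_cm([500, 900], {"s1": [10, 20]}, totals=[1_000_000])
        cm2 = make_cm([500, 900], {"s1": [10, 20]}, totals=[2_000_000])
        assert np.allclose(nf.rpkm(cm2).values, nf.rpkm(cm1).values / 2)

    def test_missing_total_reads(self):
        cm = make_cm([500], {"s1": [10]})
        cm.samples["total_mapped_reads"] = np.nan
        with pytest.raises(MetadataError):
            nf.rpkm(cm)


class TestRPKG:
    def test_hand_worked(self):
        genomes = pd.DataFrame({"length_bp": [2_000_000]},
                               index=pd.Index(["g1"], name="genome_id"))
        samples = pd.DataFrame(
            {"depth_m": [50], "fraction": ["FL"], "dna_yield_ug_per_l": [1.0],
             "total_mapped_reads": [10], "metagenome_gb": [5.0]},
            index=pd.Index(["s1"], name="sample_id"),
        )
        cm = nf.CountMatrix(genes=genomes, samples=samples,
                            counts=pd.DataFrame({"s1": [1000]}, index=genomes.index))
        assert nf.rpkg(cm).values["s1"].iloc[0] == pytest.approx(0.1)

    def test_halves_when_metagenome_doubles(self):
        cm1 = make_cm([1_000_000], {"s1": [500]}, gbs=[2.0])
        cm2 = make_cm([1_000_000], {"s1": [500]}, gbs=[4.0])
        assert nf.rpkg(cm2).values.iloc[0, 0] == pytest.approx(
            nf.rpkg(cm1).values.iloc[0, 0] / 2
        )

    def test_invalid_metagenome_size(self):
        cm = make_cm([1_000_000], {"s1": [500]}, gbs=[0.0])
        with pytest.raises(MetadataError):
            nf.rpkg(cm)


class TestDnaYield:
    def test_direct_product(self, two_gene_counts):
        out = nf.dna_yield_normalize(nf.rpm(two_gene_counts), two_gene_counts.samples)
        assert out.values["s1"].iloc[0] == pytest.approx(666666.6667 * 2, rel=1e-8)
        assert out.method == "DNA_YIELD"

    def test_columns_scaled_by_yield_vector(self):
        cm = make_cm([100, 200], {"s1": [5, 5], "s2": [5, 5], "s3": [5, 5]},
                     yields=[1.0, 2.0, 3.0])
        r = nf.rpm(cm)
        out = nf.dna_yield_normalize(r, cm.samples)
        assert np.allclose(out.values["s2"], 2 * r.values["s2"])
        assert np.allclose(out.values["s3"], 3 * r.values["s3"])

    def test_zero_yield_warns_and_zeroes(self):
        cm = make_cm([100], {"s1": [5]}, yields=[0.0])
        out = nf.dna_yield_normalize(nf.rpm(cm), cm.samples)
        assert (out.values.to_numpy() == 0).all()
        assert "zero_dna_yield" in out.warnings

    def test_rejects_non_rpm_input(self, two_gene_counts):
        with pytest.raises(InputError):
            nf.dna_yield_normalize(nf.rpkm(two_gene_counts), two_gene_counts.samples)


class TestZscore:
    def test_simple_row(self):
        cm = make_cm([100], {"s1": [1], "s2": [2], "s3": [3]})
        am = nf.AbundanceMatrix(
            pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}), "RPM")
        z = nf.zscore(am).values.iloc[0]
        assert list(z) == pytest.approx([-1.0, 0.0, 1.0])

    def test_hand_worked_row(self):
        am = nf.AbundanceMatrix(pd.DataFrame({"a": [0.0], "b": [0.0], "c": [6.0]}), "RPM")
        z = nf.zscore(am).values.iloc[0]
        assert list(z) == pytest.approx([-0.57735, -0.57735, 1.15470], abs=1e-5)

    def test_constant_row_zeroed_with_warning(self):
        am = nf.AbundanceMatrix(pd.DataFrame({"a": [5.0, 1.0], "b": [5.0, 2.0], "c": [5.0, 3.0]}), "RPM")
        out = nf.zscore(am)
        assert (out.values.iloc[0] == 0).all()
        assert "zero_sd_features" in out.warnings
        assert list(out.values.iloc[1]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_single_sample_is_design_error(self):
        am = nf.AbundanceMatrix(pd.DataFrame({"a": [5.0]}), "RPM")
        with pytest.raises(DesignError):
            nf.zscore(am)

    def test_rows_standardized_on_random_matrix(self):
        cm = random_count_matrix(np.random.default_rng(11), n_genes=8, n_samples=5)
        z = nf.zscore(nf.rpm(cm)).values
        nonconst = z.std(axis=1, ddof=1) > 0
        assert np.allclose(z[nonconst].mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z[nonconst].std(axis=1, ddof=1), 1, rtol=1e-9)


class TestTaxonContribution:
    def test_sole_taxon_gets_one(self):
        cm = make_cm([100, 200], {"s1": [5, 5]}, functions=["nirK", "nirK"],
                     taxa=["AOA", "AOA"])
        frac = nf.taxon_contribution(nf.rpm(cm), "nirK", "AOA")
        assert frac["s1"] == pytest.approx(1.0)

    def test_hand_worked_86_percent(self):
        am = nf.AbundanceMatrix(
            pd.DataFrame({"s1": [86.0, 14.0]},
                         index=pd.Index(["a", "b"], name="gene_id")),
            "RPM",
            genes=pd.DataFrame(
                {"length_bp": [100, 100], "function_label": ["nirK", "nirK"],
                 "taxon_label": ["AOA", "other"], "genome_id": ["g1", "g2"]},
                index=pd.Index(["a", "b"], name="gene_id")),
        )
        assert nf.taxon_contribution(am, "nirK", "AOA")["s1"] == pytest.approx(0.86)

    def test_absent_function_in_sample_is_missing(self):
        cm = make_cm([100, 200], {"s1": [5, 0], "s2": [5, 3]},
                     functions=["amoA", "nirK"], taxa=["AOA", "AOA"])
        frac = nf.taxon_contribution(nf.rpm(cm), "nirK", "AOA")
        assert np.isnan(frac["s1"])
        assert frac["s2"] == pytest.approx(1.0)

    def test_unknown_function_raises(self, two_gene_counts):
        with pytest.raises(InputError):
            nf.taxon_contribution(nf.rpm(two_gene_counts), "nosuch", "AOA")

    def test_partition_sums_to_one(self):
        cm = random_count_matrix(np.random.default_rng(5), n_genes=12, n_samples=4)
        r = nf.rpm(cm)
        total = None
        for taxon in cm.genes["taxon_label"].unique():
            if not (cm.genes["function_label"] == "amoA").any():
                pytest.skip("random draw lacks the function")
            frac = nf.taxon_contribution(r, "amoA", taxon)
            total = frac if total is None else total + frac
        present = ~total.isna()
        assert np.allclose(total[present], 1.0)


class TestAggregate:
    def test_conserves_totals(self):
        cm = random_count_matrix(np.random.default_rng(3), n_genes=10, n_samples=3)
        r = nf.rpm(cm)
        agg = nf.aggregate_by(r, "function_label")
        assert np.allclose(agg.values.sum(axis=0), r.values.sum(axis=0), rtol=1e-12)

    def test_two_amoa_rows_summed(self):
        cm = make_cm([100, 100, 200], {"s1": [1, 2, 3]},
                     functions=["amoA", "amoA", "nirK"])
        r = nf.rpm(cm)
        agg = nf.aggregate_by(r, "function_label")
        assert agg.values.loc["amoA", "s1"] == pytest.approx(
            r.values.iloc[0:2]["s1"].sum()
        )

    def test_missing_labels_become_unassigned(self):
        cm = make_cm([100, 100], {"s1": [1, 2]}, functions=["amoA", None])
        agg = nf.aggregate_by(nf.rpm(cm), "function_label")
        assert "unassigned" in agg.values.index
        assert np.allclose(agg.values.sum(axis=0), 1e6, rtol=1e-9)


class TestAmoaRatios:
    def make_rpkg(self, values, functions, genomes):
        genes = pd.DataFrame(
            {"length_bp": [1000] * len(functions), "function_label": functions,
             "taxon_label": ["AOA"] * len(functions), "genome_id": genomes},
            index=pd.Index([f"g{i}" for i in range(len(functions))], name="gene_id"),
        )
        return nf.AbundanceMatrix(
            pd.DataFrame({"s1": values}, index=genes.index), "RPKG", "gene", genes)

    def test_direct_quotient(self):
        ab = self.make_rpkg([2.0, 4.0], ["amoA", "amt"], ["G1", "G1"])
        ratios = nf.amoa_normalized_ratio(ab, {"G1": "cladeX"}, "amt")
        assert ratios.loc["cladeX", "s1"] == pytest.approx(2.0)

    def test_self_normalization_is_one(self):
        ab = self.make_rpkg([2.0, 4.0], ["amoA", "amt"], ["G1", "G1"])
        ratios = nf.amoa_normalized_ratio(ab, {"G1": "cladeX"}, "amoA")
        assert ratios.loc["cladeX", "s1"] == pytest.approx(1.0)

    def test_zero_amoa_sample_is_missing(self):
        ab = self.make_rpkg([0.0, 4.0], ["amoA", "amt"], ["G1", "G1"])
        ratios = nf.amoa_normalized_ratio(ab, {"G1": "cladeX"}, "amt")
        assert np.isnan(ratios.loc["cladeX", "s1"])

    def test_clade_without_amoa_raises(self):
        ab = self.make_rpkg([1.0, 4.0], ["amt", "amt"], ["G1", "G1"])
        with pytest.raises(InputError):
            nf.amoa_normalized_ratio(ab, {"G1": "cladeX"}, "amt")

    def test_requires_rpkg(self):
        ab = self.make_rpkg([2.0, 4.0], ["amoA", "amt"], ["G1", "G1"])
        ab.method = "RPM"
        with pytest.raises(InputError):
            nf.amoa_normalized_ratio(ab, {"G1": "c"}, "amt")


class TestRatioSummary:
    def test_mean_sd_n(self):
        ratios = pd.DataFrame([[2.0, 4.0]], index=pd.Index(["c"], name="clade"),
                              columns=["s1", "s2"])
        s = nf.ratio_summary(ratios)
        assert s.loc["c", "mean"] == pytest.approx(3.0)
        assert s.loc["c", "sd"] == pytest.approx(np.sqrt(2), rel=1e-6)
        assert s.loc["c", "n"] == 2

    def test_single_value_sd_missing(self):
        ratios = pd.DataFrame([[5.0]], index=pd.Index(["c"], name="clade"), columns=["s1"])
        s = nf.ratio_summary(ratios)
        assert s.loc["c", "mean"] == 5.0
        assert np.isnan(s.loc["c", "sd"])
        assert s.loc["c", "n"] == 1

    def test_explicit_outlier_exclusion_logged(self):
        ratios = pd.DataFrame([[1.0, 1.0, 10.0]], index=pd.Index(["c"], name="clade"),
                              columns=["s1", "s2", "s3"])
        s = nf.ratio_summary(ratios, exclude={"c": ["s3"]})
        assert s.loc["c", "mean"] == pytest.approx(1.0)
        assert s.loc["c", "sd"] == pytest.approx(0.0)
        assert s.loc["c", "n"] == 2
        assert s.loc["c", "n_excluded"] == 1

    def test_all_missing_clade_raises(self):
        ratios = pd.DataFrame([[np.nan, np.nan]], index=pd.Index(["c"], name="clade"),
                              columns=["s1", "s2"])
        with pytest.raises(InputError):
            nf.ratio_summary(ratios)
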