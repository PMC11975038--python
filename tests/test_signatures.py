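import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from agevelo import (
    correlate_aging_genes,
    aging_gene_counts,
    methylation_expression_coupling,
    pathway_contribution,
    pathway_enrichment,
    pathway_trajectory,
    promoter_methylation,
    recapitulation_summary,
)
from agevelo.errors import DomainError
from agevelo.io import ExpressionMatrix
from agevelo.signatures import acceleration_ratio, rowwise_slopes


def expr_from_log(y, genes, samples):
    """ExpressionMatrix whose log2(FPKM+1) equals y exactly."""
    fpkm = np.exp2(np.asarray(y, float)) - 1.0
    return ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=samples),
                            "fpkm")


def sheet_invitro(months, donor="D1", age=55.0):
    return pd.DataFrame({
        "sample_id": [f"{donor}_t{m}" for m in months],
        "donor_id": donor,
        "chronological_age_at_baseline": age,
        "time_in_culture": list(months),
        "condition": "in_vitro_control",
        "cell_type": "fibroblast",
        "assay": "rna_bulk",
    })


def pearson_oracle(x, y):
    """Textbook r = cov/(sx*sy) and t-based two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    r = (np.sum((x - x.mean()) * (y - y.mean()))
         / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    t = r * math.sqrt((n - 2) / (1 - r ** 2))
    return r, 2 * scipy.stats.t.sf(abs(t), n - 2)


def hypergeom_tail_oracle(M, K, n, k):
    """Exact rational P(X >= k) for X ~ Hypergeom(M, K, n)."""
    total = Fraction(0)
    denom = math.comb(M, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, n - i), denom)
    return float(total)


class TestAgingGeneScreen:
    def test_linear_gene_is_perfect_up_hit(self):
        months = np.arange(6)
        y = np.vstack([1 + 0.2 * months,       # exactly linear up
                       np.full(6, 3.0),        # constant -> excluded
                       5 - 0.3 * months])      # exactly linear down
        expr = expr_from_log(y, ["GUP", "GFLAT", "GDOWN"],
                             [f"D1_t{m}" for m in months])
        table = correlate_aging_genes(expr, sheet_invitro(months), "in_vitro")
        t = table.set_index("gene")
        assert t.loc["GUP", "pearson_r"] == pytest.approx(1.0)
        assert t.loc["GUP", "direction"] == "up"
        assert bool(t.loc["GUP", "passes_threshold"])
        assert np.isnan(t.loc["GFLAT", "pearson_r"])
        assert t.loc["GDOWN", "direction"] == "down"
        counts = aging_gene_counts(table)
        assert counts == {"up": 1, "down": 1, "excluded": 1,
                          "non_significant": 0, "total": 3}

    def test_matches_closed_form_pearson(self):
        months = np.arange(6)
        y = np.array([[2.0, 2.5, 2.1, 3.0, 2.8, 3.3]])
        expr = expr_from_log(y, ["G1"], [f"D1_t{m}" for m in months])
        table = correlate_aging_genes(expr, sheet_invitro(months), "in_vitro")
        r, p = pearson_oracle(months / 12.0, y[0])
        assert table["pearson_r"].iloc[0] == pytest.approx(r, abs=1e-9)
        assert table["p_value"].iloc[0] == pytest.approx(p, abs=1e-9)

    def test_too_few_samples_rejected(self):
        months = np.arange(3)
        expr = expr_from_log([[1, 2, 3]], ["G1"],
                             [f"D1_t{m}" for m in months])
        with pytest.raises(DomainError, match="4 samples"):
            correlate_aging_genes(expr, sheet_invitro(months), "in_vitro")

    def test_partition_invariant_on_synthetic_screen(self, invitro):
        table = correlate_aging_genes(invitro.fpkm, invitro.sheet, "in_vitro")
        c = aging_gene_counts(table)
        assert (c["up"] + c["down"] + c["excluded"] + c["non_significant"]
                == c["total"] == len(table))


class TestEnrichment:
    def test_toy_table_matches_exact_tail(self):
        universe = [f"g{i}" for i in range(100)]
        pathway = universe[:20]
        hits = universe[14:20] + universe[90:94]  # 6 in pathway, 10 total
        enr = pathway_enrichment(hits, {"P": pathway}, universe)
        expected = hypergeom_tail_oracle(100, 20, 10, 6)
        assert enr["enrichment_p"].iloc[0] == pytest.approx(expected,
                                                            abs=1e-12)

    def test_extreme_overlap_is_minimal_p(self):
        universe = [f"g{i}" for i in range(50)]
        pathway = universe[:5]
        enr = pathway_enrichment(pathway, {"P": pathway}, universe)
        assert enr["enrichment_p"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(50, 5, 5, 5), abs=1e-15)

    def test_null_hit_rate_not_enriched(self):
        universe = [f"g{i}" for i in range(100)]
        pathway = universe[:20]
        hits = universe[:2] + universe[20:28]  # 10% rate inside and outside
        enr = pathway_enrichment(hits, {"P": pathway}, universe)
        assert enr["enrichment_p"].iloc[0] > 0.3

    def test_empty_universe_rejected(self):
        from agevelo.errors import AgeVeloError
        with pytest.raises(AgeVeloError, match="universe"):
            pathway_enrichment(["a"], {"P": ["a"]}, [])


class TestContribution:
    def test_equal_rates_give_fifty(self):
        res = pathway_contribution(5, 50, 10, 100)
        assert res["contribution_invitro"] == pytest.approx(50.0)
        assert res["classification"] == "overlapping"

    def test_exclusive_invitro(self):
        res = pathway_contribution(7, 50, 0, 100)
        assert res["contribution_invitro"] == pytest.approx(100.0)
        assert res["classification"] == "invitro_specific"

    def test_stated_formula(self):
        res = pathway_contribution(12, 100, 3, 50)
        # (0.12)/(0.12+0.06) = 66.67
        assert res["contribution_invitro"] == pytest.approx(200 / 3, abs=1e-9)
        assert res["classification"] == "overlapping"

    def test_contributions_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            h1, h2 = rng.integers(0, 30, 2)
            if h1 == h2 == 0:
                continue
            n1, n2 = rng.integers(30, 200, 2)
            a = pathway_contribution(h1, n1, h2, n2)["contribution_invitro"]
            b = pathway_contribution(h2, n2, h1, n1)["contribution_invitro"]
            assert a + b == pytest.approx(100.0, abs=1e-9)

    def test_no_hits_rejected(self):
        with pytest.raises(DomainError, match="zero"):
            pathway_contribution(0, 50, 0, 100)


class TestRecapitulation:
    def test_printed_counts_worked_example(self):
        res = recapitulation_summary(16, 17, 51, 55)
        assert res["up_pct"] == pytest.approx(100 * 16 / 17)
        assert res["down_pct"] == pytest.approx(100 * 51 / 55)
        assert round(res["pooled_pct"]) == 93


class TestPathwayTrajectory:
    def test_constant_genes_zero_slope(self):
        months = np.arange(6)
        expr = expr_from_log(np.ones((2, 6)), ["A", "B"],
                             [f"D1_t{m}" for m in months])
        traj = pathway_trajectory(expr, sheet_invitro(months), ["A", "B"],
                                  "in_vitro", "P")
        assert traj["slope"] == 0.0

    def test_two_gene_toy_matches_ols_on_mean_z(self):
        months = np.arange(6)
        rng = np.random.default_rng(3)
        y = np.vstack([1 + 0.3 * months + rng.normal(0, 0.1, 6),
                       4 - 0.1 * months + rng.normal(0, 0.1, 6)])
        expr = expr_from_log(y, ["A", "B"], [f"D1_t{m}" for m in months])
        traj = pathway_trajectory(expr, sheet_invitro(months), ["A", "B"],
                                  "in_vitro", "P")
        z = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, keepdims=True)
        slope = scipy.stats.linregress(months / 12.0, z.mean(axis=0)).slope
        assert traj["slope"] == pytest.approx(slope, abs=1e-9)
        # z-normalization invariant: each gene centered and unit-scaled
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1, atol=1e-12)

    def test_single_gene_rejected(self):
        months = np.arange(6)
        expr = expr_from_log(np.ones((1, 6)), ["A"],
                             [f"D1_t{m}" for m in months])
        with pytest.raises(DomainError, match="PWAY"):
            pathway_trajectory(expr, sheet_invitro(months), ["A", "MISSING"],
                               "in_vitro", "PWAY")

    def test_acceleration_ratio(self):
        assert acceleration_ratio({"slope": 5.4}, {"slope": 0.007}) == \
            pytest.approx(5.4 / 0.007)


class TestPromoterMethylation:
    annot = pd.DataFrame({
        "probe_id": ["p1", "p2", "p3", "pbody"],
        "gene": ["G1", "G1", "G1", "G1"],
        "region": ["TSS200", "TSS1500", "UTR5", "Body"],
    })

    def test_uniform_betas(self):
        betas = pd.DataFrame(0.5, index=["p1", "p2", "p3", "pbody"],
                             columns=["s1", "s2"])
        out = promoter_methylation(betas, self.annot, ["G1"])
        assert np.allclose(out.loc["G1"], 0.5)

    def test_mean_over_promoter_regions_only(self):
        betas = pd.DataFrame(
            {"s1": [0.2, 0.4, 0.9, 0.99]},
            index=["p1", "p2", "p3", "pbody"])
        out = promoter_methylation(betas, self.annot, ["G1"])
        # body probe excluded; mean(0.2, 0.4, 0.9) = 0.5
        assert out.loc["G1", "s1"] == pytest.approx(0.5)

    def test_unannotated_gene_missing(self):
        betas = pd.DataFrame({"s1": [0.2]}, index=["p1"])
        out = promoter_methylation(betas, self.annot, ["G1", "GX"])
        assert np.isnan(out.loc["GX", "s1"])


class TestCoupling:
    def test_negated_slopes(self):
        e = pd.Series([0.1, -0.2, 0.5], index=["A", "B", "C"])
        res = methylation_expression_coupling(e, -e)
        assert res["r"] == pytest.approx(-1.0)

    def test_independent_slopes_uncorrelated(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(1000)]
        e = pd.Series(rng.normal(size=1000), index=genes)
        m = pd.Series(rng.normal(size=1000), index=genes)
        assert abs(methylation_expression_coupling(e, m)["r"]) < 0.1

    def test_generator_coupling_is_negative(self, invitro, world):
        genes = world.aging_genes_up + world.aging_genes_down
        prom = promoter_methylation(invitro.betas, world.probe_annotation,
                                    genes)
        m_slopes = rowwise_slopes(prom, invitro.sheet, "in_vitro",
                                  assay="dnam")
        e_slopes = rowwise_slopes(invitro.fpkm.log2_plus1(), invitro.sheet,
                                  "in_vitro").loc[genes]
        res = methylation_expression_coupling(e_slopes, m_slopes)
        assert res["r"] < -0.3
        assert res["p_value"] < 1e-6

    def test_too_few_genes_rejected(self):
        e = pd.Series([0.1, 0.2], index=["A", "B"])
        with pytest.raises(DomainError, match="3 matched"):
            methylation_expression_coupling(e, -e)
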