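import numpy as np
import pandas as pd
import pytest
import scipy.sparse
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from agevelo import (
    AgingSimConfig,
    AgingWorld,
    ClockModel,
    cell_cycle_fraction,
    clockgene_score,
    gen_single_cell,
    heterogeneity_test,
    lta_score,
    normalize_cells,
    per_pathway_cell_scores,
    pseudobulk,
    quartile_contribution,
)
from agevelo.errors import AgeVeloError, DomainError
from agevelo.io import SparseCountMatrix
from agevelo.single_cell import TARGET_SUM, directional_score


def make_counts(arr, genes=None, cells=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return SparseCountMatrix(scipy.sparse.csr_matrix(arr), genes, cells)


def norm_df(values, genes=None, cells=None):
    """Directly build a normalized-expression frame for score tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cells)


class TestNormalize:
    def test_single_gene_single_cell(self):
        counts = make_counts([[10]])
        norm, report = normalize_cells(counts, min_genes=1)
        assert norm.iloc[0, 0] == pytest.approx(np.log1p(TARGET_SUM))
        assert report["n_dropped"] == 0

    def test_identical_cells_identical_vectors(self):
        counts = make_counts([[4, 4], [6, 6]])
        norm, _ = normalize_cells(counts, min_genes=1)
        assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1])

    def test_toy_matrix_matches_arithmetic(self):
        arr = np.array([[2, 0], [3, 5], [5, 5]])
        norm, _ = normalize_cells(make_counts(arr), min_genes=1)
        expected = np.log1p(arr / arr.sum(axis=0, keepdims=True) * TARGET_SUM)
        assert np.allclose(norm.to_numpy(), expected)

    def test_low_complexity_cells_dropped(self):
        arr = np.array([[5, 1], [5, 0], [5, 0]])
        norm, report = normalize_cells(make_counts(arr), min_genes=2)
        assert report["n_dropped"] == 1 and norm.shape[1] == 1


class TestLTAScore:
    def test_cell_at_dataset_mean_scores_zero(self):
        vals = np.array([[1.0, 2.0, 3.0],
                         [4.0, 6.0, 8.0],
                         [3.0, 2.0, 1.0]])
        norm = norm_df(vals)
        score = lta_score(norm, ["g0"], ["g2"])
        assert score["c1"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_four_cells(self):
        vals = np.array([[0.0, 1.0, 2.0, 3.0],   # up gene
                         [3.0, 2.0, 1.0, 0.0]])  # down gene
        norm = norm_df(vals, genes=["UP", "DOWN"])
        score = lta_score(norm, ["UP"], ["DOWN"])
        z = (np.array([0, 1, 2, 3]) - 1.5) / np.std([0, 1, 2, 3])
        assert np.allclose(score.to_numpy(), 2 * z, atol=1e-9)

    def test_invariant_to_unrelated_genes(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 3, size=(4, 10))
        norm = norm_df(vals)
        base = lta_score(norm, ["g0"], ["g1"])
        extended = pd.concat(
            [norm, norm_df(rng.uniform(0, 3, (3, 10)),
                           genes=["x0", "x1", "x2"])])
        again = lta_score(extended, ["g0"], ["g1"])
        assert np.allclose(base.to_numpy(), again.to_numpy())

    def test_missing_genes_listed(self):
        norm = norm_df(np.ones((2, 4)))
        with pytest.raises(AgeVeloError, match="NOPE"):
            lta_score(norm, ["NOPE"], ["g1"])


class TestClockGeneScore:
    def test_zero_weight_clock_rejected(self):
        clock = ClockModel(name="z", feature_space="gene", intercept=0.0,
                           weights=pd.Series({"g0": 0.0, "g1": 0.0}))
        with pytest.raises(AgeVeloError, match="no nonzero"):
            clockgene_score(norm_df(np.ones((2, 4))), clock)

    def test_single_positive_gene_equals_its_z(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 3, (2, 6))
        norm = norm_df(vals)
        clock = ClockModel(name="one", feature_space="gene", intercept=0.0,
                           weights=pd.Series({"g0": 0.8}))
        score = clockgene_score(norm, clock)
        z = (vals[0] - vals[0].mean()) / vals[0].std()
        assert np.allclose(score.to_numpy(), z)

    def test_recovers_latent_age_rank(self, world):
        cfg = world.config.replace(sc_n_cells=500)
        ds = gen_single_cell(cfg, world)
        norm, _ = normalize_cells(ds.counts)
        score = clockgene_score(norm, world.rna_clock)
        rho = scipy.stats.spearmanr(
            score, ds.truth.cell_bioage.loc[score.index]).statistic
        assert rho > 0.8


class TestQuartiles:
    def cell_sheet(self, cells, donor="D1", timepoints=None):
        return pd.DataFrame({
            "cell_id": cells,
            "donor_id": donor,
            "timepoint": timepoints if timepoints is not None else 0,
        })

    def test_uniform_scores_quarter_each(self):
        cells = [f"c{i}" for i in range(100)]
        scores = pd.Series(np.arange(100, dtype=float), index=cells)
        sheet = self.cell_sheet(cells)
        out = quartile_contribution(scores, sheet)
        row = out.iloc[0]
        for q in ("Q1_youngest", "Q2", "Q3", "Q4_oldest"):
            assert row[q] == pytest.approx(0.25)

    def test_separated_timepoints_enumeration(self):
        cells = ["a", "b", "c", "d"]
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=cells)
        sheet = self.cell_sheet(cells, timepoints=[0, 0, 5, 5])
        out = quartile_contribution(scores, sheet).set_index("timepoint")
        assert out.loc[5, "Q3"] == pytest.approx(0.5)
        assert out.loc[5, "Q4_oldest"] == pytest.approx(0.5)
        assert out.loc[5, "Q1_youngest"] == 0.0
        assert out.loc[0, "Q1_youngest"] == pytest.approx(0.5)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        cells = [f"c{i}" for i in range(40)]
        scores = pd.Series(rng.normal(size=40), index=cells)
        sheet = self.cell_sheet(cells, timepoints=[0] * 20 + [5] * 20)
        a = quartile_contribution(scores, sheet)
        b = quartile_contribution(scores + 100.0, sheet)
        pd.testing.assert_frame_equal(a, b)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        cells = [f"c{i}" for i in range(60)]
        scores = pd.Series(rng.normal(size=60), index=cells)
        sheet = self.cell_sheet(cells, timepoints=rng.choice([0, 5], 60))
        out = quartile_contribution(scores, sheet)
        sums = out[["Q1_youngest", "Q2", "Q3", "Q4_oldest"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_zero_variance_reference_rejected(self):
        cells = [f"c{i}" for i in range(8)]
        scores = pd.Series(1.0, index=cells)
        with pytest.raises(DomainError, match="zero score variance"):
            quartile_contribution(scores, self.cell_sheet(cells))


class TestHeterogeneity:
    def test_identical_deviations_give_zero_f(self):
        g1 = np.array([1.0, 2.0, 3.0])
        res = heterogeneity_test({"a": g1, "b": g1 + 10})
        assert res["levene_F"] == pytest.approx(0.0)

    @pytest.mark.parametrize("center", ["median", "mean"])
    def test_matches_scipy_levene(self, center):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 2.5, 40)
        res = heterogeneity_test({"a": a, "b": b}, center=center)
        f_ref, p_ref = scipy.stats.levene(a, b, center=center)
        assert res["levene_F"] == pytest.approx(f_ref, abs=1e-9)
        assert res["levene_p"] == pytest.approx(p_ref, abs=1e-9)

    @given(st.integers(min_value=0, max_value=2 ** 32 - 1))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_equals_deviation_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        groups = {f"g{i}": rng.normal(0, rng.uniform(0.5, 3), rng.integers(4, 30))
                  for i in range(k)}
        res = heterogeneity_test(groups)
        devs = [np.abs(g - np.median(g)) for g in groups.values()]
        f_ref, p_ref = scipy.stats.f_oneway(*devs)
        assert res["levene_F"] == pytest.approx(f_ref, abs=1e-9)
        assert res["levene_p"] == pytest.approx(p_ref, abs=1e-9)

    def test_degenerate_group_rejected(self):
        with pytest.raises(DomainError, match="3 cells"):
            heterogeneity_test({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestPerPathwayScores:
    def cell_sheet(self, n_per_sample=20):
        rows = []
        for tp in (0, 5):
            for i in range(n_per_sample):
                rows.append({"cell_id": f"c{tp}_{i}", "donor_id": "D1",
                             "timepoint": tp})
        return pd.DataFrame(rows)

    def test_identical_timepoints_not_significant(self):
        rng = np.random.default_rng(5)
        sheet = self.cell_sheet()
        block = rng.normal(0, 1, (6, 20))
        vals = np.hstack([block, block])  # month-5 cells duplicate month-0
        norm = norm_df(vals, cells=list(sheet["cell_id"]))
        sets = {"P1": ["g0", "g1"], "P2": ["g2", "g3"], "P3": ["g4", "g5"]}
        out = per_pathway_cell_scores(
            norm, sheet, sets, {"P1": "up", "P2": "up", "P3": "up"})
        assert out["paired_tests"]["up"]["p_value"] == pytest.approx(1.0)

    def test_paired_t_matches_oracle(self):
        rng = np.random.default_rng(6)
        sheet = self.cell_sheet()
        vals = rng.normal(0, 1, (6, 20))
        spread = np.hstack([vals, vals * rng.uniform(1.2, 2.0, (6, 1))])
        norm = norm_df(spread, cells=list(sheet["cell_id"]))
        sets = {"P1": ["g0", "g1"], "P2": ["g2", "g3"], "P3": ["g4", "g5"]}
        out = per_pathway_cell_scores(
            norm, sheet, sets, {k: "down" for k in sets})
        sd = out["sd_table"].pivot_table(index="pathway", columns="timepoint",
                                         values="score_sd")
        t_ref, p_ref = scipy.stats.ttest_rel(sd[5], sd[0])
        res = out["paired_tests"]["down"]
        assert res["t"] == pytest.approx(t_ref, abs=1e-9)
        assert res["p_value"] == pytest.approx(p_ref, abs=1e-9)

    def test_down_programs_drive_heterogeneity_gain(self, world):
        """Variable loss of down-regulated programs dominates SD growth."""
        cfg = world.config.replace(sc_n_cells=400,
                                   sc_donor_ages=(world.config.donor_ages[2],))
        ds = gen_single_cell(cfg, world)
        norm, _ = normalize_cells(ds.counts)
        sets = {k: v for k, v in world.gene_sets.items()
                if world.pathway_directions[k] in ("up", "down")}
        out = per_pathway_cell_scores(norm, ds.cell_sheet, sets,
                                      world.pathway_directions,
                                      t0=0, t1=cfg.sc_month)
        up = out["paired_tests"]["up"]
        down = out["paired_tests"]["down"]
        gain_up = up["mean_sd_t1"] - up["mean_sd_t0"]
        gain_down = down["mean_sd_t1"] - down["mean_sd_t0"]
        assert gain_down > gain_up


class TestPseudobulk:
    def test_one_cell_per_group_identity(self):
        counts = make_counts([[1, 2], [3, 0]])
        groups = pd.Series(["a", "b"], index=["c0", "c1"])
        pb = pseudobulk(counts, groups)
        assert pb.values.loc["g0", "a"] == 1
        assert pb.values.loc["g1", "b"] == 0

    def test_two_cells_sum(self):
        counts = make_counts([[1, 2]])
        pb = pseudobulk(counts, pd.Series(["a", "a"], index=["c0", "c1"]))
        assert pb.values.loc["g0", "a"] == 3
        assert pb.unit == "counts"

    def test_unassigned_cell_rejected(self):
        counts = make_counts([[1, 2]])
        with pytest.raises(AgeVeloError, match="without a group"):
            pseudobulk(counts, pd.Series(["a"], index=["c0"]))


class TestCellCycle:
    def test_identical_cells_fraction_zero(self):
        norm = norm_df(np.ones((3, 5)))
        res = cell_cycle_fraction(norm, ["g0", "g1"])
        assert res["fraction_above"] == 0.0

    def test_one_elevated_cell_of_four(self):
        vals = np.array([[1.0, 1.0, 1.0, 5.0],
                         [2.0, 2.0, 2.0, 9.0]])
        res = cell_cycle_fraction(norm_df(vals), ["g0", "g1"],
                                  z_threshold=1.0)
        assert res["fraction_above"] == pytest.approx(0.25)

    def test_minus_infinity_threshold_catches_all(self):
        rng = np.random.default_rng(7)
        norm = norm_df(rng.uniform(0, 2, (3, 6)))
        res = cell_cycle_fraction(norm, ["g0"], z_threshold=-np.inf)
        assert res["fraction_above"] == 1.0

    def test_simulated_g0_population_has_low_g2m_fraction(self, world):
        cfg = world.config.replace(sc_n_cells=300,
                                   sc_donor_ages=(world.config.donor_ages[2],))
        ds = gen_single_cell(cfg, world)
        norm, _ = normalize_cells(ds.counts)
        res = cell_cycle_fraction(norm, world.gene_sets["G2M_SET"])
        assert res["fraction_above"] < 0.5


class TestLatentAgeRecovery:
    def test_lta_tracks_latent_age(self, world):
        cfg = world.config.replace(sc_n_cells=500)
        ds = gen_single_cell(cfg, world)
        norm, _ = normalize_cells(ds.counts)
        score = lta_score(norm, world.overlap_up_genes,
                          world.overlap_down_genes)
        rho = scipy.stats.spearmanr(
            score, ds.truth.cell_bioage.loc[score.index]).statistic
        assert rho > 0.8

    def test_directional_score_zero_mean(self):
        rng = np.random.default_rng(8)
        norm = norm_df(rng.uniform(0, 3, (4, 50)))
        s = directional_score(norm, ["g0", "g1", "g2"])
        assert s.mean() == pytest.approx(0.0, abs=1e-12)
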