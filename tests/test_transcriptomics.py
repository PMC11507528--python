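"""Differential expression, BH correction, and cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omixprox as ox
from omixprox.pipeline import _Study


def _study_from_matrix(matrix, case="case", control="control"):
    n = matrix.shape[1] // 2
    groups = pd.Series(
        [control] * n + [case] * (matrix.shape[1] - n), index=matrix.columns
    )
    return _Study(matrix, groups)


class TestDifferentialExpression:
    def test_identical_groups_give_zero_log2fc(self):
        rng = np.random.default_rng(0)
        block = rng.normal(8, 1, size=(10, 3))
        matrix = pd.DataFrame(
            np.hstack([block, block]),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        de = ox.differential_expression(_study_from_matrix(matrix), "case")
        assert np.allclose(de["log2fc"], 0)

    def test_p_matches_scipy_welch_oracle(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(
            rng.normal(8, 1, size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(6)],
        )
        de = ox.differential_expression(_study_from_matrix(matrix), "case")
        for i in range(5):
            oracle = stats.ttest_ind(
                matrix.iloc[i, 3:], matrix.iloc[i, :3], equal_var=False
            )
            assert de.loc[i, "p"] == pytest.approx(oracle.pvalue, rel=1e-9)

    def test_planted_genes_have_largest_fold_changes(self, small_study):
        de = ox.differential_expression(small_study, "GOLD4")
        top = set(
            de.reindex(de["log2fc"].abs().sort_values(ascending=False).index)
            .head(18)["gene"]
        )
        planted = set(
            small_study.truth.index[small_study.truth["status"] != "null"]
        )
        assert top == planted

    def test_zero_variance_gene_warns_but_computes(self):
        matrix = pd.DataFrame(
            [[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]], index=["g0"],
            columns=[f"s{i}" for i in range(6)],
        )
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            de = ox.differential_expression(_study_from_matrix(matrix), "case")
        assert np.isfinite(de.loc[0, "p"]) and de.loc[0, "p"] < 1e-6

    def test_group_with_single_sample_raises(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["g0"], columns=["a", "b", "c"]
        )
        study = _Study(matrix, pd.Series(
            ["control", "control", "case"], index=["a", "b", "c"]
        ))
        with pytest.raises(ValueError, match=">= 2 samples"):
            ox.differential_expression(study, "case")


class TestBHAdjust:
    def test_equal_ps_stay_equal(self):
        assert np.allclose(ox.bh_adjust([0.2] * 5), 0.2)

    def test_step_up_recursion_by_hand(self):
        # p*(m/rank) = (.04,.04,.04,.04); cumulative min from the right: all .04
        assert np.allclose(
            ox.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        assert ox.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_hand_rolled_step_up(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1].clip(max=1)
        oracle = np.empty(m)
        oracle[order] = adj_sorted
        assert np.allclose(ox.bh_adjust(p), oracle)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        assert np.allclose(ox.bh_adjust(p)[perm], ox.bh_adjust(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ox.bh_adjust([0.5, 1.5])


class TestClassifyDegs:
    @pytest.mark.parametrize(
        "adj_p,log2fc,expected",
        [(0.04, 1.2, "up"), (0.04, 0.9, "ns"), (0.04, -1.2, "down"),
         (0.06, 1.2, "ns"), (0.04, 1.0, "up")],
    )
    def test_threshold_boundaries(self, adj_p, log2fc, expected):
        df = pd.DataFrame(
            {"gene": ["g"], "log2fc": [log2fc], "p": [adj_p], "adj_p": [adj_p]}
        )
        ox.classify_degs(df)
        assert df.loc[0, "status"] == expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "gene": [f"g{i}" for i in range(200)],
            "log2fc": rng.normal(0, 1.5, 200),
            "p": rng.uniform(size=200),
        })
        df["adj_p"] = df["p"]
        base = ox.classify_degs(df.copy()).deg_set
        assert ox.classify_degs(df.copy(), alpha=0.01).deg_set <= base
        assert ox.classify_degs(df.copy(), lfc_threshold=2.0).deg_set <= base

    def test_counts_match_set_size(self, small_study):
        de = ox.differential_expression(small_study, "GOLD4")
        de["adj_p"] = ox.bh_adjust(de["p"])
        s = ox.classify_degs(de, stage="GOLD4")
        assert s.n_up + s.n_down == len(s.deg_set)


class TestStageOverlap:
    @staticmethod
    def _summary(stage, up=(), down=()):
        return ox.StageSummary(
            stage=stage, n_up=len(up), n_down=len(down),
            deg_set=set(up) | set(down), up_set=set(up), down_set=set(down),
        )

    def test_gene_up_everywhere_is_consistent(self):
        t = ox.stage_overlap(
            [self._summary(f"GOLD{i}", up=["SPP1"]) for i in range(1, 5)]
        )
        assert t.loc["SPP1", "consistent"] == "up"
        assert not t.loc["SPP1", "status_change"]

    def test_disjoint_stages_have_no_consistent_genes(self):
        t = ox.stage_overlap(
            [self._summary("GOLD1", up=["A"]), self._summary("GOLD2", up=["B"])]
        )
        assert (t["consistent"] == "").all()

    def test_single_shared_gene_counted_once(self):
        t = ox.stage_overlap([
            self._summary("GOLD2", up=["A", "X"]),
            self._summary("GOLD3", up=["A", "Y"]),
            self._summary("GOLD4", down=["Z"]),
        ])
        assert (t["n_stages"] >= 2).sum() == 1
        assert t.loc["A", "consistent"] == "up"

    def test_flip_flags_status_change(self):
        t = ox.stage_overlap([
            self._summary("GOLD3", up=["A"]), self._summary("GOLD4", down=["A"]),
        ])
        assert t.loc["A", "status_change"] and t.loc["A", "consistent"] == ""


class TestHypergeometricOverlap:
    def test_full_overlap_of_universe_is_certain(self):
        u = {f"g{i}" for i in range(10)}
        assert ox.hypergeometric_overlap(u, u, u) == pytest.approx(1.0)

    def test_exact_enumeration_small_case(self):
        u = {f"g{i}" for i in range(10)}
        a = {"g0", "g1", "g2"}
        assert ox.hypergeometric_overlap(a, a, u) == pytest.approx(1 / 120)

    def test_no_overlap_is_unremarkable(self):
        u = {f"g{i}" for i in range(1000)}
        assert ox.hypergeometric_overlap(
            {"g0", "g1"}, {"g10", "g11"}, u
        ) > 0.99

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            ox.hypergeometric_overlap(set(), set(), set())


class TestContingencyChiSquare:
    def test_proportional_table_has_zero_statistic(self):
        stat, df, p = ox.contingency_chi_square([[10, 20], [30, 60]])
        assert stat == pytest.approx(0) and p == pytest.approx(1)

    def test_diagonal_two_by_two_by_hand(self):
        stat, df, p = ox.contingency_chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20) and df == 1

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            ox.contingency_chi_square([[0, 0], [3, 4]])


class TestAnovaFromSummary:
    def test_equal_means_give_zero_f(self):
        f, *_, p = ox.anova_from_summary([5, 5, 5], [1, 1, 1], [10, 10, 10])
        assert f == pytest.approx(0) and p == pytest.approx(1)

    def test_two_groups_equal_pooled_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1.2, 15)
        f, _, _, p_f = ox.anova_from_summary(
            [a.mean(), b.mean()], [a.std(ddof=1), b.std(ddof=1)],
            [len(a), len(b)],
        )
        t = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t.statistic**2, rel=1e-10)
        assert p_f == pytest.approx(t.pvalue, rel=1e-10)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            ox.anova_from_summary([1, 2], [1], [5, 5])


def test_null_p_values_are_uniform():
    """With no planted effect, DE p values should be ~U(0,1)."""
    study = ox.gen_expression(2000, 10, 0, 0, sigma=0.5, seed=13)
    de = ox.differential_expression(study, "GOLD4")
    ks = stats.kstest(de["p"], "uniform")
    assert ks.pvalue > 0.01
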