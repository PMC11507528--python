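"""Druggability annotation, drug joining, and connectivity scoring."""

import math

import numpy as np
import pandas as pd
import pytest

import omixprox as ox


class TestAnnotateDruggability:
    def test_empty_table_gives_all_tier_none(self):
        records, counts = ox.annotate_druggability(
            {"A", "B"}, pd.DataFrame(columns=["gene", "tier"])
        )
        assert all(r.tier == "none" for r in records)
        assert counts == {"1": 0, "2": 0, "3": 0, "none": 2}

    def test_toy_tier_counts(self):
        table = pd.DataFrame(
            {"gene": ["A", "B", "C"], "tier": ["1", "1", "2"]}
        )
        _, counts = ox.annotate_druggability(
            {"A", "B", "C", "D", "E"}, table
        )
        assert counts == {"1": 2, "2": 1, "3": 0, "none": 2}

    def test_malformed_tier_rejected(self):
        table = pd.DataFrame({"gene": ["A"], "tier": ["platinum"]})
        with pytest.raises(ValueError, match="tier"):
            ox.annotate_druggability({"A"}, table)


class TestMapDrugs:
    TABLE = pd.DataFrame({
        "drug_id": ["D1", "D1", "D2", "D2"],
        "drug_name": ["aspirin", "aspirin", "ibuprofen", "ibuprofen"],
        "gene": ["PTGS1", "PTGS2", "PTGS2", "PTGS2"],
    })

    def test_no_overlap_yields_empty_join(self):
        assert len(ox.map_drugs({"SPP1"}, self.TABLE)) == 0

    def test_shared_drug_counted_once(self):
        hits = ox.map_drugs({"PTGS1", "PTGS2"}, self.TABLE)
        assert hits["drug_id"].nunique() == 2
        # duplicate (D2, PTGS2) rows collapse
        assert len(hits) == 3

    def test_hand_joined_result(self):
        hits = ox.map_drugs({"PTGS2"}, self.TABLE)
        assert set(map(tuple, hits[["drug_id", "gene"]].values)) == {
            ("D1", "PTGS2"), ("D2", "PTGS2")
        }


class TestWeightedKsEs:
    def test_query_at_top_scores_plus_one(self):
        ranking = [f"g{i}" for i in range(20)]
        assert ox.weighted_ks_es(ranking, set(ranking[:4])) == pytest.approx(1)

    def test_query_at_bottom_scores_minus_one(self):
        ranking = [f"g{i}" for i in range(20)]
        assert ox.weighted_ks_es(ranking, set(ranking[-4:])) == pytest.approx(-1)

    def test_matches_brute_force_running_sum(self):
        # 10-gene universe, query at ranks 1, 2, 7
        ranking = [f"g{i}" for i in range(1, 11)]
        query = {"g1", "g2", "g7"}
        running, dev = 0.0, []
        for g in ranking:
            running += 1 / 3 if g in query else -1 / 7
            dev.append(running)
        expected = max(dev, key=abs)
        assert ox.weighted_ks_es(ranking, query) == pytest.approx(expected)

    def test_antisymmetric_under_ranking_reversal(self):
        rng = np.random.default_rng(21)
        ranking = [str(g) for g in rng.permutation([f"g{i}" for i in range(50)])]
        query = set(rng.choice(ranking, 7, replace=False))
        assert ox.weighted_ks_es(ranking[::-1], query) == pytest.approx(
            -ox.weighted_ks_es(ranking, query)
        )

    def test_missing_query_gene_listed_in_error(self):
        with pytest.raises(ValueError, match="ZZZ"):
            ox.weighted_ks_es(["a", "b"], {"ZZZ"})


class TestWtcs:
    def test_opposite_extremes_score_one(self):
        ranking = [f"g{i}" for i in range(10)]
        assert ox.wtcs(ranking, set(ranking[:2]), set(ranking[-2:])) == \
            pytest.approx(1)

    def test_same_sign_enrichment_scores_zero(self):
        # both query sets at the top: incoherent signature, score 0
        ranking = [f"g{i}" for i in range(20)]
        assert ox.wtcs(ranking, set(ranking[:3]), set(ranking[3:6])) == 0

    def test_swapping_up_and_down_negates(self):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(60)]
        ranking = [str(g) for g in rng.permutation(genes)]
        up, down = set(genes[:6]), set(genes[6:12])
        assert ox.wtcs(ranking, down, up) == pytest.approx(
            -ox.wtcs(ranking, up, down)
        )

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ox.wtcs(["a", "b", "c"], {"a"}, {"a", "b"})


class TestPercentileNormalize:
    def test_value_above_every_null_scores_100(self):
        nulls = list(np.linspace(-0.3, 0.3, 200))
        pct, flag = ox.percentile_normalize(0.9, nulls, set(), set())
        assert pct == pytest.approx(100) and flag == "positive"

    def test_zero_wtcs_is_unflagged(self):
        nulls = list(np.linspace(-0.3, 0.3, 200))
        pct, flag = ox.percentile_normalize(0.0, nulls, set(), set())
        assert pct == 0 and flag == "none"

    def test_negative_value_gets_negative_percentile(self):
        nulls = list(np.linspace(-0.1, 0.1, 200))
        pct, flag = ox.percentile_normalize(-0.8, nulls, set(), set())
        assert pct == pytest.approx(-100) and flag == "negative"

    def test_too_few_nulls_rejected(self):
        with pytest.raises(ValueError, match="null"):
            ox.percentile_normalize(0.5, [0.1] * 50, set(), set())

    def test_monotone_in_absolute_wtcs(self):
        rng = np.random.default_rng(31)
        nulls = list(rng.normal(0, 0.2, 500))
        pcts = [
            ox.percentile_normalize(w, nulls, set(), set())[0]
            for w in np.linspace(0.01, 0.9, 15)
        ]
        assert all(b >= a for a, b in zip(pcts, pcts[1:]))


class TestConnectivityScores:
    def test_planted_signs_recovered_with_flags(self):
        up = [f"U{i}" for i in range(12)]
        down = [f"D{i}" for i in range(8)]
        profiles = ox.gen_perturbation_profiles(
            3, 200, ["positive", "negative", "null"], seed=9,
            query_up=up, query_down=down,
        )
        results = ox.connectivity_scores(profiles, up, down, n_null=300,
                                         seed=9)
        assert results[0].wtcs > 0 and results[0].flag == "positive"
        assert results[1].wtcs < 0 and results[1].flag == "negative"
        assert results[0].percentile > 90 and results[1].percentile < -90


class TestGoOverrepresentation:
    UNIVERSE = {f"g{i}" for i in range(50)}

    def test_term_equal_to_query_is_most_enriched(self):
        query = {"g0", "g1", "g2", "g3"}
        terms = {"hit": set(query), "other": {f"g{i}" for i in range(10, 30)}}
        table = ox.go_overrepresentation(query, terms, self.UNIVERSE)
        assert table.loc[0, "term"] == "hit"
        # maximal enrichment: upper tail of a complete overlap
        expected = 1 / math.comb(50, 4)
        assert table.loc[0, "p"] == pytest.approx(expected)

    def test_disjoint_term_not_reported(self):
        query = {"g0", "g1"}
        terms = {"hit": {"g0", "g1"}, "miss": {"g40", "g41", "g42"}}
        table = ox.go_overrepresentation(query, terms, self.UNIVERSE)
        assert "miss" not in set(table["term"])

    def test_p_values_match_exact_enumeration(self):
        query = {"g0", "g1", "g2"}
        terms = {
            "t1": {"g0", "g1", "g5"},
            "t2": {"g0", "g10", "g11", "g12"},
            "t3": {"g20", "g21"},
        }
        table = ox.go_overrepresentation(query, terms, self.UNIVERSE,
                                         alpha=1.1).set_index("term")

        def exact_p(members):
            # P(overlap >= k) by direct enumeration over the term size
            n, K, N = len(query), len(members), len(self.UNIVERSE)
            k_obs = len(query & members)
            total = math.comb(N, K)
            return sum(
                math.comb(n, k) * math.comb(N - n, K - k)
                for k in range(k_obs, min(n, K) + 1)
            ) / total

        for name, members in terms.items():
            assert table.loc[name, "p"] == pytest.approx(exact_p(members))
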