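import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ervcoex import (
    DataError,
    GeneSetCollection,
    GseaConfig,
    RankedGeneList,
    adjust_bh,
    build_ranked_list,
    enrichment_score,
    normalize_es,
    permutation_pvalues,
    run_gsea,
    storey_qvalues,
)
from ervcoex.correlation import CorrelationTable


def _corr_table(r_of: dict[str, float]) -> CorrelationTable:
    frame = pd.DataFrame(
        {
            "gene_id": list(r_of),
            "r": list(r_of.values()),
            "t": np.nan,
            "p": np.nan,
            "n": 7,
        }
    )
    return CorrelationTable("old", "T", frame)


class TestBuildRankedList:
    def test_descending_by_signed_score(self):
        ranked = build_ranked_list(_corr_table({"a": 0.5, "b": 0.9, "c": -0.2}))
        assert ranked.gene_ids == ("b", "a", "c")

    def test_ties_lexicographic_and_stable(self):
        for _ in range(3):
            ranked = build_ranked_list(_corr_table({"z": 0.5, "a": 0.5, "m": 0.5}))
            assert ranked.gene_ids == ("a", "m", "z")

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(6)
        r_of = {f"g{i:03d}": float(rng.uniform(-1, 1)) for i in range(100)}
        ranked = build_ranked_list(_corr_table(r_of))
        expected = tuple(
            g for g, _ in sorted(r_of.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        assert ranked.gene_ids == expected

    def test_undefined_scores_excluded(self):
        table = _corr_table({"a": 0.2, "b": 0.1})
        table.frame.loc[1, "r"] = np.nan
        assert build_ranked_list(table).gene_ids == ("a",)


class TestEnrichmentScore:
    def test_pure_prefix_gives_plus_one(self, worked_ranked_list):
        es, _, _, edge = enrichment_score(worked_ranked_list, {"g1", "g2"})
        assert es == pytest.approx(1.0)
        assert edge == ["g1", "g2"]

    def test_pure_suffix_gives_minus_one(self, worked_ranked_list):
        es, running, peak, edge = enrichment_score(worked_ranked_list, {"g4", "g5"})
        assert es == pytest.approx(-1.0)
        assert peak == 2  # trough just before the first member
        assert edge == ["g4", "g5"]

    def test_hand_walked_running_sum(self, worked_ranked_list):
        es, running, peak, edge = enrichment_score(worked_ranked_list, {"g1", "g3"})
        np.testing.assert_allclose(
            running, [0.75, 0.75 - 1 / 3, 2 / 3, 1 / 3, 0.0], atol=1e-12
        )
        assert es == pytest.approx(0.75)
        assert peak == 0
        assert edge == ["g1"]

    def test_degenerate_sets_rejected(self, worked_ranked_list):
        with pytest.raises(DataError):
            enrichment_score(worked_ranked_list, {"absent"})
        with pytest.raises(DataError):
            enrichment_score(
                worked_ranked_list, {"g1", "g2", "g3", "g4", "g5"}
            )

    def test_es_bounded(self):
        rng = np.random.default_rng(12)
        scores = np.sort(rng.normal(size=60))[::-1]
        ranked = RankedGeneList(tuple(f"g{i}" for i in range(60)), scores)
        for size in (1, 5, 20, 59):
            members = {f"g{i}" for i in rng.choice(60, size, replace=False)}
            es, _, _, _ = enrichment_score(ranked, members)
            assert -1.0 <= es <= 1.0

    def test_reversal_negates_es(self):
        rng = np.random.default_rng(13)
        scores = np.sort(rng.normal(size=40))[::-1]
        ids = tuple(f"g{i}" for i in range(40))
        ranked = RankedGeneList(ids, scores)
        flipped = RankedGeneList(tuple(reversed(ids)), -scores[::-1])
        for size in (3, 10):
            members = {f"g{i}" for i in rng.choice(40, size, replace=False)}
            es_f, _, _, _ = enrichment_score(ranked, members)
            es_r, _, _, _ = enrichment_score(flipped, members)
            assert es_r == pytest.approx(-es_f, abs=1e-12)

    def test_agrees_with_gseapy(self):
        """Independent cross-check against the gseapy prerank statistic."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(7)
        genes = [f"g{i:03d}" for i in range(300)]
        scores = np.sort(rng.normal(size=300))[::-1]
        sets = {
            "A": genes[5:40],
            "B": [genes[i] for i in rng.choice(300, 30, replace=False)],
            "C": genes[-40:],
        }
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": scores}),
            gene_sets=sets,
            permutation_num=10,
            min_size=5,
            max_size=200,
            seed=1,
            outdir=None,
            no_plot=True,
            weight=1.0,
        ).res2d.set_index("Term")
        ranked = RankedGeneList(tuple(genes), scores)
        for term, members in sets.items():
            es, _, _, _ = enrichment_score(ranked, set(members))
            assert es == pytest.approx(float(res.loc[term, "ES"]), abs=1e-9)


class TestPermutationPvalues:
    def test_monte_carlo_matches_exhaustive_enumeration(self, worked_ranked_list):
        """All C(5,2)=10 placements enumerate the exact null; the pooled
        Monte-Carlo p must land within 3 binomial SE of it."""
        es_null = []
        for pos in itertools.combinations(range(5), 2):
            members = {worked_ranked_list.gene_ids[i] for i in pos}
            es_null.append(enrichment_score(worked_ranked_list, members)[0])
        es_null = np.array(es_null)
        exact_pooled = (es_null >= 1.0).mean()
        assert exact_pooled == pytest.approx(0.1)
        exact_signed = (es_null >= 1.0).sum() / (es_null >= 0).sum()

        sets = GeneSetCollection.from_dict({"S": ["g1", "g2"]})
        config = GseaConfig(n_perm=10_000, min_size=1, seed=3)
        out = permutation_pvalues(worked_ranked_list, sets, config).iloc[0]
        se = np.sqrt(exact_pooled * (1 - exact_pooled) / 10_000)
        assert abs(out["pvalue_pooled"] - exact_pooled) < 3 * se
        se_s = np.sqrt(exact_signed * (1 - exact_signed) / 10_000)
        assert abs(out["pvalue"] - exact_signed) < 4 * se_s

    def test_smoothing_floor(self, worked_ranked_list):
        """An observed ES exceeding every null draw hits the add-one floor."""
        # members occupying the exact top of the list with huge scores
        ranked = RankedGeneList(
            tuple(f"g{i}" for i in range(12)),
            np.array([100.0, 99.0] + [1 - 0.01 * i for i in range(10)]),
        )
        sets = GeneSetCollection.from_dict({"S": ["g0", "g1"]})
        out = permutation_pvalues(
            ranked, sets, GseaConfig(n_perm=200, min_size=1, seed=0)
        ).iloc[0]
        assert out["pvalue_pooled"] >= 1 / 201
        assert out["pvalue"] >= out["pvalue_pooled"]

    def test_same_seed_is_bit_identical(self, worked_ranked_list):
        sets = GeneSetCollection.from_dict({"S": ["g1", "g3"]})
        config = GseaConfig(n_perm=500, min_size=1, seed=42)
        a = permutation_pvalues(worked_ranked_list, sets, config)
        b = permutation_pvalues(worked_ranked_list, sets, config)
        pd.testing.assert_frame_equal(a, b)


class TestNormalizeEs:
    def test_null_mean_equal_to_es_gives_one(self):
        assert normalize_es(0.4, 0.4, 0.3) == pytest.approx(1.0)

    def test_zero_es_is_zero(self):
        assert normalize_es(0.0, 0.5, 0.5) == 0.0

    def test_missing_same_sign_null_flagged_nan(self):
        assert np.isnan(normalize_es(-0.4, 0.5, np.nan))

    def test_enumerable_toy_ratio(self, worked_ranked_list):
        es_null = []
        for pos in itertools.combinations(range(5), 2):
            members = {worked_ranked_list.gene_ids[i] for i in pos}
            es_null.append(enrichment_score(worked_ranked_list, members)[0])
        es_null = np.array(es_null)
        pos_mean = es_null[es_null > 0].mean()
        assert normalize_es(0.75, pos_mean, np.nan) == pytest.approx(0.75 / pos_mean)


class TestMultiplicity:
    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_sorted_input_gives_monotone_output(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(size=30))
        out = adjust_bh(p)
        assert np.all(np.diff(out) >= -1e-15)
        assert np.all(out <= 1.0)
        assert np.all(out >= p)

    def test_bh_permutation_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))

    def test_invalid_p_rejected(self):
        with pytest.raises(DataError):
            adjust_bh([0.1, 1.5])

    def test_q_equals_bh_when_pi0_caps(self):
        p = np.array([0.1, 0.6, 0.9])  # pi0_hat = 2/1.5 > 1 -> capped
        np.testing.assert_allclose(storey_qvalues(p), adjust_bh(p))

    def test_pi0_floor_when_all_p_small(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(storey_qvalues(p), adjust_bh(p) / 4)

    def test_matches_direct_formula_on_uniform_draw(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=20)
        m = 20
        pi0 = min(1.0, max(1 / m, (p > 0.5).sum() / (0.5 * m)))
        np.testing.assert_allclose(storey_qvalues(p), pi0 * adjust_bh(p))

    @settings(deadline=None, max_examples=40)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    def test_q_le_bh_elementwise(self, p):
        assert np.all(storey_qvalues(p) <= adjust_bh(p) + 1e-15)


class TestRunGsea:
    def test_no_qualifying_set_gives_empty_table(self, worked_ranked_list):
        sets = GeneSetCollection.from_dict({"S": ["g1"]})
        out = run_gsea(worked_ranked_list, sets, GseaConfig(n_perm=10, min_size=3))
        assert out.empty

    def test_duplicate_sets_get_identical_rows(self):
        rng = np.random.default_rng(21)
        ids = tuple(f"g{i:03d}" for i in range(200))
        scores = np.sort(rng.normal(size=200))[::-1]
        ranked = RankedGeneList(ids, scores)
        members = [ids[i] for i in rng.choice(200, 30, replace=False)]
        sets = GeneSetCollection.from_dict({"A": members, "B": members})
        out = run_gsea(ranked, sets, GseaConfig(n_perm=500, min_size=5, seed=9))
        a = out[out["ID"] == "A"].iloc[0]
        b = out[out["ID"] == "B"].iloc[0]
        assert a["es"] == b["es"] and a["pvalue"] == b["pvalue"]

    def test_planted_set_recovered_on_top(self):
        """A set occupying the top of the list dominates the table."""
        rng = np.random.default_rng(30)
        ids = tuple(f"g{i:03d}" for i in range(400))
        scores = np.sort(rng.normal(size=400))[::-1] + np.linspace(2, 0, 400)
        ranked = RankedGeneList(ids, np.sort(scores)[::-1])
        planted = list(ids[:30])
        sets = {"PLANTED": planted}
        for k in range(8):
            sets[f"R{k}"] = [ids[i] for i in rng.choice(400, 30, replace=False)]
        out = run_gsea(
            ranked,
            GeneSetCollection.from_dict(sets),
            GseaConfig(n_perm=10_000, min_size=5, seed=2),
        )
        assert out.iloc[0]["ID"] == "PLANTED"
        assert out.iloc[0]["pvalue"] == pytest.approx(
            out["pvalue"].min()
        )
        assert out.iloc[0]["nes"] > 0
        assert out.iloc[0]["pvalue"] <= 2 / 10_000 + 1e-9

    def test_gene_ratio_consistency(self):
        rng = np.random.default_rng(31)
        ids = tuple(f"g{i:03d}" for i in range(150))
        ranked = RankedGeneList(ids, np.sort(rng.normal(size=150))[::-1])
        sets = GeneSetCollection.from_dict(
            {"A": [ids[i] for i in rng.choice(150, 25, replace=False)]}
        )
        out = run_gsea(ranked, sets, GseaConfig(n_perm=100, min_size=5, seed=4))
        row = out.iloc[0]
        n_edge = 0 if row["leading_edge"] == "" else len(row["leading_edge"].split(","))
        assert row["gene_ratio"] == pytest.approx(n_edge / row["set_size"])
        assert np.sign(row["nes"]) == np.sign(row["es"]) or row["es"] == 0
        assert row["p_adjust"] >= row["pvalue"]
        assert row["qvalue"] <= row["p_adjust"] + 1e-15
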