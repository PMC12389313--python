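"""Greedy recommendation scoring against an exhaustive brute-force oracle."""

import itertools
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grdc.io_model import DrugGeneMap, RiskLevel, RiskTable
from grdc.recommender import (
    DEFAULT_PENALTIES,
    CandidateScore,
    PenaltyTable,
    RecommendationWeights,
    frequency_score,
    gene_overlap_score,
    jaccard_similarity,
    recommend_candidates,
    recommend_substitute,
    risk_penalty,
    total_score,
)


def brute_force_total(cand, combo, counter, genes, risks, w, p):
    """Independent re-derivation of the weighted candidate score."""
    freq = 0
    for k in (1, 2):
        for subset in itertools.combinations(sorted(combo), k):
            freq += counter.get(tuple(sorted({cand, *subset})), 0)
    gene = sum(len(genes.genes(cand) & genes.genes(d)) for d in combo)
    risk = sum(p[risks.get(cand, d)] for d in combo)
    return w.alpha_freq * freq + w.beta_gene * gene + w.gamma_risk * risk


class TestComponents:
    def test_frequency_single_pair(self):
        counter = Counter({("a", "c"): 7})
        assert frequency_score("c", {"a"}, counter) == 7

    def test_frequency_all_subsets(self):
        counter = Counter({("a", "c"): 3, ("b", "c"): 2, ("a", "b", "c"): 4})
        assert frequency_score("c", {"a", "b"}, counter) == 9

    def test_frequency_absent_candidate(self):
        assert frequency_score("z", {"a", "b"}, Counter({("a", "b"): 5})) == 0

    def test_frequency_rejects_candidate_in_combo(self):
        with pytest.raises(ValueError):
            frequency_score("a", {"a", "b"}, Counter())

    def test_gene_overlap_accumulates(self):
        genes = DrugGeneMap(
            {"c": {"G1", "G2", "G3", "G4"}, "a": {"G1", "G2"}, "b": {"G3", "G4"}}
        )
        assert gene_overlap_score("c", {"a"}, genes) == 2
        assert gene_overlap_score("c", {"a", "b"}, genes) == 4
        assert gene_overlap_score("x", {"a", "b"}, genes) == 0

    def test_risk_penalty_sums(self, toy_risks):
        # aspirin-warfarin High => -10; plus aspirin-prednisone Low => -11
        assert risk_penalty("aspirin", {"warfarin"}, toy_risks) == -10
        assert risk_penalty("aspirin", {"warfarin", "prednisone"}, toy_risks) == -11
        assert risk_penalty("gabapentin", {"warfarin"}, toy_risks) == 0  # unknown

    def test_penalty_table_invariants(self):
        with pytest.raises(ValueError):
            PenaltyTable({**DEFAULT_PENALTIES, RiskLevel.HIGH: -1.0})

    @pytest.mark.parametrize(
        "parts,expected",
        [((1, 0, 0), 1.0), ((0, 1, 0), 2.0), ((2, 3, -5), 3.0)],
    )
    def test_total_default_weights(self, parts, expected):
        assert total_score(parts) == pytest.approx(expected)


class TestJaccard:
    def test_identity_disjoint_partial(self):
        genes = DrugGeneMap(
            {"a": {"G1", "G2"}, "b": {"G1", "G2"}, "c": {"G3"}, "d": {"G1", "G3", "G4"}}
        )
        assert jaccard_similarity("a", "b", genes) == 1.0
        assert jaccard_similarity("a", "c", genes) == 0.0
        assert jaccard_similarity("a", "d", genes) == pytest.approx(0.25)

    def test_both_empty_defined_zero(self):
        assert jaccard_similarity("x", "y", DrugGeneMap()) == 0.0

    def test_symmetric(self, toy_genes):
        assert jaccard_similarity("aspirin", "prednisone", toy_genes) == pytest.approx(
            jaccard_similarity("prednisone", "aspirin", toy_genes)
        )


class TestRecommendCandidates:
    def test_single_candidate_pool_gets_100(self, toy_genes, toy_risks):
        out = recommend_candidates(
            {"aspirin"}, {"aspirin", "gabapentin"}, Counter(), toy_genes, toy_risks
        )
        assert [c.candidate for c in out] == ["gabapentin"]
        assert out[0].normalized_score == 100

    def test_frequency_monotonicity(self):
        counter = Counter({("a", "x"): 5, ("a", "y"): 3})
        out = recommend_candidates(
            {"a"}, {"x", "y"}, counter, DrugGeneMap(), RiskTable()
        )
        assert [c.candidate for c in out] == ["x", "y"]
        assert out[0].normalized_score == 100 and out[1].normalized_score == 0

    def test_empty_universe(self):
        assert recommend_candidates({"a"}, {"a"}, Counter(), DrugGeneMap(), RiskTable()) == []

    def test_total_recomputable_from_parts(self, toy_genes, toy_risks, toy_admissions):
        from grdc.freq_mining import count_combination_frequencies

        counter = count_combination_frequencies(toy_admissions)
        w = RecommendationWeights()
        out = recommend_candidates(
            {"aspirin", "warfarin"},
            {"aspirin", "warfarin", "heparin", "prednisone", "gabapentin"},
            counter, toy_genes, toy_risks, w=w, k=None,
        )
        for c in out:
            assert c.total == pytest.approx(
                w.alpha_freq * c.frequency_score
                + w.beta_gene * c.gene_overlap
                + w.gamma_risk * c.risk_penalty
            )

    @given(
        combos=st.lists(
            st.sets(st.sampled_from("abcdefgh"), min_size=1, max_size=4),
            min_size=1, max_size=8,
        ),
        input_combo=st.sets(st.sampled_from("abc"), min_size=1, max_size=3),
        gene_assign=st.dictionaries(
            st.sampled_from("abcdefgh"),
            st.sets(st.sampled_from(["G1", "G2", "G3", "G4"]), max_size=4),
            max_size=8,
        ),
        risk_entries=st.lists(
            st.tuples(
                st.sampled_from("abcdefgh"), st.sampled_from("abcdefgh"),
                st.sampled_from(list(RiskLevel)),
            ),
            max_size=10,
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_ranking_matches_brute_force(self, combos, input_combo, gene_assign, risk_entries):
        counter = Counter(tuple(sorted(c)) for c in combos)
        genes = DrugGeneMap(gene_assign)
        risks = RiskTable()
        for a, b, lv in risk_entries:
            if a != b:
                risks.set(a, b, lv)
        universe = set("abcdefgh")
        w, p = RecommendationWeights(), PenaltyTable()
        out = recommend_candidates(input_combo, universe, counter, genes, risks, w, p, k=None)
        expected = sorted(
            (
                (-brute_force_total(c, input_combo, counter, genes, risks, w, p), c)
                for c in universe - input_combo
            ),
        )
        assert [c.candidate for c in out] == [c for _, c in expected]
        for c in out:
            assert c.total == pytest.approx(
                brute_force_total(c.candidate, input_combo, counter, genes, risks, w, p)
            )

    def test_normalized_score_affine_invariant(self, toy_genes, toy_risks):
        counter = Counter({("a", "x"): 5, ("a", "y"): 3, ("a", "z"): 1})
        base = recommend_candidates({"a"}, {"x", "y", "z"}, counter, DrugGeneMap(), RiskTable(), k=None)
        # scaling all frequencies by 10 is an affine map of the totals
        scaled_counter = Counter({k: 10 * v for k, v in counter.items()})
        scaled = recommend_candidates({"a"}, {"x", "y", "z"}, scaled_counter, DrugGeneMap(), RiskTable(), k=None)
        assert [c.normalized_score for c in base] == [c.normalized_score for c in scaled]


class TestRecommendSubstitute:
    def test_planted_low_risk_substitute_recovered(self):
        # one candidate shares 7 genes with the risky drug and is Low-risk
        # toward the context; the risky drug is Moderate toward it
        genes = DrugGeneMap(
            {
                "risky": {f"G{i}" for i in range(10)},
                "good": {f"G{i}" for i in range(7)} | {"X1", "X2", "X3"},
                "bad": {"Y1"},
                "ctx": {"Z1"},
            }
        )
        risks = RiskTable()
        risks.set("risky", "ctx", RiskLevel.MODERATE)
        risks.set("good", "ctx", RiskLevel.LOW)
        risks.set("bad", "ctx", RiskLevel.HIGH)
        out = recommend_substitute(
            "risky", {"risky", "ctx"}, Counter(), genes, risks,
            universe={"risky", "ctx", "good", "bad"},
        )
        assert [c.candidate for c in out] == ["good"]
        assert out[0].shared_genes == 7
        assert out[0].similarity == pytest.approx(7 / 13)
        assert out[0].substitute_risk is RiskLevel.LOW

    def test_all_candidates_worse_gives_empty(self):
        risks = RiskTable()
        risks.set("risky", "ctx", RiskLevel.LOW)
        risks.set("cand", "ctx", RiskLevel.HIGH)
        out = recommend_substitute(
            "risky", {"risky", "ctx"}, Counter(), DrugGeneMap(), risks,
            universe={"risky", "ctx", "cand"},
        )
        assert out == []

    def test_risky_drug_must_be_in_combo(self):
        with pytest.raises(ValueError):
            recommend_substitute("x", {"a", "b"}, Counter(), DrugGeneMap(), RiskTable())

    def test_substitute_never_riskier_property(self, toy_genes, toy_risks, toy_admissions):
        from grdc.freq_mining import count_combination_frequencies
        from grdc.recommender import _risk_toward

        counter = count_combination_frequencies(toy_admissions)
        combo = {"aspirin", "warfarin"}
        out = recommend_substitute(
            "warfarin", combo, counter, toy_genes, toy_risks, k=None
        )
        original = _risk_toward("warfarin", combo - {"warfarin"}, toy_risks)
        for c in out:
            assert c.substitute_risk.severity <= original.severity

    def test_ordering_matches_brute_force_on_filtered_pool(self, toy_risks):
        counter = Counter(
            {("ctx", "p"): 6, ("ctx", "q"): 2, ("ctx", "r"): 9}
        )
        genes = DrugGeneMap({"risky": {"G1"}, "p": {"G1"}, "q": {"G1"}, "r": set()})
        out = recommend_substitute(
            "risky", {"risky", "ctx"}, counter, genes, toy_risks,
            universe={"risky", "ctx", "p", "q", "r"},
        )
        w, p_tab = RecommendationWeights(), PenaltyTable()
        totals = {
            c: brute_force_total(c, {"ctx"}, counter, genes, toy_risks, w, p_tab)
            for c in ("p", "q", "r")
        }
        expected = sorted(totals, key=lambda c: (-totals[c], c))
        assert [c.candidate for c in out] == expected
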