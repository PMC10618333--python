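"""Pareto partition, stereoisomer enumeration, similarity, attention maps."""

import numpy as np
import pytest

from hitgen.fixtures import FixtureSpec, make_corpus
from hitgen.selection import (
    Solution,
    count_unassigned_stereocenters,
    enumerate_stereoisomers,
    pareto_front,
    pareto_front_bruteforce,
    rank_stereoisomers,
    similarity_report,
)


class TestParetoFront:
    def test_single_solution_is_front(self):
        s = Solution("CCO", 6.0, 2.0)
        front, dominated = pareto_front([s])
        assert front == [s] and dominated == []

    def test_strict_domination(self):
        a = Solution("a", 6.0, 2.0)
        b = Solution("b", 5.0, 3.0)
        front, dominated = pareto_front([a, b])
        assert front == [a] and dominated == [b]

    def test_ties_on_both_axes_both_retained(self):
        a = Solution("a", 6.0, 2.0)
        b = Solution("b", 6.0, 2.0)
        front, _ = pareto_front([a, b])
        assert len(front) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pareto_front([])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            Solution("x", float("nan"), 2.0)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for trial in range(100):
            n = int(rng.integers(1, 201))
            sols = [Solution(f"m{i}", float(rng.integers(0, 12)) / 2,
                             float(rng.integers(2, 14)) / 2)
                    for i in range(n)]
            fast_front, fast_dom = pareto_front(sols)
            slow_front, slow_dom = pareto_front_bruteforce(sols)
            assert {id(s) for s in fast_front} == {id(s) for s in slow_front}
            assert {id(s) for s in fast_dom} == {id(s) for s in slow_dom}


class TestStereoisomers:
    def test_no_stereocenters_single_entry(self):
        sset = enumerate_stereoisomers("CCO")
        assert sset.c == 0
        assert len(sset.isomers) == 1

    def test_two_independent_centers_give_four(self):
        sset = enumerate_stereoisomers("CC(N)C(O)CC(=O)O")  # 2 centers
        assert sset.c == 2
        assert len(sset.isomers) == 4

    @pytest.mark.parametrize("smiles,c", [
        ("CC(N)C(=O)O", 1),
        ("CC(N)C(O)CC", 2),
        ("CC(N)C(O)C(F)CC(=O)O", 3),
    ])
    def test_count_is_two_to_the_c(self, smiles, c):
        sset = enumerate_stereoisomers(smiles)
        assert sset.c == c
        assert len(sset.isomers) == 2 ** c

    def test_never_exceeds_bound_on_fixture_molecules(self):
        for s in make_corpus(FixtureSpec(n=120, seed=9)):
            sset = enumerate_stereoisomers(s)
            assert 1 <= len(sset.isomers) <= 2 ** max(sset.c, 0)

    def test_isomers_share_achiral_skeleton(self):
        from rdkit import Chem

        sset = enumerate_stereoisomers("CC(N)C(O)CC")
        skeletons = {Chem.MolToSmiles(Chem.MolFromSmiles(s),
                                      isomericSmiles=False)
                     for s in sset.isomers}
        assert len(skeletons) == 1

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            enumerate_stereoisomers("C(")

    def test_assigned_centers_not_reenumerated(self):
        c = count_unassigned_stereocenters("C[C@H](N)C(=O)O")
        assert c == 0


class TestRanking:
    def test_ranking_deterministic_and_best_is_argmax(self, toy_predictor):
        sset = enumerate_stereoisomers("CC(O)c1ccc(NC(=O)CN)cc1")
        ranked = rank_stereoisomers(sset, toy_predictor)
        assert ranked.best == 0
        assert ranked.pic50 == sorted(ranked.pic50, reverse=True)
        assert all(1 <= s <= 10 for s in ranked.sas)
        again = rank_stereoisomers(enumerate_stereoisomers(
            "CC(O)c1ccc(NC(=O)CN)cc1"), toy_predictor)
        assert again.isomers == ranked.isomers

    def test_parent_without_centers_trivially_best(self, toy_predictor):
        ranked = rank_stereoisomers(enumerate_stereoisomers("CCOc1ccccc1"),
                                    toy_predictor)
        assert len(ranked.isomers) == 1 and ranked.best == 0


class TestSimilarity:
    def test_identical_molecules(self):
        rep = similarity_report("CCO", "OCC")
        assert rep.t_s == 1.0
        assert rep.t_mcs == pytest.approx(1.0)

    def test_ethane_vs_benzene_atom_count_convention(self):
        rep = similarity_report("CC", "c1ccccc1")
        assert rep.t_mcs == pytest.approx(1 / 3)

    def test_symmetric(self):
        a, b = "CCN(C)C(=O)c1ccccc1", "CCOC(=O)c1ccc(N)cc1"
        r1 = similarity_report(a, b)
        r2 = similarity_report(b, a)
        assert r1.t_s == pytest.approx(r2.t_s)
        assert r1.t_mcs == pytest.approx(r2.t_mcs)

    def test_self_similarity_bound(self, small_corpus):
        for s in small_corpus[:5]:
            rep = similarity_report(s, s)
            assert rep.t_mcs == pytest.approx(1.0)
            assert rep.t_s == 1.0

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            similarity_report("C(", "CCO")


class TestAttentionAtomMap:
    def test_weights_sum_to_one(self, toy_predictor):
        from hitgen.selection import attention_atom_map

        out = attention_atom_map(toy_predictor, "CC(=O)Nc1ccc(Cl)cc1")
        assert np.isclose(sum(out["atom_weights"]), 1.0, atol=1e-6)
        assert len(out["atom_tokens"]) == len(out["atom_weights"])

    def test_single_heavy_atom_carries_all_weight(self, toy_predictor):
        from hitgen.selection import attention_atom_map

        out = attention_atom_map(toy_predictor, "C")
        assert out["atom_weights"] == [pytest.approx(1.0)]

    def test_non_attention_model_rejected(self):
        from hitgen.predictor import Pic50Predictor, PredictorConfig

        model = Pic50Predictor(config=PredictorConfig(
            configuration="H", embedding_dim=8, recurrent_units=8, max_len=20),
            seed=0)
        with pytest.raises(ValueError):
            model.attention_weights("CCO")
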