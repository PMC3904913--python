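import random

import pytest

from sempar.annotations import expand_set
from sempar.fixtures import FixtureSpec, figure1_fixture, random_dag
from sempar.informativeness import SemanticValueModel, from_table
from sempar.measures import (
    compare,
    lin_term_similarity,
    mica_informativeness,
    mica_term,
    most_informative_common_terms,
    most_particular_terms,
    particular_informativeness,
    particularity,
    set_similarity,
    wang_term_similarity,
)
from sempar.ontology import OntologyGraph

from .conftest import random_subset
from .oracles import brute_bma, brute_mct, brute_mica_info, brute_mpt, edge_map


@pytest.fixture(scope="module")
def fig():
    return figure1_fixture()


def sv_cases(n_cases, seed, n_terms=25):
    """(graph, model, s1, s2) instances over a few seeded random DAGs."""
    rng = random.Random(seed)
    graphs = [
        random_dag(FixtureSpec(n_terms=n_terms, max_parents=3, seed=seed + k))
        for k in range(4)
    ]
    models = [SemanticValueModel(g) for g in graphs]
    for _ in range(n_cases):
        k = rng.randrange(len(graphs))
        g = graphs[k]
        yield g, models[k], random_subset(g, rng), random_subset(g, rng)


class TestMostParticularTerms:
    def test_worked_example_hsa_dme(self, fig):
        assert most_particular_terms(fig.graph, fig.sg_hsa, fig.sg_dme) == {
            "tRNA binding"
        }

    def test_worked_example_hsa_rno(self, fig):
        assert most_particular_terms(fig.graph, fig.sg_hsa, fig.sg_rno) == {
            "protein binding"
        }

    def test_self_comparison_empty(self, fig):
        for s in (fig.sg_hsa, fig.sg_rno, fig.sg_dme):
            assert most_particular_terms(fig.graph, s, s) == set()

    def test_ancestor_in_direct_set_never_selected(self, chain_graph):
        # T:mid has a descendant (T:leaf) inside the direct set
        out = most_particular_terms(chain_graph, {"T:leaf", "T:mid"}, set())
        assert out == {"T:leaf"}

    def test_mixed_namespaces_rejected(self):
        g1 = OntologyGraph.build([("a", "r", "is_a")], namespace="ns1")
        g1.graph.add_node("x")
        g1.namespaces["x"] = "ns2"
        with pytest.raises(ValueError):
            most_particular_terms(g1, {"a"}, {"x"})

    def test_matches_bruteforce(self):
        for g, _m, s1, s2 in sv_cases(40, seed=100):
            parents = edge_map(g.graph)
            assert most_particular_terms(g, s1, s2) == brute_mpt(parents, s1, s2)

    def test_disjoint_from_sg2_star(self):
        for g, _m, s1, s2 in sv_cases(20, seed=101):
            mpt = most_particular_terms(g, s1, s2)
            assert not (mpt & expand_set(g, s2))


class TestMostInformativeCommonTerms:
    def test_worked_example(self, fig):
        assert most_informative_common_terms(fig.graph, fig.sg_hsa, fig.sg_dme) == {
            "protein transporter activity",
            "protein binding",
        }

    def test_worked_example_rno(self, fig):
        assert most_informative_common_terms(fig.graph, fig.sg_hsa, fig.sg_rno) == {
            "tRNA binding",
            "protein transporter activity",
        }

    def test_self_comparison_gives_deepest_terms(self, chain_graph):
        out = most_informative_common_terms(
            chain_graph, {"T:leaf", "T:mid"}, {"T:leaf", "T:mid"}
        )
        assert out == {"T:leaf"}

    def test_matches_bruteforce(self):
        for g, _m, s1, s2 in sv_cases(40, seed=102):
            parents = edge_map(g.graph)
            assert most_informative_common_terms(g, s1, s2) == brute_mct(
                parents, s1, s2
            )

    def test_subset_of_both_expansions_no_inner_descendants(self):
        for g, _m, s1, s2 in sv_cases(20, seed=103):
            s1_star, s2_star = expand_set(g, s1), expand_set(g, s2)
            mct = most_informative_common_terms(g, s1, s2)
            assert mct <= s1_star & s2_star
            for t in mct:
                assert not (g.descendants(t) & s1_star)
                assert not (g.descendants(t) & s2_star)


class TestMica:
    def test_worked_example_value(self, fig):
        # MICA of the single most-particular human term against drosophila
        assert mica_informativeness(
            fig.graph, fig.informativeness, "tRNA binding", fig.sg_dme
        ) == pytest.approx(1.8)

    def test_term_in_sg2_is_its_own_mica(self, fig):
        assert mica_informativeness(
            fig.graph, fig.informativeness, "protein binding", fig.sg_dme
        ) == pytest.approx(2.44)

    def test_empty_sg2_gives_zero(self, fig):
        assert (
            mica_informativeness(fig.graph, fig.informativeness, "tRNA binding", set())
            == 0.0
        )

    def test_mica_term_reported(self, fig):
        assert (
            mica_term(fig.graph, fig.informativeness, "tRNA binding", fig.sg_dme)
            == "binding"
        )
        assert mica_term(fig.graph, fig.informativeness, "tRNA binding", set()) is None

    def test_matches_bruteforce(self):
        rng = random.Random(104)
        for g, m, _s1, s2 in sv_cases(40, seed=104):
            t = rng.choice(sorted(g.terms))
            parents = edge_map(g.graph)
            assert mica_informativeness(g, m, t, s2) == pytest.approx(
                brute_mica_info(parents, m.value, t, s2)
            )


class TestParticularInformativeness:
    def test_worked_example_arithmetic(self, fig):
        # single most-particular term: I(tRNA binding) - I(binding)
        assert particular_informativeness(
            fig.graph, fig.informativeness, fig.sg_hsa, fig.sg_dme
        ) == pytest.approx(4.201 - 1.8)

    def test_self_comparison_zero(self, fig):
        assert (
            particular_informativeness(
                fig.graph, fig.informativeness, fig.sg_hsa, fig.sg_hsa
            )
            == 0.0
        )

    def test_empty_sg2_sums_full_informativeness(self, fig):
        pi = particular_informativeness(
            fig.graph, fig.informativeness, fig.sg_rno, set()
        )
        assert pi == pytest.approx(4.201 + 2.952)

    def test_nonnegative(self):
        for g, m, s1, s2 in sv_cases(30, seed=105):
            assert particular_informativeness(g, m, s1, s2) >= 0.0


class TestParticularity:
    def test_worked_example_hsa_dme(self, fig):
        par = particularity(fig.graph, fig.informativeness, fig.sg_hsa, fig.sg_dme)
        assert par == pytest.approx(0.308, abs=5e-4)

    def test_worked_example_hsa_rno(self, fig):
        par = particularity(fig.graph, fig.informativeness, fig.sg_hsa, fig.sg_rno)
        assert par == pytest.approx(0.082, abs=5e-4)

    def test_no_species_specific_terms_in_reverse(self, fig):
        assert particularity(fig.graph, fig.informativeness, fig.sg_dme, fig.sg_hsa) == 0.0
        assert particularity(fig.graph, fig.informativeness, fig.sg_rno, fig.sg_hsa) == 0.0

    def test_prop1_non_symmetric_witness(self, fig):
        par12 = particularity(fig.graph, fig.informativeness, fig.sg_hsa, fig.sg_dme)
        par21 = particularity(fig.graph, fig.informativeness, fig.sg_dme, fig.sg_hsa)
        assert par12 != par21

    def test_prop2_self_is_zero(self):
        for g, m, s1, _s2 in sv_cases(30, seed=106):
            assert particularity(g, m, s1, s1) == 0.0

    def test_prop3_empty_conventions(self):
        for g, m, s1, _s2 in sv_cases(30, seed=107):
            assert particularity(g, m, s1, set()) == 1.0
            assert particularity(g, m, set(), s1) == 0.0

    def test_both_empty_is_error(self, fig):
        with pytest.raises(ValueError):
            particularity(fig.graph, fig.informativeness, set(), set())

    def test_range(self):
        for g, m, s1, s2 in sv_cases(60, seed=108):
            assert 0.0 <= particularity(g, m, s1, s2) <= 1.0

    def test_prop4_invariance_under_disjoint_union(self):
        # s3 lives in a subtree whose expansion meets s1* only at the root
        found = 0
        rng = random.Random(109)
        for seed in range(40):
            g = random_dag(FixtureSpec(n_terms=30, max_parents=2, seed=500 + seed))
            m = SemanticValueModel(g)
            root = g.roots["toy"]
            s1 = random_subset(g, rng)
            s1_star = expand_set(g, s1)
            candidates = [
                t
                for t in sorted(g.terms)
                if expand_set(g, {t}) & s1_star <= {root} and t != root
            ]
            if not candidates:
                continue
            s3 = set(rng.sample(candidates, min(2, len(candidates))))
            s2 = random_subset(g, rng)
            par = particularity(g, m, s1, s2)
            par_union = particularity(g, m, s1, s2 | s3)
            assert par == pytest.approx(par_union, abs=1e-12)
            found += 1
        assert found >= 10

    def test_matches_raw_definition_oracle(self):
        from .oracles import brute_par

        for g, m, s1, s2 in sv_cases(30, seed=110):
            parents = edge_map(g.graph)
            assert particularity(g, m, s1, s2) == pytest.approx(
                brute_par(parents, m.value, s1, s2)
            )


class TestWangTermSimilarity:
    def test_identity(self, chain_graph):
        for t in chain_graph.terms:
            assert wang_term_similarity(chain_graph, t, t) == pytest.approx(1.0)

    def test_siblings_hand_enumeration(self):
        g = OntologyGraph.build(
            [("a", "p", "is_a"), ("b", "p", "is_a"), ("p", "r", "is_a")]
        )
        expected = (0.8 + 0.8 + 0.64 + 0.64) / (2.44 + 2.44)
        assert wang_term_similarity(g, "a", "b") == pytest.approx(expected)

    def test_leaves_sharing_only_root(self):
        g = OntologyGraph.build([("a", "r", "is_a"), ("b", "r", "is_a")])
        # shared ancestor set is {r}: (0.8 + 0.8) / (1.8 + 1.8)
        assert wang_term_similarity(g, "a", "b") == pytest.approx(1.6 / 3.6)

    def test_symmetric_and_bounded(self):
        g = random_dag(FixtureSpec(n_terms=20, max_parents=3, seed=15))
        terms = sorted(g.terms)
        rng = random.Random(15)
        for _ in range(30):
            a, b = rng.choice(terms), rng.choice(terms)
            s = wang_term_similarity(g, a, b)
            assert 0.0 <= s <= 1.0
            assert s == pytest.approx(wang_term_similarity(g, b, a))

    def test_unknown_term(self, chain_graph):
        with pytest.raises(KeyError):
            wang_term_similarity(chain_graph, "T:leaf", "T:ghost")


class TestLinTermSimilarity:
    def _corpus_model(self):
        from sempar.annotations import corpus_from_mapping
        from sempar.informativeness import InformationContentModel

        g = OntologyGraph.build(
            [("a", "r", "is_a"), ("b", "r", "is_a"), ("c", "a", "is_a")]
        )
        c = corpus_from_mapping(
            g, {"g1": {"c"}, "g2": {"b"}, "g3": {"a"}, "g4": {"r"}}
        )
        return g, InformationContentModel(c)

    def test_identity(self):
        g, ic = self._corpus_model()
        assert lin_term_similarity(g, ic, "c", "c") == pytest.approx(1.0)

    def test_disjoint_leaves_sharing_root_only(self):
        g, ic = self._corpus_model()
        # MICA is the root with IC 0
        assert lin_term_similarity(g, ic, "c", "b") == 0.0

    def test_root_with_itself(self):
        g, ic = self._corpus_model()
        assert lin_term_similarity(g, ic, "r", "r") == 1.0

    def test_closed_form(self):
        import math

        g, ic = self._corpus_model()
        # p(a)=0.5 (g1,g3), p(c)=0.25; MICA(c,a)=a
        expected = 2 * math.log(2) / (math.log(4) + math.log(2))
        assert lin_term_similarity(g, ic, "c", "a") == pytest.approx(expected)


class TestSetSimilarity:
    def test_identity_bma_and_max(self):
        for g, m, s1, _s2 in sv_cases(10, seed=111):
            assert set_similarity(g, m, s1, s1, combine="bma") == pytest.approx(1.0)
            assert set_similarity(g, m, s1, s1, combine="max") == pytest.approx(1.0)

    def test_empty_set_rejected(self, fig):
        with pytest.raises(ValueError):
            set_similarity(fig.graph, fig.informativeness, set(), fig.sg_hsa)

    def test_bma_matches_double_loop_oracle(self):
        for g, m, s1, s2 in sv_cases(30, seed=112):
            got = set_similarity(g, m, s1, s2, method="wang", combine="bma")
            want = brute_bma(lambda a, b: wang_term_similarity(g, a, b), sorted(s1), sorted(s2))
            assert got == pytest.approx(want)

    def test_symmetric_combiners(self):
        for g, m, s1, s2 in sv_cases(15, seed=113):
            for combine in ("bma", "max", "avg"):
                assert set_similarity(g, m, s1, s2, combine=combine) == pytest.approx(
                    set_similarity(g, m, s2, s1, combine=combine)
                )

    def test_range(self):
        for g, m, s1, s2 in sv_cases(30, seed=114):
            for combine in ("bma", "max", "avg"):
                assert 0.0 <= set_similarity(g, m, s1, s2, combine=combine) <= 1.0

    def test_unknown_method_or_combine(self, fig):
        with pytest.raises(ValueError):
            set_similarity(fig.graph, None, fig.sg_hsa, fig.sg_dme, method="resnik")
        with pytest.raises(ValueError):
            set_similarity(
                fig.graph, None, fig.sg_hsa, fig.sg_dme, combine="rcmax"
            )


class TestCompare:
    def test_worked_example_tuple(self, fig):
        c = compare(fig.graph, fig.informativeness, fig.sg_hsa, fig.sg_dme)
        assert c.par12 == pytest.approx(0.308, abs=5e-4)
        assert c.par21 == 0.0
        assert c.mpt12 == frozenset({"tRNA binding"})
        assert c.mpt21 == frozenset()
        assert c.mct == frozenset({"protein transporter activity", "protein binding"})

    def test_identical_sets(self, fig):
        c = compare(fig.graph, fig.informativeness, fig.sg_hsa, fig.sg_hsa)
        assert (c.sim, c.par12, c.par21) == (pytest.approx(1.0), 0.0, 0.0)

    def test_empty_rejected(self, fig):
        with pytest.raises(ValueError):
            compare(fig.graph, fig.informativeness, set(), fig.sg_hsa)

    def test_fields_equal_individual_operations(self):
        for g, m, s1, s2 in sv_cases(15, seed=115):
            c = compare(g, m, s1, s2)
            assert c.mpt12 == most_particular_terms(g, s1, s2)
            assert c.mpt21 == most_particular_terms(g, s2, s1)
            assert c.mct == most_informative_common_terms(g, s1, s2)
            assert c.pi12 == particular_informativeness(g, m, s1, s2)
            assert c.par12 == particularity(g, m, s1, s2)
            assert c.par21 == particularity(g, m, s2, s1)
            assert c.sim == set_similarity(g, m, s1, s2)
            assert c.sg1_star == expand_set(g, s1)


class TestBackendRankingAgreement:
    def test_sv_and_ic_agree_on_forced_ranking(self):
        """A deep specific branch vs. a shallow one: both backings must rank
        the deep-branch pair as the more particular one."""
        from sempar.annotations import corpus_from_mapping
        from sempar.informativeness import InformationContentModel

        edges = [("mid1", "root", "is_a")]
        for k in range(2, 6):
            edges.append((f"mid{k}", f"mid{k - 1}", "is_a"))
        edges += [("shallow", "root", "is_a"), ("common", "root", "is_a")]
        g = OntologyGraph.build(edges)
        deep_pair = ({"mid5", "common"}, {"common"})
        shallow_pair = ({"shallow", "common"}, {"common"})
        # corpus where rarity tracks depth so IC agrees with SV
        corpus = corpus_from_mapping(
            g,
            {
                "g1": {"mid5"},
                "g2": {"mid1"},
                "g3": {"shallow"},
                "g4": {"shallow"},
                "g5": {"common"},
                "g6": {"common"},
            },
        )
        for backing in (SemanticValueModel(g), InformationContentModel(corpus)):
            par_deep = particularity(g, backing, *deep_pair)
            par_shallow = particularity(g, backing, *shallow_pair)
            assert par_deep > par_shallow
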