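import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import matching_score_bruteforce, mcs_size_bruteforce
from conftest import random_graph
from enzrepo.rdm import (
    RDMConfig,
    RDMPattern,
    RDMTriple,
    extract_rdm,
    map_atoms,
    pattern_similarity,
    score_reaction_pair,
    triple_similarity,
)
from enzrepo.reaction_model import (
    AtomMapping,
    CompoundGraph,
    ConfigError,
    ReactantPair,
)

ETHANOL = CompoundGraph.build("eth", ["C", "C", "O"], [(0, 1, 1), (1, 2, 1)])
ACETALDEHYDE = CompoundGraph.build("ald", ["C", "C", "O"], [(0, 1, 1), (1, 2, 2)])
METHANE = CompoundGraph.build("met", ["C"], [])
WATER = CompoundGraph.build("wat", ["O"], [])


class TestMapAtoms:
    def test_self_mapping_covers_graph(self):
        m = map_atoms(ReactantPair(ETHANOL, ETHANOL))
        assert m.score == 3 and m.pairs == ((0, 0), (1, 1), (2, 2))

    def test_bond_orders_do_not_restrict_mapping(self):
        # dehydrogenation: the C-O order change must stay inside the mapping
        m = map_atoms(ReactantPair(ETHANOL, ACETALDEHYDE))
        assert m.score == 3

    def test_disjoint_elements_give_empty_mapping(self):
        m = map_atoms(ReactantPair(METHANE, WATER))
        assert m.score == 0 and m.pairs == ()

    def test_greedy_fallback_beyond_cap_records_mode(self):
        pair = ReactantPair(ETHANOL, ACETALDEHYDE)
        m = map_atoms(pair, "exact", size_cap=2)
        assert m.mode == "greedy-fallback"
        assert m.score == 3  # greedy finds the full mapping here too

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_size_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        g1 = random_graph(rng, 3, 7, "a")
        g2 = random_graph(rng, 3, 7, "b")
        m = map_atoms(ReactantPair(g1, g2))
        assert m.score == mcs_size_bruteforce(g1, g2)

    def test_deterministic_tie_break(self):
        # two identical methyl branches: smallest pair sequence must win
        g = CompoundGraph.build("t", ["C", "C", "C"], [(0, 1, 1), (0, 2, 1)])
        m1 = map_atoms(ReactantPair(g, g))
        m2 = map_atoms(ReactantPair(g, g))
        assert m1.pairs == m2.pairs == ((0, 0), (1, 1), (2, 2))


class TestExtractRdm:
    def test_identity_pair_has_empty_pattern(self):
        pair = ReactantPair(ETHANOL, ETHANOL)
        pat = extract_rdm(pair, map_atoms(pair))
        assert len(pat) == 0

    def test_dehydrogenation_centers_hand_traced(self):
        pair = ReactantPair(ETHANOL, ACETALDEHYDE)
        pat = extract_rdm(pair, map_atoms(pair))
        # centers: the carbonyl carbon and oxygen; the methyl carbon is not
        assert len(pat) == 2
        r_changes = {t.r_change for t in pat.triples}
        assert r_changes == {
            ("C.sp3.ac.h1", "C.sp2.ac.h1"),
            ("O.sp3.ac.h0", "O.sp2.ac.h0"),
        }
        carbon = next(t for t in pat.triples if t.r_change[0].startswith("C"))
        assert carbon.d_set == ()
        assert ("O.sp3.ac.h0", "O.sp2.ac.h0") in carbon.m_set

    def test_pendant_atom_loss_lands_in_d_set(self):
        propane = CompoundGraph.build("p3", ["C", "C", "C"], [(0, 1, 1), (1, 2, 1)])
        ethane = CompoundGraph.build("p2", ["C", "C"], [(0, 1, 1)])
        pair = ReactantPair(propane, ethane)
        pat = extract_rdm(pair, map_atoms(pair))
        assert len(pat) == 1
        (t,) = pat.triples
        assert t.d_set == ("C.sp3.ac.h0",)

    def test_mapping_pair_mismatch_rejected(self):
        bad = AtomMapping(((0, 0),), 1)
        with pytest.raises(ValueError, match="different elements"):
            extract_rdm(ReactantPair(METHANE, WATER), bad)


T1 = RDMTriple(("C.sp3.ac.h0", "C.sp2.ac.h0"), (), (("O.sp3.ac.h0", "O.sp3.ac.h0"),))
T2 = RDMTriple(("C.sp3.ac.h0", "C.sp2.ac.h0"), ("N.sp3.ac.h0",), (("C.ar.rg.h0", "C.ar.rg.h0"),))
T3 = RDMTriple(("O.sp3.ac.h0", "O.sp2.ac.h0"), (), ())
T4 = RDMTriple(("N.sp3.ac.h0", "N.sp2.ac.h0"), (), ())


class TestTripleSimilarity:
    def test_identical_triples_score_one(self):
        assert triple_similarity(T1, T1) == 1.0

    def test_same_center_disjoint_context_scores_half(self):
        assert triple_similarity(T1, T2) == pytest.approx(0.5)

    def test_empty_context_agreement_convention(self):
        # different center, both D and M empty: jaccard(∅,∅)=1 on both
        assert triple_similarity(T3, T4) == pytest.approx(0.5)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigError):
            triple_similarity(T1, T1, weights=(0.9, 0.9, 0.9))


class TestPatternSimilarity:
    def test_self_similarity_is_one(self):
        p = RDMPattern((T1, T3))
        assert pattern_similarity(p, p).value == 1.0

    def test_one_empty_pattern_scores_zero(self):
        assert pattern_similarity(RDMPattern((T1,)), RDMPattern(())).value == 0.0
        assert pattern_similarity(RDMPattern(()), RDMPattern(())).value == 1.0

    def test_duplicate_triples_penalised_by_size(self):
        p = RDMPattern((T1, T1))
        q = RDMPattern((T1,))
        assert pattern_similarity(p, q).value == pytest.approx(0.5)

    def test_vocabulary_mismatch_rejected(self):
        q = RDMPattern((T1,), vocabulary="other-vocab")
        with pytest.raises(ConfigError, match="vocabulary"):
            pattern_similarity(RDMPattern((T1,)), q)

    @pytest.mark.parametrize("seed", range(20))
    def test_matching_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        p = random_pattern(rng)
        q = random_pattern(rng)
        got = pattern_similarity(p, q).value
        assert got == pytest.approx(matching_score_bruteforce(p, q))
        assert got == pytest.approx(pattern_similarity(q, p).value)  # symmetric
        assert 0.0 <= got <= 1.0

    def test_serialization_round_trip(self):
        p = RDMPattern((T1, T2), pair_id="a>b")
        assert RDMPattern.from_json(p.to_json()) == p


CODES = [
    "C.sp3.ac.h0",
    "C.sp2.ac.h1",
    "C.ar.rg.h0",
    "O.sp3.ac.h0",
    "N.sp3.rg.h1",
]


def random_triple(rng) -> RDMTriple:
    pick = lambda: CODES[int(rng.integers(len(CODES)))]  # noqa: E731
    r = (pick(), pick())
    d = tuple(sorted(pick() for _ in range(int(rng.integers(0, 3)))))
    m = tuple(sorted((pick(), pick()) for _ in range(int(rng.integers(0, 3)))))
    return RDMTriple(r, d, m)


def random_pattern(rng, max_triples=4) -> RDMPattern:
    return RDMPattern(
        tuple(random_triple(rng) for _ in range(int(rng.integers(0, max_triples + 1))))
    )


_code = st.sampled_from(CODES)
_triple = st.builds(
    RDMTriple,
    st.tuples(_code, _code),
    st.lists(_code, max_size=3).map(lambda x: tuple(sorted(x))),
    st.lists(st.tuples(_code, _code), max_size=3).map(lambda x: tuple(sorted(x))),
)


class TestSimilarityProperties:
    @settings(derandomize=True, max_examples=100)
    @given(_triple, _triple)
    def test_triple_similarity_symmetric_bounded_reflexive(self, a, b):
        s = triple_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(triple_similarity(b, a))
        assert triple_similarity(a, a) == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(_triple, max_size=4), st.lists(_triple, max_size=4))
    def test_pattern_similarity_one_iff_equal_multisets(self, ts1, ts2):
        p, q = RDMPattern(tuple(ts1)), RDMPattern(tuple(ts2))
        s = pattern_similarity(p, q).value
        assert 0.0 <= s <= 1.0
        assert (s == 1.0) == (sorted(p.triples) == sorted(q.triples))


class TestScoreReactionPair:
    def test_self_pair_scores_one(self):
        pair = ReactantPair(ETHANOL, ACETALDEHYDE)
        assert score_reaction_pair(pair, pair).value == 1.0

    def test_unrelated_chemistry_scores_zero(self):
        # ethanol->acetaldehyde (non-empty pattern) vs identical pair (empty)
        changed = ReactantPair(ETHANOL, ACETALDEHYDE)
        unchanged = ReactantPair(METHANE, METHANE)
        assert score_reaction_pair(changed, unchanged).value == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_atom_permutation(self, seed):
        from enzrepo.synthetic import GeneratorConfig, generate_database

        db, man = generate_database(
            GeneratorConfig(seed=seed, n_plant_reactions=2, n_planted_analogs=2,
                            n_bacterial_reactions=2, n_shared_reactions=0,
                            n_orphan_plant_reactions=0)
        )
        cfg = RDMConfig()
        p = man["planted"][0]
        q = db.reactions[p["query"]].main_pair
        a = db.reactions[p["analog"]].main_pair
        base = score_reaction_pair(q, a, cfg).value

        rng = np.random.default_rng(seed + 100)
        perm = list(rng.permutation(len(q.substrate)))
        inv = {old: new for new, old in enumerate(perm)}
        permuted_sub = CompoundGraph.build(
            "perm",
            [q.substrate.element(perm[i]) for i in range(len(q.substrate))],
            [(inv[b.a], inv[b.b], b.order) for b in q.substrate.bonds],
        )
        q_perm = ReactantPair(permuted_sub, q.product)
        assert score_reaction_pair(q_perm, a, RDMConfig()).value == pytest.approx(base)
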