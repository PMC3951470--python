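import itertools
import math

import networkx as nx
import numpy as np
import pytest

from conftest import TOY_EDGES, TOY_FREQS, make_instance
from oracles import matching_total_oracle

from ppimkl.semantic_sim import (
    ConceptError,
    SimilarityParams,
    Taxonomy,
    build_context,
    gram_sim,
    hybrid_sim,
    k_sim,
    li_sim,
    lin_sim,
    munkres_max_matching,
    sim_con,
    sim_pp,
    word_sim,
)

ALPHA, BETA = 0.2, 0.6


# -- independent oracles over the toy taxonomy (networkx + closed forms) -----

def li_oracle(c1, c2):
    G = nx.Graph(TOY_EDGES)
    D = nx.DiGraph((child, parent) for child, parent in TOY_EDGES)
    depth = {c: nx.shortest_path_length(G, c, "r") + 1 for c in G.nodes}
    anc = {c: nx.descendants(D, c) | {c} for c in G.nodes}
    common = anc[c1] & anc[c2]
    l = min(
        nx.shortest_path_length(G, c1, s) + nx.shortest_path_length(G, s, c2)
        for s in common
    )
    h = max(
        depth[s] for s in common
        if nx.shortest_path_length(G, c1, s) + nx.shortest_path_length(G, s, c2) == l
    )
    return math.exp(-ALPHA * l) * math.tanh(BETA * h)


def ic_oracle():
    D = nx.DiGraph((parent, child) for child, parent in TOY_EDGES)
    total = sum(TOY_FREQS.values())
    ic = {}
    for c in D.nodes:
        cum = sum(TOY_FREQS[d] for d in nx.descendants(D, c) | {c})
        ic[c] = -math.log(max(cum, 0.5) / total) if c != "r" else 0.0
    return ic


def lin_oracle(c1, c2):
    ic = ic_oracle()
    D = nx.DiGraph((child, parent) for child, parent in TOY_EDGES)
    common = (nx.descendants(D, c1) | {c1}) & (nx.descendants(D, c2) | {c2})
    denom = ic[c1] + ic[c2]
    if denom == 0:
        return 1.0 if c1 == c2 else 0.0
    return 2 * max(ic[s] for s in common) / denom


CONCEPTS = ["r", "a", "b", "a1", "a2", "b1", "b2"]


class TestLiSim:
    def test_identity_is_tanh_of_depth(self, toy_taxonomy):
        # identical concepts: l = 0, value = tanh(beta * depth)
        assert li_sim("a1", "a1", toy_taxonomy) == pytest.approx(math.tanh(BETA * 3))
        assert li_sim("r", "r", toy_taxonomy) == pytest.approx(math.tanh(BETA * 1))

    def test_root_only_overlap_small(self, toy_taxonomy):
        value = li_sim("a1", "b1", toy_taxonomy)
        # subsumer is the root: l = 4, h = 1
        assert value == pytest.approx(math.exp(-ALPHA * 4) * math.tanh(BETA * 1))
        assert value < li_sim("a1", "a2", toy_taxonomy)

    def test_all_pairs_match_oracle(self, toy_taxonomy):
        for c1, c2 in itertools.product(CONCEPTS, repeat=2):
            assert li_sim(c1, c2, toy_taxonomy) == pytest.approx(li_oracle(c1, c2))

    def test_missing_concept_named(self, toy_taxonomy):
        with pytest.raises(ConceptError, match="ghost"):
            li_sim("ghost", "a1", toy_taxonomy)

    def test_monotone_decreasing_in_path_length(self, toy_taxonomy):
        # same subsumer depth (root), increasing l
        l_values = [(2, "a", "b"), (3, "a", "b1"), (4, "a1", "b1")]
        sims = [li_sim(c1, c2, toy_taxonomy) for _, c1, c2 in l_values]
        assert sims[0] > sims[1] > sims[2]

    def test_monotone_increasing_in_depth(self, toy_taxonomy):
        # l = 2 in both cases; subsumer depth 1 (root) vs 2 (node a)
        assert li_sim("a1", "a2", toy_taxonomy) > li_sim("a", "b", toy_taxonomy)


class TestLinSim:
    def test_self_similarity_one_when_ic_positive(self, toy_taxonomy):
        for c in CONCEPTS:
            if toy_taxonomy.ic[c] > 0:
                assert lin_sim(c, c, toy_taxonomy) == pytest.approx(1.0)

    def test_root_lcs_zero(self, toy_taxonomy):
        assert lin_sim("a1", "b1", toy_taxonomy) == 0.0

    def test_root_pair_convention(self, toy_taxonomy):
        assert lin_sim("r", "r", toy_taxonomy) == 1.0
        assert lin_sim("r", "a", toy_taxonomy) == 0.0

    def test_all_pairs_match_oracle(self, toy_taxonomy):
        for c1, c2 in itertools.product(CONCEPTS, repeat=2):
            assert lin_sim(c1, c2, toy_taxonomy) == pytest.approx(lin_oracle(c1, c2))

    def test_ic_invariants(self, toy_taxonomy):
        assert toy_taxonomy.p["r"] == 1.0
        assert toy_taxonomy.ic["r"] == 0.0
        for child, parent in TOY_EDGES:
            assert toy_taxonomy.p[child] <= toy_taxonomy.p[parent] + 1e-12
        assert all(v >= 0 for v in toy_taxonomy.ic.values())


class TestHybridSim:
    def test_mean_of_components(self, toy_taxonomy):
        for c1, c2 in [("a1", "a2"), ("a1", "b1"), ("b1", "b1")]:
            li = li_sim(c1, c2, toy_taxonomy)
            lin = lin_sim(c1, c2, toy_taxonomy)
            assert hybrid_sim(c1, c2, toy_taxonomy) == pytest.approx((li + lin) / 2)

    def test_product_combiner(self, toy_taxonomy):
        params = SimilarityParams(combiner="product")
        for c1, c2 in itertools.product(["a1", "a2", "b1"], repeat=2):
            expected = li_oracle(c1, c2) * lin_oracle(c1, c2)
            assert hybrid_sim(c1, c2, toy_taxonomy, params) == pytest.approx(expected)

    def test_single_measure_combiners(self, toy_taxonomy):
        assert hybrid_sim("a1", "a2", toy_taxonomy, SimilarityParams(combiner="li_only")) \
            == pytest.approx(li_oracle("a1", "a2"))
        assert hybrid_sim("a1", "a2", toy_taxonomy, SimilarityParams(combiner="lin_only")) \
            == pytest.approx(lin_oracle("a1", "a2"))

    def test_bounded_and_symmetric(self, toy_taxonomy):
        for c1, c2 in itertools.product(CONCEPTS, repeat=2):
            v = hybrid_sim(c1, c2, toy_taxonomy)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(hybrid_sim(c2, c1, toy_taxonomy))


class TestSimPP:
    def test_pair_matrix_matches_oracle(self, toy_taxonomy):
        pairs = [("a1", "a2"), ("b1", "b2"), ("a1", "b1")]
        for pa, pb in itertools.product(pairs, repeat=2):
            expected = 0.5 * (
                (li_oracle(pa[0], pb[0]) + lin_oracle(pa[0], pb[0])) / 2
                + (li_oracle(pa[1], pb[1]) + lin_oracle(pa[1], pb[1])) / 2
            )
            assert sim_pp(pa, pb, toy_taxonomy) == pytest.approx(expected)

    def test_symmetry(self, toy_taxonomy):
        pa, pb = ("a1", "b2"), ("a2", "b1")
        assert sim_pp(pa, pb, toy_taxonomy) == pytest.approx(sim_pp(pb, pa, toy_taxonomy))

    def test_string_identity_fallback(self, toy_taxonomy):
        assert sim_pp(("X99", "a1"), ("X99", "a1"), toy_taxonomy) == pytest.approx(
            0.5 * (1.0 + hybrid_sim("a1", "a1", toy_taxonomy))
        )
        assert sim_pp(("X99", "a1"), ("Y88", "a1"), toy_taxonomy) == pytest.approx(
            0.5 * (0.0 + hybrid_sim("a1", "a1", toy_taxonomy))
        )
        assert sim_pp((None, "a1"), (None, "a1"), toy_taxonomy) == pytest.approx(
            0.5 * hybrid_sim("a1", "a1", toy_taxonomy)
        )


class TestMunkres:
    def test_diagonal_matrix(self):
        W = np.diag([0.9, 0.8, 0.7])
        pairs, total = munkres_max_matching(W)
        assert set(pairs) >= {(0, 0), (1, 1), (2, 2)}
        assert total == pytest.approx(2.4)

    def test_one_by_one(self):
        pairs, total = munkres_max_matching([[0.7]])
        assert pairs == [(0, 0)]
        assert total == pytest.approx(0.7)

    def test_empty(self):
        pairs, total = munkres_max_matching(np.zeros((0, 0)))
        assert pairs == [] and total == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            munkres_max_matching([[-0.1]])

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            m, n = rng.integers(1, 7, size=2)
            W = rng.random((m, n))
            pairs, total = munkres_max_matching(W)
            assert total == pytest.approx(matching_total_oracle(W), rel=1e-12)
            rows = [r for r, _ in pairs]
            cols = [c for _, c in pairs]
            assert len(set(rows)) == len(rows) and len(set(cols)) == len(cols)
            assert total == pytest.approx(sum(W[r, c] for r, c in pairs))


class TestWordAndContextSim:
    @pytest.fixture()
    def word_tax(self):
        edges = [("kw", "root"), ("top", "root"),
                 ("interact", "kw"), ("bind", "kw"),
                 ("cat", "top"), ("dog", "top")]
        freqs = {"root": 0, "kw": 0, "top": 0,
                 "interact": 4, "bind": 4, "cat": 6, "dog": 2}
        return Taxonomy(edges, freqs)

    def test_same_word_in_vocab(self, word_tax):
        assert word_sim("cat", "cat", word_tax) == pytest.approx(1.0)

    def test_both_oov(self, word_tax):
        assert word_sim("zebra", "yak", word_tax) == 0.0
        assert word_sim("zebra", "zebra", word_tax) == 1.0

    def test_matches_lin_oracle(self, word_tax):
        expected = lin_sim("interact", "bind", word_tax)
        assert word_sim("interact", "bind", word_tax) == pytest.approx(expected)

    def test_multi_sense_takes_max(self, word_tax):
        mapping = {"pet": ["cat", "dog"], "feline": ["cat"]}
        expected = max(
            lin_sim(a, "cat", word_tax) for a in ("cat", "dog")
        )
        assert word_sim("pet", "feline", word_tax, mapping) == pytest.approx(expected)

    def test_identical_contexts_in_vocab(self, word_tax):
        ctx = ["cat", "dog", "interact"]
        assert sim_con(ctx, ctx, word_tax) == pytest.approx(1.0)

    def test_empty_context_zero(self, word_tax):
        assert sim_con([], ["cat"], word_tax) == 0.0

    def test_three_by_three_matches_permutation_oracle(self, word_tax):
        ctx_a = ["cat", "interact", "zebra"]
        ctx_b = ["dog", "bind", "zebra"]
        W = np.array([[word_sim(a, b, word_tax) for b in ctx_b] for a in ctx_a])
        assert sim_con(ctx_a, ctx_b, word_tax) == pytest.approx(
            matching_total_oracle(W) / 3
        )

    def test_symmetry_and_bounds(self, word_tax):
        ctx_a = ["cat", "interact"]
        ctx_b = ["dog", "bind", "zebra"]
        v = sim_con(ctx_a, ctx_b, word_tax)
        assert v == pytest.approx(sim_con(ctx_b, ctx_a, word_tax))
        assert 0.0 <= v <= 1.0

    def test_build_context_excludes_proteins_and_stopwords(self):
        inst = make_instance(
            ["The", "Abc", "binds", "the", "Xyz", "strongly"], (1, 2), (4, 5)
        )
        ctx = build_context(inst)
        assert ctx == ["binds", "strongly"]


class TestKSim:
    def test_mix_boundaries(self, toy_taxonomy, synthetic_bundle):
        word_tax = synthetic_bundle["word_tax"]
        x = make_instance(["Abc", "binds", "Xyz"], (0, 1), (2, 3),
                          inst_id="x", concepts=("a1", "a2"))
        y = make_instance(["Def", "modulates", "Ghi"], (0, 1), (2, 3),
                          inst_id="y", concepts=("b1", "b2"))
        spp = sim_pp(("a1", "a2"), ("b1", "b2"), toy_taxonomy)
        scon = sim_con(build_context(x), build_context(y), word_tax)
        assert k_sim(x, y, toy_taxonomy, word_tax, mix=1.0) == pytest.approx(spp)
        assert k_sim(x, y, toy_taxonomy, word_tax, mix=0.0) == pytest.approx(scon)
        assert k_sim(x, y, toy_taxonomy, word_tax, mix=0.5) == pytest.approx(
            0.5 * spp + 0.5 * scon
        )

    def test_self_similarity(self, toy_taxonomy, synthetic_bundle):
        # sim_con(x, x) = 1 when every context word is in vocabulary; the
        # sim_pp part reaches 1 only in the deep-concept limit (li -> tanh).
        word_tax = synthetic_bundle["word_tax"]
        x = make_instance(["w0", "Abc", "w1", "Xyz"], (1, 2), (3, 4),
                          inst_id="x", concepts=("a1", "b1"))
        spp_self = sim_pp(("a1", "b1"), ("a1", "b1"), toy_taxonomy)
        assert sim_con(build_context(x), build_context(x),
                       word_tax) == pytest.approx(1.0)
        assert k_sim(x, x, toy_taxonomy, word_tax) == pytest.approx(
            0.5 * spp_self + 0.5
        )
        # lin components are 1 at identity, so self-similarity stays high
        assert k_sim(x, x, toy_taxonomy, word_tax) > 0.95

    def test_gram_matches_pairwise(self, synthetic_bundle):
        corpus = synthetic_bundle["corpus"][:8]
        tax, word_tax = synthetic_bundle["tax"], synthetic_bundle["word_tax"]
        K = gram_sim(corpus, tax, word_tax)
        for i in range(8):
            for j in range(8):
                assert K[i, j] == pytest.approx(
                    k_sim(corpus[i], corpus[j], tax, word_tax)
                )

    def test_gram_symmetric_bounded(self, synthetic_bundle):
        corpus = synthetic_bundle["corpus"][:30]
        K = gram_sim(corpus, synthetic_bundle["tax"], synthetic_bundle["word_tax"])
        assert np.allclose(K, K.T)
        assert K.min() >= 0.0 and K.max() <= 1.0 + 1e-12
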