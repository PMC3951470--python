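"""Taxonomy-based concept similarity, protein-pair and context similarity.

Concept similarity combines an edge-counting measure (exponential decay in path
length, tanh saturation in subsumer depth) with an information-content measure.
Context similarity aligns the non-protein, non-stopword words of two sentences
via a maximum-weight bipartite matching (Kuhn–Munkres) over word similarities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .corpus_io import Instance, TaxonomyFile, TaxonomyError, ensure_masked

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.2
DEFAULT_BETA = 0.6
DEFAULT_MIX = 0.5
COMBINERS = ("mean", "product", "li_only", "lin_only")

#: Small English stopword list; configurable via file.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """a an the and or but of in on at to from with by for as is are was were be
    been being that this these those it its their his her our your my we you
    they he she i not no nor so if then than too very can will just do does did
    have has had which who whom whose what when where why how each other into
    onto over under between among both all any some such own same s t don
    """.split()
)


class ConceptError(KeyError):
    """Raised when a concept id is not present in the taxonomy."""


@dataclass
class SimilarityParams:
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    combiner: str = "mean"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.combiner not in COMBINERS:
            raise ValueError(f"combiner must be one of {COMBINERS}")


class Taxonomy:
    """Rooted concept DAG with depths, cumulative probabilities and IC.

    Depth of the root is 1.  p(c) is the cumulative frequency of c and its
    descendants divided by the root's cumulative frequency, so p(root) = 1 and
    IC(root) = 0.
    """

    def __init__(self, edges: Sequence[tuple[str, str]], frequencies: Mapping[str, float]):
        tf = TaxonomyFile(
            concepts=set(frequencies),
            edges=list(edges),
            frequencies=dict(frequencies),
        )
        self.root = tf.validate()
        self.parents: dict[str, set[str]] = {}
        self.children: dict[str, set[str]] = {}
        concepts: set[str] = set(frequencies)
        for child, parent in edges:
            concepts.add(child)
            concepts.add(parent)
            self.parents.setdefault(child, set()).add(parent)
            self.children.setdefault(parent, set()).add(child)
        self.concepts = concepts
        for c in concepts:
            self.parents.setdefault(c, set())
            self.children.setdefault(c, set())
        self.frequencies = {c: float(frequencies.get(c, 0.0)) for c in concepts}
        for c, f in self.frequencies.items():
            if f < 0:
                raise TaxonomyError(f"negative frequency for {c!r}")

        # depth: 1 + min edge distance from root
        self.depth: dict[str, int] = {self.root: 1}
        frontier = [self.root]
        while frontier:
            nxt = []
            for node in frontier:
                for child in self.children[node]:
                    if child not in self.depth:
                        self.depth[child] = self.depth[node] + 1
                        nxt.append(child)
            frontier = nxt

        # cumulative frequency over self-or-descendants (sets avoid
        # double-counting in DAGs with multiple parents)
        desc_memo: dict[str, frozenset[str]] = {}

        def descendants(c: str) -> frozenset[str]:
            if c not in desc_memo:
                acc: set[str] = {c}
                for child in self.children[c]:
                    acc |= descendants(child)
                desc_memo[c] = frozenset(acc)
            return desc_memo[c]

        self.cumfreq = {
            c: sum(self.frequencies[d] for d in descendants(c)) for c in concepts
        }
        total = self.cumfreq[self.root]
        if total <= 0:
            raise TaxonomyError("taxonomy has zero total frequency")
        # half pseudo-count for zero-frequency subtrees so IC stays finite
        self.p = {c: max(self.cumfreq[c], 0.5) / total for c in concepts}
        self.p[self.root] = 1.0
        self.ic = {c: -math.log(self.p[c]) for c in concepts}

    @classmethod
    def from_file(cls, tf: TaxonomyFile) -> "Taxonomy":
        return cls(tf.edges, {c: tf.frequencies.get(c, 0.0) for c in tf.concepts})

    def __contains__(self, concept: str) -> bool:
        return concept in self.concepts

    def _require(self, concept: str) -> None:
        if concept not in self.concepts:
            raise ConceptError(f"concept {concept!r} not in taxonomy")

    def ancestor_dists(self, concept: str) -> dict[str, int]:
        """Minimum upward edge distance to every ancestor (including self at 0)."""
        self._require(concept)
        dists = {concept: 0}
        frontier = [concept]
        while frontier:
            nxt = []
            for node in frontier:
                for parent in self.parents[node]:
                    if parent not in dists:
                        dists[parent] = dists[node] + 1
                        nxt.append(parent)
            frontier = nxt
        return dists

    def path_through_subsumer(self, c1: str, c2: str) -> tuple[int, int, str]:
        """Shortest path length through a common subsumer and that subsumer's depth.

        Returns (l, h, subsumer); among minimum-length subsumers the deepest
        one is chosen.
        """
        d1, d2 = self.ancestor_dists(c1), self.ancestor_dists(c2)
        common = set(d1) & set(d2)
        best: Optional[tuple[int, int, str]] = None
        for s in sorted(common):
            l = d1[s] + d2[s]
            h = self.depth[s]
            if best is None or l < best[0] or (l == best[0] and h > best[1]):
                best = (l, h, s)
        assert best is not None  # root is always common
        return best

    def lcs_by_ic(self, c1: str, c2: str) -> str:
        d1, d2 = self.ancestor_dists(c1), self.ancestor_dists(c2)
        common = sorted(set(d1) & set(d2))
        return max(common, key=lambda s: (self.ic[s], s))


def li_sim(
    c1: str,
    c2: str,
    tax: Taxonomy,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> float:
    """Edge-based similarity: exp(-alpha*l) * tanh(beta*h) with l the shortest
    path through a common subsumer and h that subsumer's depth."""
    tax._require(c1)
    tax._require(c2)
    l, h, _ = tax.path_through_subsumer(c1, c2)
    return math.exp(-alpha * l) * math.tanh(beta * h)


def lin_sim(c1: str, c2: str, tax: Taxonomy) -> float:
    """Information-content similarity: 2*IC(lcs) / (IC(c1) + IC(c2))."""
    tax._require(c1)
    tax._require(c2)
    denom = tax.ic[c1] + tax.ic[c2]
    if denom == 0.0:
        return 1.0 if c1 == c2 else 0.0
    lcs = tax.lcs_by_ic(c1, c2)
    return min(1.0, 2.0 * tax.ic[lcs] / denom)


def hybrid_sim(
    c1: str, c2: str, tax: Taxonomy, params: Optional[SimilarityParams] = None
) -> float:
    """Combined edge-based + IC-based concept similarity."""
    params = params or SimilarityParams()
    if params.combiner == "li_only":
        return li_sim(c1, c2, tax, params.alpha, params.beta)
    if params.combiner == "lin_only":
        return lin_sim(c1, c2, tax)
    li = li_sim(c1, c2, tax, params.alpha, params.beta)
    lin = lin_sim(c1, c2, tax)
    if params.combiner == "product":
        return li * lin
    return (li + lin) / 2.0


def sim_pp(
    pair_a: tuple[Optional[str], Optional[str]],
    pair_b: tuple[Optional[str], Optional[str]],
    tax: Taxonomy,
    params: Optional[SimilarityParams] = None,
) -> float:
    """Protein-pair similarity: positionally aligned mean of concept similarities.

    A position where either concept is unresolvable falls back to string
    identity (1 if identical surface/id, else 0).
    """
    params = params or SimilarityParams()
    values = []
    for a, b in zip(pair_a, pair_b):
        if a is not None and b is not None and a in tax and b in tax:
            values.append(hybrid_sim(a, b, tax, params))
        else:
            logger.debug("sim_pp fallback to string identity for (%r, %r)", a, b)
            values.append(1.0 if (a is not None and a == b) else 0.0)
    return sum(values) / len(values)


# ---------------------------------------------------------------------------
# Kuhn-Munkres maximum-weight bipartite matching
# ---------------------------------------------------------------------------


def munkres_max_matching(W) -> tuple[list[tuple[int, int]], float]:
    """Maximum-total-weight one-to-one matching of a nonnegative m x n matrix.

    Returns (pairs, total) where pairs are (row, col) with each row and column
    used at most once.  Implemented as the O(n^3) Hungarian algorithm with
    potentials; because weights are nonnegative, assigning every row (or
    column, whichever is fewer) attains the maximum over partial matchings.
    """
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        return [], 0.0
    if W.ndim != 2:
        raise ValueError("weight matrix must be 2-dimensional")
    if not np.all(np.isfinite(W)) or np.any(W < 0):
        raise ValueError("weights must be finite and nonnegative")
    original = W
    transposed = False
    if W.shape[0] > W.shape[1]:
        W = W.T
        transposed = True
    n, m = W.shape
    cost = -W  # minimize
    INF = float("inf")
    u = [0.0] * (n + 1)
    v = [0.0] * (m + 1)
    p = [0] * (m + 1)  # p[j] = row matched to column j (1-based; 0 = free)
    way = [0] * (m + 1)
    for i in range(1, n + 1):
        p[0] = i
        j0 = 0
        minv = [INF] * (m + 1)
        used = [False] * (m + 1)
        while True:
            used[j0] = True
            i0 = p[j0]
            delta = INF
            j1 = -1
            for j in range(1, m + 1):
                if not used[j]:
                    cur = cost[i0 - 1][j - 1] - u[i0] - v[j]
                    if cur < minv[j]:
                        minv[j] = cur
                        way[j] = j0
                    if minv[j] < delta:
                        delta = minv[j]
                        j1 = j
            for j in range(m + 1):
                if used[j]:
                    u[p[j]] += delta
                    v[j] -= delta
                else:
                    minv[j] -= delta
            j0 = j1
            if p[j0] == 0:
                break
        while j0:
            j1 = way[j0]
            p[j0] = p[j1]
            j0 = j1
    pairs = []
    for j in range(1, m + 1):
        if p[j]:
            r, c = p[j] - 1, j - 1
            pairs.append((c, r) if transposed else (r, c))
    pairs.sort()
    total = float(sum(original[r][c] for r, c in pairs))
    return pairs, total


# ---------------------------------------------------------------------------
# Context similarity
# ---------------------------------------------------------------------------


def word_sim(
    w1: str,
    w2: str,
    word_tax: Taxonomy,
    mapping: Optional[Mapping[str, Sequence[str]]] = None,
) -> float:
    """IC-based similarity between two words via their taxonomy concepts.

    Words map to concepts through ``mapping`` (default: the word itself if it
    is a concept id).  When a word has several senses the best-matching concept
    pair wins.  Out-of-vocabulary comparisons fall back to string identity.
    """
    def concepts(word: str) -> list[str]:
        if mapping is not None and word in mapping:
            return [c for c in mapping[word] if c in word_tax]
        return [word] if word in word_tax else []

    cs1, cs2 = concepts(w1), concepts(w2)
    if not cs1 or not cs2:
        return 1.0 if w1 == w2 else 0.0
    return max(lin_sim(a, b, word_tax) for a in cs1 for b in cs2)


def build_context(inst: Instance, stopwords: Optional[frozenset[str]] = None) -> list[str]:
    """Bag of lowercase sentence words excluding protein placeholders and stopwords."""
    inst = ensure_masked(inst)
    stops = DEFAULT_STOPWORDS if stopwords is None else stopwords
    context = []
    for token in inst.token_texts():
        if token.startswith("PROTEIN"):
            continue
        word = token.lower()
        if word in stops or not any(ch.isalnum() for ch in word):
            continue
        context.append(word)
    return context


def sim_con(
    ctx_a: Sequence[str],
    ctx_b: Sequence[str],
    word_tax: Taxonomy,
    mapping: Optional[Mapping[str, Sequence[str]]] = None,
) -> float:
    """Context similarity: maximum bipartite matching total / max(|A|, |B|)."""
    if not ctx_a or not ctx_b:
        return 0.0
    W = np.array(
        [[word_sim(a, b, word_tax, mapping) for b in ctx_b] for a in ctx_a]
    )
    _, total = munkres_max_matching(W)
    return total / max(len(ctx_a), len(ctx_b))


def k_sim(
    x: Instance,
    y: Instance,
    tax: Taxonomy,
    word_tax: Taxonomy,
    params: Optional[SimilarityParams] = None,
    mix: float = DEFAULT_MIX,
    stopwords: Optional[frozenset[str]] = None,
    mapping: Optional[Mapping[str, Sequence[str]]] = None,
) -> float:
    """Semantic kernel: mix * sim_pp + (1 - mix) * sim_con."""
    if not (0.0 <= mix <= 1.0):
        raise ValueError("mix must be in [0, 1]")
    x, y = ensure_masked(x), ensure_masked(y)
    pair_x = (x.entity("P1").concept_id, x.entity("P2").concept_id)
    pair_y = (y.entity("P1").concept_id, y.entity("P2").concept_id)
    spp = sim_pp(pair_x, pair_y, tax, params)
    scon = sim_con(build_context(x, stopwords), build_context(y, stopwords), word_tax, mapping)
    return mix * spp + (1.0 - mix) * scon


def gram_sim(
    instances: Sequence[Instance],
    tax: Taxonomy,
    word_tax: Taxonomy,
    params: Optional[SimilarityParams] = None,
    mix: float = DEFAULT_MIX,
    stopwords: Optional[frozenset[str]] = None,
    mapping: Optional[Mapping[str, Sequence[str]]] = None,
) -> np.ndarray:
    """Semantic-kernel Gram matrix with concept- and word-level caching."""
    if not (0.0 <= mix <= 1.0):
        raise ValueError("mix must be in [0, 1]")
    params = params or SimilarityParams()
    masked = [ensure_masked(inst) for inst in instances]
    pairs = [(m.entity("P1").concept_id, m.entity("P2").concept_id) for m in masked]
    contexts = [build_context(m, stopwords) for m in masked]
    n = len(masked)

    concept_cache: dict[tuple, float] = {}

    def cached_sim_pp(pa, pb) -> float:
        key = tuple(sorted((pa, pb), key=repr))
        if key not in concept_cache:
            concept_cache[key] = sim_pp(pa, pb, tax, params)
        return concept_cache[key]

    word_cache: dict[tuple[str, str], float] = {}

    def cached_word_sim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in word_cache:
            word_cache[key] = word_sim(a, b, word_tax, mapping)
        return word_cache[key]

    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            spp = cached_sim_pp(pairs[i], pairs[j])
            ca, cb = contexts[i], contexts[j]
            if not ca or not cb:
                scon = 0.0
            else:
                W = np.array([[cached_word_sim(a, b) for b in cb] for a in ca])
                _, total = munkres_max_matching(W)
                scon = total / max(len(ca), len(cb))
            K[i, j] = K[j, i] = mix * spp + (1.0 - mix) * scon
    return K
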