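"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the library code paths they check: the tree-kernel
oracle enumerates common subtree fragments explicitly, and the matching oracle
enumerates injections.
"""

import itertools
from collections import Counter

import numpy as np

from ppimkl.corpus_io import ParseTree

NONTERMINALS = ["A", "B", "C"]
TOKENS = ["x", "y", "z"]


def random_tree(rng: np.random.Generator, budget: int = 8) -> ParseTree:
    """Random labeled tree with at most ``budget`` total nodes (>= 2)."""

    def build(budget: int, depth: int) -> tuple[ParseTree, int]:
        if budget < 4 or (depth > 0 and rng.random() < 0.3):
            leaf = ParseTree(TOKENS[rng.integers(0, len(TOKENS))])
            return ParseTree(NONTERMINALS[rng.integers(0, len(NONTERMINALS))], [leaf]), 2
        n_children = int(rng.integers(1, 4))
        used = 1
        kids = []
        for _ in range(n_children):
            remaining = budget - used
            if remaining < 2:
                break
            sub, u = build(remaining, depth + 1)
            kids.append(sub)
            used += u
        return ParseTree(NONTERMINALS[rng.integers(0, len(NONTERMINALS))], kids), used

    tree, _ = build(budget, 0)
    return tree


def enumerate_fragments(node: ParseTree) -> list[tuple[str, int]]:
    """All subtree fragments rooted at ``node`` as (canonical string, #rules).

    A fragment expands its root's full production and, for each non-leaf
    child, either stops or recursively expands that child's production.
    """
    if node.is_leaf:
        return []
    child_options = []
    for child in node.children:
        options = [(child.label, 0)]
        if not child.is_leaf:
            options += enumerate_fragments(child)
        child_options.append(options)
    out = []
    for combo in itertools.product(*child_options):
        shape = "(" + node.label + " " + " ".join(s for s, _ in combo) + ")"
        rules = 1 + sum(r for _, r in combo)
        out.append((shape, rules))
    return out


def ctk_oracle(t1: ParseTree, t2: ParseTree, lam: float) -> float:
    """Convolution kernel by explicit common-fragment enumeration: each matched
    fragment pair contributes lambda ** (#productions in the fragment)."""

    def all_fragments(tree: ParseTree) -> Counter:
        counts: Counter = Counter()
        for n in tree.iter_nodes():
            for shape, rules in enumerate_fragments(n):
                counts[(shape, rules)] += 1
        return counts

    c1, c2 = all_fragments(t1), all_fragments(t2)
    return float(
        sum(c1[key] * c2[key] * lam ** key[1] for key in c1.keys() & c2.keys())
    )


def matching_total_oracle(W) -> float:
    """Maximum matching weight by exhaustive enumeration of injections."""
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        return 0.0
    if W.shape[0] > W.shape[1]:
        W = W.T
    m, n = W.shape
    best = 0.0
    for cols in itertools.permutations(range(n), m):
        best = max(best, sum(W[i, cols[i]] for i in range(m)))
    return float(best)


def auc_pairwise_oracle(scores, labels) -> float:
    """AUC as the Mann-Whitney pairwise statistic with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
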