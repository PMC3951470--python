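"""Parse-tree pruning (MCT, SPT, dynamic extension) and the convolution tree kernel.

MCT is the subtree rooted at the lowest common ancestor of the two protein
leaves.  SPT is the MCT restricted to the token span between the proteins
(path-enclosed pruning: material between the two spines is kept).  The dynamic
extension keeps the SPT when it is large enough, otherwise widens it to the MCT
or to the subtree rooted at the parent of the SPT root.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus_io import Instance, ParseTree, ensure_masked

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 7
#: The size rule counts syntactic (non-leaf) nodes by default: with all-node
#: counting the canonical 7-token SPT "(NP (NNP PROTEIN_1) (CC and)
#: (NNP PROTEIN_2))" would never trigger the extension.
DEFAULT_NODE_COUNT = "nonleaf"
DEFAULT_LAMBDA = 0.4

STRATEGY_SPT = "SPT"
STRATEGY_MCT = "MCT"
STRATEGY_PARENT = "PARENT"


class ProteinLeafError(ValueError):
    """Raised when a required PROTEIN_1/PROTEIN_2 leaf is absent."""


@dataclass
class PrunedTree:
    tree: ParseTree
    strategy: str
    node_count: int  # total nodes (leaves included) of the returned tree
    provenance: str = ""


def _leaf_paths(parse: ParseTree) -> tuple[list[ParseTree], dict[int, int]]:
    """Return leaves in order plus a map node-id -> width (leaf count)."""
    widths: dict[int, int] = {}
    leaves: list[ParseTree] = []

    def walk(node: ParseTree) -> int:
        if node.is_leaf:
            leaves.append(node)
            widths[id(node)] = 1
            return 1
        w = sum(walk(c) for c in node.children)
        widths[id(node)] = w
        return w

    walk(parse)
    return leaves, widths


def _path_to_leaf(parse: ParseTree, leaf_index: int, widths: dict[int, int]) -> list[ParseTree]:
    """Root-to-leaf node path for the leaf at the given global index."""
    path = [parse]
    node, lo = parse, 0
    while not node.is_leaf:
        for child in node.children:
            w = widths[id(child)]
            if lo <= leaf_index < lo + w:
                path.append(child)
                node = child
                break
            lo += w
    return path


def _protein_indices(parse: ParseTree) -> tuple[int, int]:
    leaves = parse.leaves()
    try:
        i1 = leaves.index("PROTEIN_1")
    except ValueError:
        raise ProteinLeafError("parse has no PROTEIN_1 leaf") from None
    try:
        i2 = leaves.index("PROTEIN_2")
    except ValueError:
        raise ProteinLeafError("parse has no PROTEIN_2 leaf") from None
    return (i1, i2) if i1 < i2 else (i2, i1)


def _lca_info(parse: ParseTree) -> tuple[list[ParseTree], int, int, int]:
    """Return (root->LCA path, lca leaf offset, i1, i2) for the protein leaves."""
    i1, i2 = _protein_indices(parse)
    _, widths = _leaf_paths(parse)
    path1 = _path_to_leaf(parse, i1, widths)
    path2 = _path_to_leaf(parse, i2, widths)
    k = 0
    while k < min(len(path1), len(path2)) and path1[k] is path2[k]:
        k += 1
    spine = path1[:k]  # root..lca inclusive
    lca = spine[-1]
    # leaf offset of the LCA within the full parse
    offset = 0
    node = parse
    for nxt in spine[1:]:
        for child in node.children:
            if child is nxt:
                break
            offset += widths[id(child)]
        node = nxt
    return spine, offset, i1, i2


def mct(parse: ParseTree, provenance: str = "") -> PrunedTree:
    """Minimum complete tree: full subtree at the LCA of the protein leaves."""
    spine, _, _, _ = _lca_info(parse)
    tree = spine[-1]
    return PrunedTree(tree, STRATEGY_MCT, tree.node_count("all"), provenance)


def _prune_to_span(node: ParseTree, lo: int, i1: int, i2: int,
                   widths: dict[int, int]) -> Optional[ParseTree]:
    hi = lo + widths[id(node)]
    if hi <= i1 or lo > i2:
        return None
    if node.is_leaf:
        return ParseTree(node.label)
    kids = []
    off = lo
    for child in node.children:
        pruned = _prune_to_span(child, off, i1, i2, widths)
        off += widths[id(child)]
        if pruned is not None:
            kids.append(pruned)
    return ParseTree(node.label, kids) if kids else None


def spt(parse: ParseTree, provenance: str = "") -> PrunedTree:
    """Path-enclosed tree: MCT restricted to leaves between the two proteins."""
    spine, offset, i1, i2 = _lca_info(parse)
    lca = spine[-1]
    _, widths = _leaf_paths(parse)
    tree = _prune_to_span(lca, offset, i1, i2, widths)
    assert tree is not None
    return PrunedTree(tree, STRATEGY_SPT, tree.node_count("all"), provenance)


def det(
    parse: ParseTree,
    threshold: int = DEFAULT_THRESHOLD,
    node_count: str = DEFAULT_NODE_COUNT,
    provenance: str = "",
) -> PrunedTree:
    """Dynamic extension: SPT when it has >= ``threshold`` nodes, otherwise the
    MCT (when different from the SPT) or the subtree rooted at the parent of
    the SPT root."""
    spine, offset, i1, i2 = _lca_info(parse)
    lca = spine[-1]
    _, widths = _leaf_paths(parse)
    spt_tree = _prune_to_span(lca, offset, i1, i2, widths)
    assert spt_tree is not None
    if spt_tree.node_count(node_count) >= threshold:
        return PrunedTree(spt_tree, STRATEGY_SPT, spt_tree.node_count("all"), provenance)
    if spt_tree != lca:
        return PrunedTree(lca, STRATEGY_MCT, lca.node_count("all"), provenance)
    if len(spine) < 2:
        logger.warning(
            "%s: SPT root is the parse root and cannot be extended; keeping SPT",
            provenance or "instance",
        )
        return PrunedTree(spt_tree, STRATEGY_SPT, spt_tree.node_count("all"), provenance)
    parent = spine[-2]
    return PrunedTree(parent, STRATEGY_PARENT, parent.node_count("all"), provenance)


def prune(
    parse: ParseTree,
    strategy: str = "DET",
    threshold: int = DEFAULT_THRESHOLD,
    node_count: str = DEFAULT_NODE_COUNT,
    provenance: str = "",
) -> PrunedTree:
    if strategy == "MCT":
        return mct(parse, provenance)
    if strategy == "SPT":
        return spt(parse, provenance)
    if strategy == "DET":
        return det(parse, threshold, node_count, provenance)
    raise ValueError(f"unknown pruning strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Convolution tree kernel
# ---------------------------------------------------------------------------


def _production(node: ParseTree) -> tuple:
    return (node.label, tuple(c.label for c in node.children))


def ctk(t1: ParseTree, t2: ParseTree, lam: float = DEFAULT_LAMBDA) -> float:
    """Collins–Duffy convolution kernel: decayed count of common subtree fragments.

    C(n1, n2) = 0 when productions differ, else
    lambda * prod_j (1 + C(child_j(n1), child_j(n2))), with C = 0 over leaves.
    """
    if not (0.0 < lam <= 1.0):
        raise ValueError(f"lambda must be in (0, 1], got {lam}")
    internal1 = [n for n in t1.iter_nodes() if not n.is_leaf]
    by_prod: dict[tuple, list[ParseTree]] = {}
    for n in t2.iter_nodes():
        if not n.is_leaf:
            by_prod.setdefault(_production(n), []).append(n)
    memo: dict[tuple[int, int], float] = {}

    def C(n1: ParseTree, n2: ParseTree) -> float:
        key = (id(n1), id(n2))
        if key in memo:
            return memo[key]
        if _production(n1) != _production(n2):
            memo[key] = 0.0
            return 0.0
        value = lam
        for c1, c2 in zip(n1.children, n2.children):
            if not c1.is_leaf:
                value *= 1.0 + C(c1, c2)
        memo[key] = value
        return value

    total = 0.0
    for n1 in internal1:
        for n2 in by_prod.get(_production(n1), ()):
            total += C(n1, n2)
    return total


def normalized_ctk(
    t1: ParseTree,
    t2: ParseTree,
    lam: float = DEFAULT_LAMBDA,
    self1: Optional[float] = None,
    self2: Optional[float] = None,
) -> float:
    """ctk normalized to unit self-similarity; 0 for degenerate trees."""
    if self1 is None:
        self1 = ctk(t1, t1, lam)
    if self2 is None:
        self2 = ctk(t2, t2, lam)
    if self1 <= 0.0 or self2 <= 0.0:
        logger.warning("degenerate tree with zero self-kernel; similarity set to 0")
        return 0.0
    return ctk(t1, t2, lam) / math.sqrt(self1 * self2)


def k_det(
    x: Instance,
    y: Instance,
    lam: float = DEFAULT_LAMBDA,
    threshold: int = DEFAULT_THRESHOLD,
    node_count: str = DEFAULT_NODE_COUNT,
) -> float:
    """Normalized convolution kernel on dynamically extended trees."""
    tx = det(ensure_masked(x).parse, threshold, node_count, x.id).tree
    ty = det(ensure_masked(y).parse, threshold, node_count, y.id).tree
    return normalized_ctk(tx, ty, lam)


def gram_det(
    instances: Sequence[Instance],
    lam: float = DEFAULT_LAMBDA,
    threshold: int = DEFAULT_THRESHOLD,
    node_count: str = DEFAULT_NODE_COUNT,
    strategy: str = "DET",
) -> np.ndarray:
    """Gram matrix of the normalized tree kernel over pruned trees."""
    trees = [
        prune(ensure_masked(inst).parse, strategy, threshold, node_count, inst.id).tree
        for inst in instances
    ]
    n = len(trees)
    selfs = np.array([ctk(t, t, lam) for t in trees])
    K = np.eye(n)
    for i in range(n):
        if selfs[i] <= 0.0:
            K[i, i] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if selfs[i] <= 0.0 or selfs[j] <= 0.0:
                value = 0.0
            else:
                value = ctk(trees[i], trees[j], lam) / math.sqrt(selfs[i] * selfs[j])
            K[i, j] = K[j, i] = value
    return K
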