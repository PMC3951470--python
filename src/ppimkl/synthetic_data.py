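"""Seeded synthetic corpora and toy taxonomies with controllable signal.

The generator builds template sentences around a candidate protein pair.
``keyword_signal`` gates every lexical/syntactic cue tied to the label: an
interaction keyword between the pair, a verb-phrase attachment of that keyword,
and a shorter between-span.  ``taxonomy_signal`` gates whether a positive
pair's concepts are taxonomic siblings.  With both signals at zero the
instance distribution is label-independent, so every kernel's cross-validated
AUC sits at chance.

Labels are assigned by quota (exact positive count), not by Bernoulli draws,
so tests are deterministic.  All randomness flows from one seeded generator;
corpus serialization is byte-identical per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .corpus_io import (
    EntityMention,
    Instance,
    ParseTree,
    TaxonomyFile,
    Token,
    validate_instance,
)
from .feature_kernel import DEFAULT_KEYWORDS

#: Baseline rate (relative to keyword_signal) at which negatives carry cues.
NEGATIVE_CUE_FACTOR = 0.3
INSTANCES_PER_DOC = 5


@dataclass
class GenConfig:
    n_instances: int = 100
    positive_rate: float = 0.3
    keyword_signal: float = 0.8
    taxonomy_signal: float = 0.8
    distance_noise: float = 0.3
    vocab_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instances < 10:
            raise ValueError("n_instances must be >= 10")
        if not (0.0 < self.positive_rate < 1.0):
            raise ValueError("positive_rate must be in (0, 1)")
        for name in ("keyword_signal", "taxonomy_signal", "distance_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.vocab_size < 5:
            raise ValueError("vocab_size must be >= 5")


def gen_taxonomy(depth: int, branching: int, seed: int, prefix: str = "c") -> TaxonomyFile:
    """Complete rooted tree of the given depth/branching with power-law counts."""
    if depth < 2 or branching < 2:
        raise ValueError("depth and branching must both be >= 2")
    rng = np.random.default_rng(seed)
    concepts = [f"{prefix}0"]
    edges: list[tuple[str, str]] = []
    level = [f"{prefix}0"]
    next_id = 1
    for _ in range(depth - 1):
        nxt = []
        for parent in level:
            for _ in range(branching):
                cid = f"{prefix}{next_id}"
                next_id += 1
                concepts.append(cid)
                edges.append((cid, parent))
                nxt.append(cid)
        level = nxt
    frequencies = {
        cid: float(int(rng.pareto(1.5) * 10.0) + 1) for cid in concepts
    }
    tf = TaxonomyFile(concepts=set(concepts), edges=edges, frequencies=frequencies)
    tf.validate()
    return tf


def gen_word_taxonomy(cfg: GenConfig, seed: Optional[int] = None) -> TaxonomyFile:
    """Word-level taxonomy: keywords grouped under one node, filler vocabulary
    split into topic groups.  Concept ids are the words themselves."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    root = "w_root"
    concepts = {root}
    edges: list[tuple[str, str]] = []
    frequencies: dict[str, float] = {root: 0.0}

    def add(child: str, parent: str, freq: float = 0.0) -> None:
        concepts.add(child)
        edges.append((child, parent))
        frequencies[child] = freq

    add("w_kw", root)
    for kw in DEFAULT_KEYWORDS:
        add(kw, "w_kw", float(rng.integers(1, 20)))
    n_topics = max(2, cfg.vocab_size // 10)
    for t in range(n_topics):
        add(f"w_topic{t}", root)
    for k in range(cfg.vocab_size):
        add(f"w{k}", f"w_topic{k % n_topics}", float(rng.integers(1, 20)))
    for k in range(cfg.vocab_size):
        add(f"v{k}", f"w_topic{(k + 1) % n_topics}", float(rng.integers(1, 20)))
    tf = TaxonomyFile(concepts=concepts, edges=edges, frequencies=frequencies)
    tf.validate()
    return tf


def _leaf_groups(tax: TaxonomyFile) -> tuple[list[str], dict[str, list[str]]]:
    """Leaves of the taxonomy and leaves grouped by parent (sibling pools)."""
    parents = {c for _, c in tax.edges}
    leaves = sorted(c for c in tax.concepts if c not in parents)
    by_parent: dict[str, list[str]] = {}
    for child, parent in sorted(tax.edges):
        if child in leaves:
            by_parent.setdefault(parent, []).append(child)
    sibling_pools = {p: ls for p, ls in by_parent.items() if len(ls) >= 2}
    return leaves, sibling_pools


def _build_instance(
    idx: int,
    label: int,
    cfg: GenConfig,
    rng: np.random.Generator,
    leaves: list[str],
    sibling_pools: dict[str, list[str]],
) -> Instance:
    def filler(tag: str = "w") -> str:
        return f"{tag}{rng.integers(0, cfg.vocab_size)}"

    cue = rng.random() < (
        cfg.keyword_signal if label == 1 else cfg.keyword_signal * NEGATIVE_CUE_FACTOR
    )
    # between-span length: cued instances sit close together
    n_mid = int(rng.integers(0, 2)) if cue else int(rng.integers(2, 7))
    if rng.random() < cfg.distance_noise:
        n_mid += int(rng.integers(0, 4))
    n_pre = int(rng.integers(0, 3))
    n_post = int(rng.integers(0, 3))
    verb = str(rng.choice(DEFAULT_KEYWORDS)) if cue else filler("v")

    p1_name = [f"PR{idx}A"]
    if rng.random() < 0.15:
        p1_name.append("alpha")
    p2_name = [f"PR{idx}B"]

    pre = [filler() for _ in range(n_pre)]
    mids = [filler() for _ in range(n_mid)]
    other_name: Optional[str] = None
    if rng.random() < 0.2:
        other_name = f"PR{idx}X"
        mids.insert(int(rng.integers(0, len(mids) + 1)), other_name)
    post = [filler() for _ in range(n_post)]

    tokens = pre + p1_name + [verb] + mids + p2_name + post

    # template parse: (S (NP pre* P1) (VP (V verb) (NP mid* P2 post*)))
    def pt(tag: str, word: str) -> ParseTree:
        return ParseTree(tag, [ParseTree(word)])

    if len(p1_name) == 1:
        p1_nodes = [pt("NNP", p1_name[0])]
    else:
        p1_nodes = [ParseTree("NP", [pt("NNP", w) for w in p1_name])]
    np1 = ParseTree("NP", [pt("NN", w) for w in pre] + p1_nodes)
    obj_kids = (
        [pt("NNP" if w == other_name else "NN", w) for w in mids]
        + [pt("NNP", p2_name[0])]
        + [pt("NN", w) for w in post]
    )
    vp = ParseTree(
        "VP", [pt("VBP" if cue else "VBZ", verb), ParseTree("NP", obj_kids)]
    )
    parse = ParseTree("S", [np1, vp])

    # entity spans over the token list
    p1_start = len(pre)
    p1_end = p1_start + len(p1_name)
    p2_start = p1_end + 1 + len(mids)
    entities = []
    # concepts
    if label == 1 and rng.random() < cfg.taxonomy_signal:
        # interacting pairs cluster in a few "protein family" branches so that
        # positive instances are taxonomically close to one another as well
        pool_names = sorted(sibling_pools)[: max(1, len(sibling_pools) // 3)]
        pool = sibling_pools[pool_names[int(rng.integers(0, len(pool_names)))]]
        c1, c2 = (str(c) for c in rng.choice(pool, size=2, replace=False))
    else:
        c1, c2 = (str(c) for c in rng.choice(leaves, size=2, replace=False))
    entities.append(EntityMention(p1_start, p1_end, "P1", concept_id=c1))
    entities.append(EntityMention(p2_start, p2_start + 1, "P2", concept_id=c2))
    if other_name is not None:
        pos = tokens.index(other_name)
        entities.append(EntityMention(pos, pos + 1, "OTHER"))

    inst = Instance(
        id=f"inst{idx:05d}",
        doc_id=f"d{idx // INSTANCES_PER_DOC}",
        tokens=[Token(t, i) for i, t in enumerate(tokens)],
        entities=entities,
        parse=parse,
        label=label,
    )
    validate_instance(inst)
    return inst


def gen_corpus(cfg: GenConfig, tax: TaxonomyFile) -> list[Instance]:
    """Generate a corpus of validated instances; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_instances
    n_pos = round(n * cfg.positive_rate)
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    leaves, sibling_pools = _leaf_groups(tax)
    if len(leaves) < 2 or not sibling_pools:
        raise ValueError("taxonomy needs >= 2 leaves including one sibling pair")
    return [
        _build_instance(i, int(labels[i]), cfg, rng, leaves, sibling_pools)
        for i in range(n)
    ]
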