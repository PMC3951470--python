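import numpy as np
import pytest

from ppimkl.corpus_io import (
    EntityMention,
    Instance,
    ParseTree,
    Token,
    parse_ptb,
)
from ppimkl.semantic_sim import Taxonomy
from ppimkl.synthetic_data import GenConfig, gen_corpus, gen_taxonomy, gen_word_taxonomy


def make_instance(
    tokens,
    p1,
    p2,
    others=(),
    parse=None,
    label=1,
    inst_id="i0",
    doc_id="d0",
    concepts=(None, None),
):
    """Hand-built instance; default parse is a flat (S (X tok) ...) scaffold."""
    if parse is None:
        parse = ParseTree("S", [ParseTree("X", [ParseTree(t)]) for t in tokens])
    entities = [
        EntityMention(p1[0], p1[1], "P1", concept_id=concepts[0]),
        EntityMention(p2[0], p2[1], "P2", concept_id=concepts[1]),
    ]
    for start, end in others:
        entities.append(EntityMention(start, end, "OTHER"))
    return Instance(
        id=inst_id,
        doc_id=doc_id,
        tokens=[Token(t, i) for i, t in enumerate(tokens)],
        entities=entities,
        parse=parse,
        label=label,
    )


@pytest.fixture()
def worked_trees():
    """The worked pruning example: full parse, its SPT and extended tree."""
    spt_str = "(NP (NNP PROTEIN_1) (CC and) (NNP PROTEIN_2))"
    det_str = (
        "(S (NP (NNP PROTEIN_1) (CC and) (NNP PROTEIN_2)) "
        "(VP (VBP interact) (PP (IN with) (NP (DT each) (JJ other)))))"
    )
    return {"full": parse_ptb(det_str), "spt": spt_str, "det": det_str}


TOY_EDGES = [
    ("a", "r"), ("b", "r"),
    ("a1", "a"), ("a2", "a"),
    ("b1", "b"), ("b2", "b"),
]
TOY_FREQS = {"r": 0.0, "a": 2.0, "b": 4.0, "a1": 3.0, "a2": 1.0, "b1": 5.0, "b2": 5.0}


@pytest.fixture()
def toy_taxonomy():
    """7-concept tree: root r, inner a/b, leaves a1 a2 b1 b2."""
    return Taxonomy(TOY_EDGES, TOY_FREQS)


@pytest.fixture(scope="session")
def synthetic_bundle():
    """A 100-instance corpus with taxonomies, shared across tests."""
    cfg = GenConfig(n_instances=100, seed=7)
    tax = gen_taxonomy(4, 3, seed=7)
    word_tax = gen_word_taxonomy(cfg)
    corpus = gen_corpus(cfg, tax)
    return {
        "cfg": cfg,
        "tax_file": tax,
        "word_tax_file": word_tax,
        "tax": Taxonomy.from_file(tax),
        "word_tax": Taxonomy.from_file(word_tax),
        "corpus": corpus,
    }
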