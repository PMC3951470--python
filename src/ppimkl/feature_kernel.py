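"""Lexical word/distance features and the cosine feature kernel.

Feature groups per instance: words inside the two protein names, words between
them, words in a surrounding window, a single interaction-keyword feature, a
binned between-distance, and a count of other proteins between the pair.  The
kernel is cosine similarity over the one-hot encoding of the union of groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus_io import Instance, ensure_masked

#: Interaction keyword lemmas printed in the method description, plus their
#: common morphological variants.  Overridable via a keyword file.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "interact", "interacts", "interacted", "interacting", "interaction", "interactions",
    "regulate", "regulates", "regulated", "regulating", "regulation",
    "modulate", "modulates", "modulated", "modulating", "modulation",
)

NULL = "NULL"
DEFAULT_WINDOW = 5


def load_keywords(path: str | Path) -> list[str]:
    """One lowercase keyword per line; blank lines ignored."""
    keywords = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.strip().lower()
            if word:
                keywords.append(word)
    if not keywords:
        raise ValueError(f"keyword file {path} is empty")
    return keywords


def _fold(token: str) -> str:
    """Lowercase, except the PROTEIN placeholders which stay verbatim."""
    return token if token.startswith("PROTEIN") else token.lower()


@dataclass(frozen=True)
class FeatureVector:
    """Named sparse features for one instance."""

    words_in_proteins: frozenset[str]
    words_between: frozenset[str]
    words_surrounding: frozenset[str]
    interaction_term: str
    word_num_bin: str
    protein_count: int

    def items(self) -> frozenset[str]:
        """One-hot encoding: each active feature as a 'group=value' atom."""
        atoms = set()
        atoms.update(f"p={w}" for w in self.words_in_proteins)
        atoms.update(f"b={w}" for w in self.words_between)
        atoms.update(f"s={w}" for w in self.words_surrounding)
        atoms.add(f"kw={self.interaction_term}")
        atoms.add(f"bin={self.word_num_bin}")
        atoms.add(f"pc={self.protein_count}")
        return frozenset(atoms)


def words_features(
    inst: Instance, window: int = DEFAULT_WINDOW
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Word-feature groups 1-3: in-protein, between, surrounding.

    Empty between/surrounding groups carry the "NULL" sentinel.
    """
    inst = ensure_masked(inst)
    p1, p2 = inst.entity("P1"), inst.entity("P2")
    texts = inst.token_texts()

    in_proteins: set[str] = set()
    for ent in (p1, p2):
        surface = ent.surface if ent.surface else tuple(texts[ent.start:ent.end])
        in_proteins.update(_fold(w) for w in surface)

    between = {_fold(w) for w in texts[p1.end:p2.start]}
    if not between:
        between = {NULL}

    left = texts[max(0, p1.start - window):p1.start]
    right = texts[p2.end:p2.end + window]
    surrounding = {_fold(w) for w in left + right}
    if not surrounding:
        surrounding = {NULL}

    return frozenset(in_proteins), frozenset(between), frozenset(surrounding)


def interaction_term(
    inst: Instance,
    keywords: Optional[Sequence[str]] = None,
    window: int = DEFAULT_WINDOW,
) -> str:
    """First interaction keyword between the pair, then in the surrounding window.

    Between-words are scanned first (in sentence order), then the left window of
    P1 and the right window of P2; "NULL" if no keyword matches.
    """
    inst = ensure_masked(inst)
    kwset = {k.lower() for k in (keywords if keywords is not None else DEFAULT_KEYWORDS)}
    p1, p2 = inst.entity("P1"), inst.entity("P2")
    texts = inst.token_texts()
    scan = (
        texts[p1.end:p2.start]
        + texts[max(0, p1.start - window):p1.start]
        + texts[p2.end:p2.end + window]
    )
    for token in scan:
        word = token.lower()
        if word in kwset:
            return word
    return NULL


def distance_features(inst: Instance) -> tuple[str, int]:
    """Binned count of non-protein words between the pair, and count of other
    proteins between the pair."""
    inst = ensure_masked(inst)
    p1, p2 = inst.entity("P1"), inst.entity("P2")
    others_between = [e for e in inst.others() if p1.end <= e.start and e.end <= p2.start]
    protein_tokens = sum(e.end - e.start for e in others_between)
    word_num = (p2.start - p1.end) - protein_tokens
    if word_num <= 3:
        word_num_bin = "1"
    elif word_num <= 6:
        word_num_bin = "2"
    elif word_num <= 9:
        word_num_bin = "3"
    else:
        word_num_bin = "4"
    return word_num_bin, len(others_between)


def extract_features(
    inst: Instance,
    keywords: Optional[Sequence[str]] = None,
    window: int = DEFAULT_WINDOW,
) -> FeatureVector:
    inst = ensure_masked(inst)
    g1, g2, g3 = words_features(inst, window)
    word_num_bin, protein_count = distance_features(inst)
    return FeatureVector(
        words_in_proteins=g1,
        words_between=g2,
        words_surrounding=g3,
        interaction_term=interaction_term(inst, keywords, window),
        word_num_bin=word_num_bin,
        protein_count=protein_count,
    )


def k_fea(x: FeatureVector, y: FeatureVector) -> float:
    """Cosine similarity of one-hot feature encodings; symmetric, in [0, 1]."""
    xs, ys = x.items(), y.items()
    if not xs or not ys:
        raise ValueError("empty feature vector")
    return len(xs & ys) / math.sqrt(len(xs) * len(ys))


def gram_fea(
    instances: Sequence[Instance],
    keywords: Optional[Sequence[str]] = None,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Feature-kernel Gram matrix (unit diagonal, PSD by construction)."""
    vectors = [extract_features(inst, keywords, window) for inst in instances]
    vocab: dict[str, int] = {}
    for v in vectors:
        for atom in sorted(v.items()):
            vocab.setdefault(atom, len(vocab))
    M = np.zeros((len(vectors), len(vocab)))
    for i, v in enumerate(vectors):
        for atom in v.items():
            M[i, vocab[atom]] = 1.0
    norms = np.sqrt((M * M).sum(axis=1))
    K = (M @ M.T) / np.outer(norms, norms)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return K
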