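"""Instance data model, Penn-Treebank tree I/O, taxonomy files and protein masking.

The corpus format is JSONL: one record per candidate protein pair, carrying the
tokenized sentence, entity spans, a bracketed constituency parse and a binary
interaction label.  Trees are plain rooted ordered labeled trees; leaves are
word tokens and their left-to-right order must match the sentence tokens.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"

#: Placeholder tokens substituted for protein mentions, by entity role.
PLACEHOLDERS = {"P1": "PROTEIN_1", "P2": "PROTEIN_2", "OTHER": "PROTEIN"}
ROLES = ("P1", "P2", "OTHER")

#: Node-counting conventions for pruned-tree size rules.
NODE_COUNT_MODES = ("all", "nonleaf", "leaves")


class PTBParseError(ValueError):
    """Raised on malformed bracketed-tree input."""


class CorpusError(ValueError):
    """Raised when a corpus record violates an Instance invariant."""


class TaxonomyError(ValueError):
    """Raised when a taxonomy file is not a rooted acyclic hierarchy."""


# ---------------------------------------------------------------------------
# Parse trees
# ---------------------------------------------------------------------------


@dataclass
class ParseTree:
    """Rooted ordered labeled tree.  A node with no children is a leaf token."""

    label: str
    children: list["ParseTree"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_preterminal(self) -> bool:
        return len(self.children) == 1 and self.children[0].is_leaf

    def iter_nodes(self) -> Iterator["ParseTree"]:
        """Pre-order traversal over all nodes (including leaves)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[str]:
        return [n.label for n in self.iter_nodes() if n.is_leaf]

    def node_count(self, mode: str = "all") -> int:
        """Count nodes under ``mode``: every node, non-leaf nodes only, or leaves only."""
        if mode not in NODE_COUNT_MODES:
            raise ValueError(f"unknown node-count mode {mode!r}; choose from {NODE_COUNT_MODES}")
        if mode == "all":
            return sum(1 for _ in self.iter_nodes())
        if mode == "nonleaf":
            return sum(1 for n in self.iter_nodes() if not n.is_leaf)
        return sum(1 for n in self.iter_nodes() if n.is_leaf)

    def copy(self) -> "ParseTree":
        return ParseTree(self.label, [c.copy() for c in self.children])


def _tokenize_ptb(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "()":
            tokens.append((ch, i))
            i += 1
        elif ch.isspace():
            i += 1
        else:
            j = i
            while j < len(text) and not text[j].isspace() and text[j] not in "()":
                j += 1
            tokens.append((text[i:j], i))
            i = j
    return tokens


def parse_ptb(text: str) -> ParseTree:
    """Parse a Penn-Treebank bracketed string into a :class:`ParseTree`.

    Raises :class:`PTBParseError` naming the character offset on unbalanced or
    malformed input.
    """
    tokens = _tokenize_ptb(text)
    if not tokens:
        raise PTBParseError("empty input")
    pos = 0

    def parse_node() -> ParseTree:
        nonlocal pos
        tok, off = tokens[pos]
        if tok == "(":
            open_off = off
            pos += 1
            if pos >= len(tokens) or tokens[pos][0] in "()":
                raise PTBParseError(f"expected node label after '(' at offset {open_off}")
            label = tokens[pos][0]
            pos += 1
            children: list[ParseTree] = []
            while pos < len(tokens) and tokens[pos][0] != ")":
                children.append(parse_node())
            if pos >= len(tokens):
                raise PTBParseError(
                    f"unbalanced parentheses: missing ')' for '(' at offset {open_off}"
                )
            pos += 1  # consume ')'
            if not children:
                raise PTBParseError(f"node {label!r} at offset {open_off} has no children")
            return ParseTree(label, children)
        if tok == ")":
            raise PTBParseError(f"unbalanced parentheses: unexpected ')' at offset {off}")
        pos += 1
        return ParseTree(tok)

    tree = parse_node()
    if pos != len(tokens):
        _, off = tokens[pos]
        raise PTBParseError(f"unexpected trailing content at offset {off}")
    if tree.is_leaf:
        raise PTBParseError("top-level tree must be bracketed, got a bare token")
    return tree


def write_ptb(tree: ParseTree) -> str:
    """Serialize a tree back to single-space bracketed notation.

    Inverse of :func:`parse_ptb` up to whitespace normalization; writes are
    bit-exact (deterministic single spacing).
    """
    if tree.is_leaf:
        return tree.label
    inner = " ".join(write_ptb(c) for c in tree.children)
    return f"({tree.label} {inner})"


# ---------------------------------------------------------------------------
# Instances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    text: str
    index: int


@dataclass
class EntityMention:
    """Half-open token span [start, end) with a role in {P1, P2, OTHER}.

    ``surface`` keeps the pre-masking tokens of the mention so lexical features
    can still see the original protein name after masking.
    """

    start: int
    end: int
    role: str
    concept_id: Optional[str] = None
    surface: Optional[tuple[str, ...]] = None


@dataclass
class Instance:
    """One candidate protein pair in one sentence."""

    id: str
    doc_id: str
    tokens: list[Token]
    entities: list[EntityMention]
    parse: ParseTree
    label: int
    masked: bool = False

    def token_texts(self) -> list[str]:
        return [t.text for t in self.tokens]

    def entity(self, role: str) -> EntityMention:
        for e in self.entities:
            if e.role == role:
                return e
        raise CorpusError(f"instance {self.id}: no entity with role {role}")

    def others(self) -> list[EntityMention]:
        return [e for e in self.entities if e.role == "OTHER"]


def validate_instance(inst: Instance) -> None:
    """Check every Instance invariant; raise :class:`CorpusError` listing failures."""
    problems: list[str] = []
    n = len(inst.tokens)
    if n == 0:
        problems.append("no tokens")
    for t in inst.tokens:
        if not t.text:
            problems.append(f"empty token at index {t.index}")
    if [t.index for t in inst.tokens] != list(range(n)):
        problems.append("token indices not contiguous from 0")
    if not inst.doc_id:
        problems.append("missing doc_id")
    if inst.label not in (0, 1):
        problems.append(f"label must be 0 or 1, got {inst.label!r}")

    roles = [e.role for e in inst.entities]
    for r in roles:
        if r not in ROLES:
            problems.append(f"unknown entity role {r!r}")
    if roles.count("P1") != 1 or roles.count("P2") != 1:
        problems.append("must have exactly one P1 and one P2 entity")
    for e in inst.entities:
        if not (0 <= e.start < e.end <= n):
            problems.append(f"span [{e.start},{e.end}) out of bounds for {n} tokens")
    if roles.count("P1") == 1 and roles.count("P2") == 1:
        p1, p2 = inst.entity("P1"), inst.entity("P2")
        if not p1.start < p2.start:
            problems.append("P1 span must precede P2 span")
        if p1.end > p2.start:
            problems.append("P1 and P2 spans overlap")
    spans = sorted((e.start, e.end) for e in inst.entities)
    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            problems.append(f"overlapping entity spans at token {s2}")
            break
    if inst.parse is None:
        problems.append("missing parse")
    elif inst.parse.leaves() != inst.token_texts():
        problems.append("parse leaves do not equal sentence tokens")
    if problems:
        raise CorpusError(f"instance {inst.id}: " + "; ".join(problems))


def instance_to_record(inst: Instance) -> dict:
    entities = []
    for e in inst.entities:
        rec: dict = {"start": e.start, "end": e.end, "role": e.role}
        if e.concept_id is not None:
            rec["concept_id"] = e.concept_id
        if e.surface is not None:
            rec["surface"] = list(e.surface)
        entities.append(rec)
    return {
        "format_version": FORMAT_VERSION,
        "id": inst.id,
        "doc_id": inst.doc_id,
        "tokens": inst.token_texts(),
        "entities": entities,
        "parse": write_ptb(inst.parse),
        "label": inst.label,
        "masked": inst.masked,
    }


def instance_from_record(record: dict) -> Instance:
    rid = record.get("id", "<missing id>")
    for key in ("id", "doc_id", "tokens", "entities", "label"):
        if key not in record:
            raise CorpusError(f"record {rid}: missing field {key!r}")
    if "parse" not in record or not record["parse"]:
        raise CorpusError(f"record {rid}: missing parse")
    try:
        parse = parse_ptb(record["parse"])
    except PTBParseError as exc:
        raise CorpusError(f"record {rid}: bad parse: {exc}") from exc
    tokens = [Token(text, i) for i, text in enumerate(record["tokens"])]
    entities = [
        EntityMention(
            start=e["start"],
            end=e["end"],
            role=e["role"],
            concept_id=e.get("concept_id"),
            surface=tuple(e["surface"]) if e.get("surface") is not None else None,
        )
        for e in record["entities"]
    ]
    inst = Instance(
        id=record["id"],
        doc_id=record["doc_id"],
        tokens=tokens,
        entities=entities,
        parse=parse,
        label=int(record["label"]),
        masked=bool(record.get("masked", False)),
    )
    validate_instance(inst)
    return inst


def read_corpus(path: str | Path) -> list[Instance]:
    """Read a JSONL corpus, validating every record; errors name the record id."""
    instances = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: invalid JSON: {exc}") from exc
            instances.append(instance_from_record(record))
    logger.info("read %d instances from %s", len(instances), path)
    return instances


def write_corpus(instances: Iterable[Instance], path: str | Path) -> None:
    """Write a JSONL corpus deterministically (sorted keys, compact separators)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for inst in instances:
            fh.write(json.dumps(instance_to_record(inst), sort_keys=True, separators=(",", ":")))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------


def mask_proteins(inst: Instance) -> Instance:
    """Replace protein mentions with placeholder tokens, in tokens and parse.

    P1 becomes a single PROTEIN_1 token, P2 becomes PROTEIN_2 and every OTHER
    mention becomes PROTEIN.  A multi-token mention collapses to one leaf under
    its lowest exactly-dominating node; when no single node dominates the span
    exactly, the leftmost leaf is replaced and the rest deleted (with a
    warning).  Idempotent.
    """
    validate_instance(inst)
    spans = sorted(
        ((e.start, e.end, PLACEHOLDERS[e.role], e) for e in inst.entities),
        key=lambda s: s[0],
    )

    # Which spans have an exactly-covering tree node?  (for fallback warnings)
    widths: dict[int, int] = {}

    def width(node: ParseTree) -> int:
        key = id(node)
        if key not in widths:
            widths[key] = 1 if node.is_leaf else sum(width(c) for c in node.children)
        return widths[key]

    covered: set[int] = set()

    def scan(node: ParseTree, lo: int) -> None:
        hi = lo + width(node)
        for k, (s, e, _, _) in enumerate(spans):
            if (lo, hi) == (s, e):
                covered.add(k)
        off = lo
        for c in node.children:
            scan(c, off)
            off += width(c)

    scan(inst.parse, 0)
    for k, (s, e, _, ent) in enumerate(spans):
        if k not in covered and e - s > 1:
            logger.warning(
                "instance %s: %s span [%d,%d) not dominated by a single node; "
                "keeping leftmost leaf only",
                inst.id, ent.role, s, e,
            )

    def span_at(lo: int, hi: int) -> Optional[tuple[int, int, str, EntityMention]]:
        for s, e, ph, ent in spans:
            if (lo, hi) == (s, e):
                return (s, e, ph, ent)
        return None

    def rebuild(node: ParseTree, lo: int) -> Optional[ParseTree]:
        hi = lo + width(node)
        exact = span_at(lo, hi)
        if node.is_leaf:
            for s, e, ph, _ in spans:
                if s <= lo < e:
                    return ParseTree(ph) if lo == s else None
            return ParseTree(node.label)
        if exact is not None:
            # Collapse at the LOWEST exactly-covering node: recurse while a
            # single child still covers the whole span.
            if not any(width(c) == hi - lo for c in node.children):
                return ParseTree(node.label, [ParseTree(exact[2])])
        kids = []
        off = lo
        for c in node.children:
            new = rebuild(c, off)
            off += width(c)
            if new is not None:
                kids.append(new)
        if not kids:
            return None
        return ParseTree(node.label, kids)

    new_parse = rebuild(inst.parse, 0)
    if new_parse is None:  # pragma: no cover - impossible for valid instances
        raise CorpusError(f"instance {inst.id}: masking deleted the whole tree")

    # Rebuild tokens and entity spans.
    old_texts = inst.token_texts()
    new_texts: list[str] = []
    new_entities: list[EntityMention] = []
    i = 0
    span_iter = {s: (e, ph, ent) for s, e, ph, ent in spans}
    while i < len(old_texts):
        if i in span_iter:
            e, ph, ent = span_iter[i]
            pos = len(new_texts)
            new_texts.append(ph)
            surface = ent.surface if ent.surface is not None else tuple(old_texts[i:e])
            new_entities.append(
                EntityMention(pos, pos + 1, ent.role, ent.concept_id, surface)
            )
            i = e
        else:
            new_texts.append(old_texts[i])
            i += 1

    masked = Instance(
        id=inst.id,
        doc_id=inst.doc_id,
        tokens=[Token(t, i) for i, t in enumerate(new_texts)],
        entities=new_entities,
        parse=new_parse,
        label=inst.label,
        masked=True,
    )
    if masked.parse.leaves() != masked.token_texts():
        raise CorpusError(
            f"instance {inst.id}: masked parse leaves diverge from masked tokens"
        )
    return masked


def ensure_masked(inst: Instance) -> Instance:
    return inst if inst.masked else mask_proteins(inst)


# ---------------------------------------------------------------------------
# Taxonomy files
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyFile:
    """Edge-list taxonomy: child->parent pairs plus per-concept counts."""

    concepts: set[str]
    edges: list[tuple[str, str]]
    frequencies: dict[str, float]

    def validate(self) -> str:
        """Check rootedness/acyclicity and frequency keys; return the root id."""
        known = set(self.concepts)
        for child, parent in self.edges:
            known.add(child)
            known.add(parent)
        for concept in self.frequencies:
            if concept not in known:
                raise TaxonomyError(f"frequency for unknown concept {concept!r}")
        parents: dict[str, set[str]] = {c: set() for c in known}
        for child, parent in self.edges:
            parents[child].add(parent)
        roots = [c for c in sorted(known) if not parents[c]]
        if len(roots) != 1:
            raise TaxonomyError(f"taxonomy must have exactly one root, found {roots}")
        # cycle check: walk up from every node
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {c: WHITE for c in known}

        def visit(c: str) -> None:
            color[c] = GRAY
            for p in parents[c]:
                if color[p] == GRAY:
                    raise TaxonomyError(f"cycle through concept {c!r}")
                if color[p] == WHITE:
                    visit(p)
            color[c] = BLACK

        for c in known:
            if color[c] == WHITE:
                visit(c)
        return roots[0]


def read_taxonomy(edges_path: str | Path, freq_path: str | Path) -> TaxonomyFile:
    """Read a taxonomy from TSV edge list (child TAB parent) + frequency table."""
    edges: list[tuple[str, str]] = []
    concepts: set[str] = set()
    with open(edges_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TaxonomyError(f"{edges_path}:{lineno}: expected 'child<TAB>parent'")
            edges.append((parts[0], parts[1]))
            concepts.update(parts)
    frequencies: dict[str, float] = {}
    with open(freq_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TaxonomyError(f"{freq_path}:{lineno}: expected 'concept<TAB>count'")
            frequencies[parts[0]] = float(parts[1])
            concepts.add(parts[0])
    tf = TaxonomyFile(concepts=concepts, edges=edges, frequencies=frequencies)
    tf.validate()
    return tf


def write_taxonomy(tf: TaxonomyFile, edges_path: str | Path, freq_path: str | Path) -> None:
    with open(edges_path, "w", encoding="utf-8", newline="\n") as fh:
        for child, parent in sorted(tf.edges):
            fh.write(f"{child}\t{parent}\n")
    with open(freq_path, "w", encoding="utf-8", newline="\n") as fh:
        for concept in sorted(tf.frequencies):
            freq = tf.frequencies[concept]
            fh.write(f"{concept}\t{freq:g}\n")
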