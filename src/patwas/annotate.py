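"""Token- and sequence-level annotation.

Token-level tags (cardinal numbers, stems, part-of-speech) raise recall: a
pattern position may later match any tag of a token, not just its surface.
Sequence-level annotation raises specificity by fusing multi-token spans —
vocabulary concepts replace their tokens with a single unigram; parse-tree
constituents register group tokens alongside the originals.

POS tags and constituency parses are consumed from pre-annotation files
(CoNLL-style token/tag lines, or one Penn-bracketed tree per line); no
tagger or parser is bundled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .corpus import Corpus, GroupSpan, Sentence, Token
from .stem import porter_stem

__all__ = [
    "VocabularyEntry",
    "PreAnnotation",
    "AnnotationError",
    "tag_numbers",
    "stem_tokens",
    "apply_preannotations",
    "group_from_parse",
    "vocab_aggregate",
    "prune_annotations",
    "load_vocabulary",
    "load_conll",
    "load_trees",
    "parse_number",
]


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class VocabularyEntry:
    phrase: tuple[str, ...]  # token surfaces, matched case-insensitively
    concept_id: str


@dataclass
class PreAnnotation:
    """Per-document external annotations: POS/lemma rows per sentence and/or
    Penn-bracketed parse trees, aligned by sentence index."""

    doc_id: str
    pos_sentences: list[list[tuple[str, str, Optional[str]]]] = field(default_factory=list)
    trees: list[str] = field(default_factory=list)


_NUM_RE = re.compile(r"[+-]?(?:\d+(?:\.\d+)?|\.\d+)$")


def parse_number(surface: str) -> Optional[float]:
    """Parse a cardinal-number surface (thousands commas stripped), else None."""
    s = surface.replace(",", "")
    if _NUM_RE.match(s):
        return float(s)
    return None


def tag_numbers(sentence: Sentence) -> Sentence:
    """Tag cardinal-number tokens with NUM and attach their numeric value."""
    for tok in sentence.tokens:
        v = parse_number(tok.surface)
        if v is not None:
            tok.tags.add("NUM")
            tok.numeric_value = v
    return sentence


def stem_tokens(sentence: Sentence) -> Sentence:
    """Attach STEM:<stem> to purely alphabetic tokens (lower-cased input)."""
    for tok in sentence.tokens:
        if tok.surface.isalpha():
            tok.tags.add("STEM:" + porter_stem(tok.surface.lower()))
    return sentence


def load_conll(path: str | Path) -> list[list[tuple[str, str, Optional[str]]]]:
    """Read CoNLL-style `token<TAB>POS[<TAB>lemma]` lines, blank line between
    sentences.  Returns one (token, pos, lemma) row list per sentence."""
    sentences: list[list[tuple[str, str, Optional[str]]]] = []
    cur: list[tuple[str, str, Optional[str]]] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            if cur:
                sentences.append(cur)
                cur = []
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise AnnotationError(f"{path}: malformed CoNLL line {line!r}")
        cur.append((parts[0], parts[1], parts[2] if len(parts) > 2 else None))
    if cur:
        sentences.append(cur)
    return sentences


def load_trees(path: str | Path) -> list[str]:
    """Read one Penn-bracketed tree per non-blank line."""
    return [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]


def apply_preannotations(corpus: Corpus, annotations: Iterable[PreAnnotation]) -> Corpus:
    """Attach POS:<tag> (and STEM:<lemma> when given) tags and register parse
    groups.  Token-count mismatches are fatal, naming the offending sentence;
    documents without a pre-annotation are left untagged."""
    by_doc = {a.doc_id: a for a in annotations}
    for case in corpus.cases:
        for doc in case.documents:
            ann = by_doc.get(doc.doc_id)
            if ann is None:
                continue
            for si, rows in enumerate(ann.pos_sentences):
                if si >= len(doc.sentences):
                    raise AnnotationError(f"{doc.doc_id}: more annotated sentences than chunked")
                sent = doc.sentences[si]
                if len(rows) != len(sent.tokens):
                    raise AnnotationError(
                        f"{doc.doc_id} sentence {si}: {len(rows)} annotation rows "
                        f"vs {len(sent.tokens)} tokens")
                for tok, (_, pos, lemma) in zip(sent.tokens, rows):
                    tok.tags.add("POS:" + pos)
                    if lemma:
                        tok.tags.add("STEM:" + lemma.lower())
            for si, tree in enumerate(ann.trees):
                if si >= len(doc.sentences):
                    raise AnnotationError(f"{doc.doc_id}: more trees than sentences")
                group_from_parse(doc.sentences[si], tree)
    return corpus


def _parse_tree(s: str, pos: int = 0):
    """Recursive-descent parse of a Penn-bracketed tree.

    Returns (node, next_pos); node = (label, children) or a leaf string.
    """
    while pos < len(s) and s[pos].isspace():
        pos += 1
    if pos >= len(s) or s[pos] != "(":
        raise AnnotationError(f"malformed bracketing at position {pos}")
    pos += 1
    m = re.match(r"[^\s()]+", s[pos:])
    if not m:
        raise AnnotationError(f"missing node label at position {pos}")
    label = m.group(0)
    pos += len(label)
    children: list = []
    while True:
        while pos < len(s) and s[pos].isspace():
            pos += 1
        if pos >= len(s):
            raise AnnotationError("unbalanced bracketing")
        if s[pos] == ")":
            return (label, children), pos + 1
        if s[pos] == "(":
            child, pos = _parse_tree(s, pos)
            children.append(child)
        else:
            m = re.match(r"[^\s()]+", s[pos:])
            children.append(m.group(0))
            pos += len(m.group(0))


def group_from_parse(sentence: Sentence, tree: str) -> Sentence:
    """Register a group token for every internal parse node spanning >= 2
    tokens: surface is the underscore-join of the span, tag GRP:<label>.

    Group tokens coexist with their constituents and are offered to the
    feature search as single-position alternatives covering their span.
    """
    node, end = _parse_tree(tree)
    if tree[end:].strip():
        raise AnnotationError(f"trailing text after tree: {tree[end:]!r}")

    leaves: list[str] = []

    def collect(n) -> tuple[int, int]:
        """Return the [start, end) token span of node n, registering groups."""
        if isinstance(n, str):
            leaves.append(n)
            return len(leaves) - 1, len(leaves)
        label, children = n
        start = len(leaves)
        for c in children:
            collect(c)
        end_ = len(leaves)
        if end_ - start >= 2:
            span = GroupSpan(start=start, end=end_,
                             surface="_".join(leaves[start:end_]), tag="GRP:" + label)
            if span not in sentence.groups:
                sentence.groups.append(span)
        return start, end_

    collect(node)
    if leaves != sentence.surfaces():
        raise AnnotationError(
            f"tree leaves {leaves} do not match sentence tokens {sentence.surfaces()}")
    return sentence


def load_vocabulary(path: str | Path) -> list[VocabularyEntry]:
    """Read a `phrase<TAB>concept_id` TSV; phrases are tokenized on whitespace."""
    entries = []
    seen: set[tuple[str, ...]] = set()
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        if not ln.strip():
            continue
        try:
            phrase, cid = ln.split("\t")
        except ValueError as exc:
            raise AnnotationError(f"{path}: malformed vocabulary line {ln!r}") from exc
        key = tuple(phrase.lower().split())
        if key in seen:
            raise AnnotationError(f"{path}: duplicate vocabulary phrase {phrase!r}")
        seen.add(key)
        entries.append(VocabularyEntry(phrase=key, concept_id=cid))
    return entries


def vocab_aggregate(sentence: Sentence, vocabulary: list[VocabularyEntry]) -> Sentence:
    """Longest-string concept recognition: replace each matched span with one
    token (underscore-joined surface) tagged CONCEPT:<id>.

    Left-to-right, case-insensitive; after a match, scanning resumes past it.
    Replacement is destructive (the span's tokens are fused), so any
    registered group spans are cleared if token positions shift.
    """
    by_first: dict[str, list[VocabularyEntry]] = {}
    for e in vocabulary:
        by_first.setdefault(e.phrase[0], []).append(e)
    out: list[Token] = []
    toks = sentence.tokens
    i = 0
    changed = False
    while i < len(toks):
        lowered = toks[i].surface.lower()
        best: Optional[VocabularyEntry] = None
        for e in by_first.get(lowered, ()):
            n = len(e.phrase)
            if i + n <= len(toks) and tuple(t.surface.lower() for t in toks[i:i + n]) == e.phrase:
                if best is None or n > len(best.phrase):
                    best = e
        if best is not None:
            out.append(Token(surface="_".join(t.surface for t in toks[i:i + len(best.phrase)]),
                             tags={"CONCEPT:" + best.concept_id}))
            i += len(best.phrase)
            changed = True
        else:
            out.append(toks[i])
            i += 1
    if changed:
        sentence.tokens = out
        sentence.groups = []
    return sentence


def prune_annotations(corpus: Corpus) -> int:
    """Remove every tag value supported by exactly one distinct token surface
    corpus-wide (such a tag can never generalise a pattern).  Returns the
    number of tag attachments removed.  Idempotent."""
    surfaces_by_tag: dict[str, set[str]] = {}
    for _, _, _, sent in corpus.iter_sentences():
        for tok in sent.tokens:
            for tag in tok.tags:
                surfaces_by_tag.setdefault(tag, set()).add(tok.surface)
        for g in sent.groups:
            surfaces_by_tag.setdefault(g.tag, set()).add(g.surface)
    doomed = {tag for tag, surfs in surfaces_by_tag.items() if len(surfs) == 1}
    removed = 0
    for _, _, _, sent in corpus.iter_sentences():
        for tok in sent.tokens:
            hit = tok.tags & doomed
            if hit:
                removed += len(hit)
                tok.tags -= hit
                if "NUM" in hit:
                    tok.numeric_value = None
        kept_groups = []
        for g in sent.groups:
            if g.tag in doomed:
                removed += 1
            else:
                kept_groups.append(g)
        sent.groups = kept_groups
    return removed
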