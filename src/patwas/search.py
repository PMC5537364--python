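"""Exhaustive within-sentence pattern search.

Three feature families are generated:

* surface n-grams — contiguous token sequences, never crossing a sentence
  or document boundary;
* tagged patterns — like n-grams, but each position may match either the
  token surface or any one of its tags (combinatorial search);
* numeric features — "A <NUMBER> B" constructs: a pair of flanking n-grams
  around a cardinal number, whose per-case value is the number itself.

All searches are support-pruned: elongation of a candidate stops once its
corpus occurrence count drops below 2 (an elongating pattern occurring once
can never generalise) or its case support falls below ``min_support``.
Support is anti-monotone in pattern length, so the pruning is lossless.

Group tokens registered by parse annotation participate as single-position
alternatives covering their span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np

from .corpus import Corpus, Sentence

__all__ = [
    "PatternElement",
    "NGramPattern",
    "BinaryFeature",
    "NumericFeature",
    "lit",
    "tag",
    "render_pattern",
    "enumerate_ngrams",
    "enumerate_tagged_patterns",
    "extract_numeric_features",
    "build_profile",
    "sentence_options",
]


@dataclass(frozen=True)
class PatternElement:
    """One pattern position: a literal surface or a tag value."""

    kind: str  # "lit" | "tag"
    value: str

    def __post_init__(self) -> None:
        if self.kind not in ("lit", "tag"):
            raise ValueError(f"bad element kind {self.kind!r}")


def lit(value: str) -> PatternElement:
    return PatternElement("lit", value)


def tag(value: str) -> PatternElement:
    return PatternElement("tag", value)


NGramPattern = tuple[PatternElement, ...]


def _is_punct(surface: str) -> bool:
    return len(surface) == 1 and not surface.isalnum() and surface != "_"


def render_pattern(pattern: NGramPattern) -> str:
    """Render a pattern: elements space-joined, no space before punctuation,
    tags as ``<NS:value>`` (the bare ``<NUM>`` for the number tag)."""
    parts: list[str] = []
    out = ""
    for el in pattern:
        if el.kind == "lit":
            piece = el.value
            if out and _is_punct(piece):
                out += piece
                continue
        else:
            piece = f"<{el.value}>"
        out = piece if not out else out + " " + piece
    return out


def pattern_length(pattern: NGramPattern) -> int:
    return len(pattern)


@dataclass
class BinaryFeature:
    """A pattern with its case-level occurrence profile."""

    pattern: NGramPattern
    profile: np.ndarray  # bool, one bit per case in corpus order
    feature_type: str = "ngram"  # "ngram" | "tagged" | "regex"

    @property
    def support(self) -> int:
        return int(self.profile.sum())

    def rendered(self) -> str:
        return render_pattern(self.pattern)


@dataclass
class NumericFeature:
    """Flanking n-gram pair around a number; at most one value per case."""

    left_flank: NGramPattern
    right_flank: NGramPattern
    values: dict[str, float] = field(default_factory=dict)

    @property
    def support(self) -> int:
        return len(self.values)

    def rendered(self) -> str:
        return f"{render_pattern(self.left_flank)} <NUMBER> {render_pattern(self.right_flank)}"


# A lattice option at a sentence position: (element surfaces+tags, next position)
def sentence_options(sent: Sentence) -> list[list[tuple[str, frozenset, int]]]:
    """Per-position alternatives: the token itself (advance 1) plus any group
    token starting there (advance to the end of its span).  Each option is
    (surface, tags, next_position)."""
    n = len(sent.tokens)
    opts: list[list[tuple[str, frozenset, int]]] = [[] for _ in range(n)]
    for i, tok in enumerate(sent.tokens):
        opts[i].append((tok.surface, frozenset(tok.tags), i + 1))
    for g in sent.groups:
        if 0 <= g.start < n and g.end <= n:
            opts[g.start].append((g.surface, frozenset({g.tag}), g.end))
    return opts


def _iter_sentence_lattices(corpus: Corpus):
    for ci, di, si, sent in corpus.iter_sentences():
        yield ci, (di, si), sentence_options(sent)


def enumerate_ngrams(corpus: Corpus, min_support: int = 2,
                     max_len: Optional[int] = None) -> list[BinaryFeature]:
    """Every distinct surface n-gram occurring within one sentence in at
    least ``min_support`` cases, each exactly once with its case profile.

    Level-wise elongation; a candidate is extended only while its corpus
    occurrence count stays >= max(2, needed) and its support >= min_support.
    Output is sorted by pattern length, then rendered form.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    lattices = list(_iter_sentence_lattices(corpus))
    n_cases = corpus.n_cases

    # occurrence: (sentence ordinal, end position); pattern -> (case set, occs)
    level: dict[tuple[str, ...], tuple[set[int], list[tuple[int, int]]]] = {}
    for sid, (ci, _, opts) in enumerate(lattices):
        for start in range(len(opts)):
            for surf, _, nxt in opts[start]:
                cs, occ = level.setdefault((surf,), (set(), []))
                cs.add(ci)
                occ.append((sid, nxt))

    out: list[BinaryFeature] = []
    length = 1
    while level:
        survivors: dict[tuple[str, ...], tuple[set[int], list[tuple[int, int]]]] = {}
        for pat, (cs, occ) in level.items():
            if len(cs) >= min_support:
                profile = np.zeros(n_cases, dtype=bool)
                profile[list(cs)] = True
                out.append(BinaryFeature(pattern=tuple(map(lit, pat)), profile=profile,
                                         feature_type="ngram"))
            # elongation heuristic: occurrences >= 2 and support >= min_support
            if len(occ) >= 2 and len(cs) >= min_support:
                survivors[pat] = (cs, occ)
        if max_len is not None and length >= max_len:
            break
        level = {}
        for pat, (_, occ) in survivors.items():
            for sid, end in occ:
                ci, _, opts = lattices[sid]
                if end < len(opts):
                    for surf, _, nxt in opts[end]:
                        cs2, occ2 = level.setdefault(pat + (surf,), (set(), []))
                        cs2.add(ci)
                        occ2.append((sid, nxt))
        length += 1

    out.sort(key=lambda f: (len(f.pattern), f.rendered()))
    return out


def enumerate_tagged_patterns(corpus: Corpus, min_support: int = 2,
                              max_len: int = 5) -> list[BinaryFeature]:
    """Combinatorial sub-sequence search: each position matches the surface
    or any tag of the underlying token.  Pure-surface combinations are left
    to :func:`enumerate_ngrams` and excluded here."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    lattices = list(_iter_sentence_lattices(corpus))
    n_cases = corpus.n_cases

    def reps(surf: str, tags: frozenset) -> list[PatternElement]:
        return [lit(surf)] + [tag(t) for t in sorted(tags)]

    level: dict[NGramPattern, tuple[set[int], list[tuple[int, int]]]] = {}
    for sid, (ci, _, opts) in enumerate(lattices):
        for start in range(len(opts)):
            for surf, tg, nxt in opts[start]:
                for el in reps(surf, tg):
                    cs, occ = level.setdefault((el,), (set(), []))
                    cs.add(ci)
                    occ.append((sid, nxt))

    out: list[BinaryFeature] = []
    length = 1
    while level:
        survivors = {}
        for pat, (cs, occ) in level.items():
            if len(cs) >= min_support:
                if not all(el.kind == "lit" for el in pat):
                    profile = np.zeros(n_cases, dtype=bool)
                    profile[list(cs)] = True
                    out.append(BinaryFeature(pattern=pat, profile=profile,
                                             feature_type="tagged"))
            if len(occ) >= 2 and len(cs) >= min_support:
                survivors[pat] = (cs, occ)
        if length >= max_len:
            break
        level = {}
        for pat, (_, occ) in survivors.items():
            for sid, end in occ:
                ci, _, opts = lattices[sid]
                if end < len(opts):
                    for surf, tg, nxt in opts[end]:
                        for el in reps(surf, tg):
                            cs2, occ2 = level.setdefault(pat + (el,), (set(), []))
                            cs2.add(ci)
                            occ2.append((sid, nxt))
        length += 1

    out.sort(key=lambda f: (len(f.pattern), f.rendered()))
    return out


def _element_matches(el: PatternElement, surf: str, tags: frozenset) -> bool:
    return el.value == surf if el.kind == "lit" else el.value in tags


def _match_at(pattern: NGramPattern, opts, pos: int) -> bool:
    """DFS over the lattice: does the pattern match starting at pos?"""
    if not pattern:
        return True
    if pos >= len(opts):
        return False
    el = pattern[0]
    for surf, tags, nxt in opts[pos]:
        if _element_matches(el, surf, tags) and _match_at(pattern[1:], opts, nxt):
            return True
    return False


def build_profile(pattern: NGramPattern, corpus: Corpus) -> np.ndarray:
    """Case-level occurrence profile: bit set iff the pattern matches within
    any single sentence of any of the case's documents."""
    profile = np.zeros(corpus.n_cases, dtype=bool)
    for ci, _, _, sent in corpus.iter_sentences():
        if profile[ci]:
            continue
        opts = sentence_options(sent)
        if any(_match_at(pattern, opts, p) for p in range(len(opts))):
            profile[ci] = True
    return profile


def extract_numeric_features(corpus: Corpus, max_flank_len: int = 3,
                             min_support: int = 2) -> list[NumericFeature]:
    """All "A <NUMBER> B" features with flank lengths 1..max_flank_len.

    A candidate flank pair must match in >= min_support cases; if it matches
    more than once within any single case, the whole feature is discarded
    (ambiguity rule).  Flanks are plain surface n-grams within one sentence.
    Requires :func:`patwas.annotate.tag_numbers` to have been applied.
    """
    # (left surfaces, right surfaces) -> case_id -> list of matched values
    cand: dict[tuple[tuple[str, ...], tuple[str, ...]], dict[str, list[float]]] = {}
    for ci, _, _, sent in corpus.iter_sentences():
        cid = corpus.cases[ci].case_id
        surfs = sent.surfaces()
        for k, tok in enumerate(sent.tokens):
            if "NUM" not in tok.tags:
                continue
            for ll in range(1, max_flank_len + 1):
                if k - ll < 0:
                    break
                left = tuple(surfs[k - ll:k])
                for rl in range(1, max_flank_len + 1):
                    if k + 1 + rl > len(surfs):
                        break
                    right = tuple(surfs[k + 1:k + 1 + rl])
                    cand.setdefault((left, right), {}).setdefault(cid, []).append(
                        float(tok.numeric_value))
    out = []
    for (left, right), by_case in sorted(cand.items()):
        if any(len(v) > 1 for v in by_case.values()):
            continue  # ambiguous within a case: discard entirely
        if len(by_case) < min_support:
            continue
        out.append(NumericFeature(left_flank=tuple(map(lit, left)),
                                  right_flank=tuple(map(lit, right)),
                                  values={c: v[0] for c, v in by_case.items()}))
    out.sort(key=lambda f: f.rendered())
    return out
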