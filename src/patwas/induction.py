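"""Token-regex induction by global alignment.

Syntactically similar n-grams that share their first and last tokens are
consolidated into a linear, non-recursive token regular expression — e.g.
"extensive bone metastasis" + "extensive liver metastasis" become
"extensive (bone|liver) metastasis" — which is then re-scored as a single
meta-feature.  The notation: alternation "(v1|v2)", optional "(v)?",
optional alternation "(v1|v2)?".

The member sequences are aligned by Needleman-Wunsch global alignment (a
wildcard at either end of an expression would match indiscriminately, hence
global rather than local alignment), consolidated by star alignment against
the longest member.
"""

from __future__ import annotations

import re as _re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import Corpus, Outcome
from .search import (BinaryFeature, NGramPattern, PatternElement,
                     sentence_options)
from .stats import AssociationResult, associate

__all__ = [
    "Literal",
    "Group",
    "TokenRegex",
    "Alignment",
    "InductionError",
    "group_candidates",
    "align_pair",
    "consolidate",
    "match_regex",
    "induce_and_rescore",
    "render_regex",
    "parse_regex",
]


class InductionError(ValueError):
    pass


@dataclass(frozen=True)
class Literal:
    token: str


@dataclass(frozen=True)
class Group:
    """Alternation over plain token sequences; optional when '?'-marked.

    A single-variant optional group renders "(v)?"; alternatives are
    pairwise distinct and never nested.
    """

    variants: tuple[tuple[str, ...], ...]
    optional: bool = False

    def __post_init__(self) -> None:
        if len(set(self.variants)) != len(self.variants):
            raise InductionError("alternation variants must be distinct")
        if not self.variants or any(len(v) == 0 for v in self.variants):
            raise InductionError("variants must be non-empty token sequences")
        if len(self.variants) == 1 and not self.optional:
            raise InductionError("single-variant group must be optional")


RegexElement = "Literal | Group"


@dataclass
class TokenRegex:
    elements: tuple
    members: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if not self.elements or not isinstance(self.elements[0], Literal) \
                or not isinstance(self.elements[-1], Literal):
            raise InductionError("first and last elements must be literals")

    def __eq__(self, other) -> bool:  # members are provenance, not identity
        return isinstance(other, TokenRegex) and self.elements == other.elements

    def rendered(self) -> str:
        return render_regex(self)


@dataclass
class RegexFeature:
    """A TokenRegex with its corpus occurrence profile (feature adapter)."""

    regex: TokenRegex
    profile: np.ndarray
    feature_type: str = "regex"

    @property
    def pattern(self):
        return self.regex

    @property
    def support(self) -> int:
        return int(self.profile.sum())

    def rendered(self) -> str:
        return render_regex(self.regex)


@dataclass
class Alignment:
    """Columns of (token-or-None, token-or-None) over two sequences."""

    columns: list[tuple[Optional[str], Optional[str]]]
    score: float


def _surfaces(pattern: NGramPattern) -> tuple[str, ...]:
    if any(el.kind != "lit" for el in pattern):
        raise InductionError("regex induction operates on surface n-grams")
    return tuple(el.value for el in pattern)


def group_candidates(features: Sequence[BinaryFeature]) -> dict[tuple[str, str], list[NGramPattern]]:
    """Maximal groups (size >= 2) of surface n-grams keyed by their shared
    (first token, last token).  Length-1 patterns cannot supply two boundary
    literals and are skipped, as are tagged patterns."""
    groups: dict[tuple[str, str], list[NGramPattern]] = {}
    seen: dict[tuple[str, str], set[tuple[str, ...]]] = {}
    for f in features:
        if f.feature_type != "ngram" or len(f.pattern) < 2:
            continue
        if any(el.kind != "lit" for el in f.pattern):
            continue
        surfs = _surfaces(f.pattern)
        key = (surfs[0], surfs[-1])
        if surfs in seen.setdefault(key, set()):
            continue
        seen[key].add(surfs)
        groups.setdefault(key, []).append(f.pattern)
    return {k: v for k, v in groups.items() if len(v) >= 2}


def align_pair(seq_a: Sequence[str], seq_b: Sequence[str], match: float = 1.0,
               mismatch: float = -1.0, gap: float = -1.0) -> Alignment:
    """Needleman-Wunsch global alignment of two token sequences.

    Traceback tie preference: diagonal > up (gap in b) > left (gap in a).
    """
    a, b = list(seq_a), list(seq_b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * gap
    score[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            score[i, j] = max(diag, up, left)
    cols: list[tuple[Optional[str], Optional[str]]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
                match if a[i - 1] == b[j - 1] else mismatch):
            cols.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            cols.append((a[i - 1], None))
            i -= 1
        else:
            cols.append((None, b[j - 1]))
            j -= 1
    cols.reverse()
    return Alignment(columns=cols, score=float(score[n, m]))


def _star_align(center: tuple[str, ...], others: list[tuple[str, ...]]) -> list[list[Optional[str]]]:
    """Star alignment of ``others`` against ``center``.

    Returns columns; each column is [center token or None, member1 token or
    None, ...].  Insertions relative to the center occupy their own columns
    (center = None) grouped before the center position they precede.
    """
    n = len(center)
    # per member: aligned[i] token opposite center[i]; inserts[i] tokens before center pos i
    aligned: list[list[Optional[str]]] = []
    inserts: list[list[list[str]]] = []
    for other in others:
        al = align_pair(center, other)
        a_pos = 0
        row: list[Optional[str]] = [None] * n
        ins: list[list[str]] = [[] for _ in range(n + 1)]
        for ca, cb in al.columns:
            if ca is not None:
                row[a_pos] = cb
                a_pos += 1
            else:
                ins[a_pos].append(cb)
        aligned.append(row)
        inserts.append(ins)

    k = len(others)
    columns: list[list[Optional[str]]] = []
    for i in range(n + 1):
        width = max((len(ins[i]) for ins in inserts), default=0)
        for w in range(width):
            col: list[Optional[str]] = [None]
            for mi in range(k):
                toks = inserts[mi][i]
                col.append(toks[w] if w < len(toks) else None)
            columns.append(col)
        if i < n:
            col = [center[i]]
            for mi in range(k):
                col.append(aligned[mi][i])
            columns.append(col)
    return columns


def consolidate(group: Sequence[NGramPattern],
                member_support: Optional[dict[tuple[str, ...], int]] = None) -> TokenRegex:
    """Consolidate >= 2 n-grams sharing first/last tokens into a TokenRegex.

    The shared boundary tokens are pinned as literal anchors; the interior
    is star-aligned against the longest member (ties: lexicographically
    first).  Columns where every member agrees become literals; each maximal
    run of disagreeing columns becomes one alternation/optional element
    holding the members' gap-stripped subsequences over the run.  Variants
    are ordered by descending member support (when known), then by first
    appearance in the group.
    """
    members = []
    for p in group:
        s = _surfaces(p) if p and isinstance(p[0], PatternElement) else tuple(p)
        if s not in members:
            members.append(s)
    if len(members) < 2:
        raise InductionError("nothing to consolidate: members identical")
    first, last = members[0][0], members[0][-1]
    if any(m[0] != first or m[-1] != last for m in members):
        raise InductionError("members must share first and last tokens")
    if any(len(m) < 2 for m in members):
        raise InductionError("members must have length >= 2")

    middles = [m[1:-1] for m in members]
    order = list(range(len(members)))

    def var_key(variant: tuple[str, ...], firsts: dict) -> tuple:
        sup = -max((member_support.get(members[mi], 0) for mi in firsts[variant]),
                   default=0) if member_support else 0
        return (sup, min(firsts[variant]))

    elements: list = [Literal(first)]
    nonempty = [mid for mid in middles if mid]
    if nonempty:
        maxlen = max(len(s) for s in nonempty)
        center = sorted(s for s in nonempty if len(s) == maxlen)[0]
        # align every distinct non-center middle; empty middles become the
        # empty variant of the (single) interior group
        others_distinct: list[tuple[str, ...]] = []
        for i in order:
            if middles[i] != center and middles[i] not in others_distinct:
                others_distinct.append(middles[i])
        nonempty_others = [o for o in others_distinct if o]
        columns = _star_align(center, nonempty_others)
        # rows: center + nonempty others; empty middles handled as empty variant
        n_rows = 1 + len(nonempty_others)
        has_empty_middle = any(not mid for mid in middles)

        run: list[list[Optional[str]]] = []

        def flush_run() -> None:
            if not run:
                return
            variants_per_row: list[tuple[str, ...]] = []
            for r in range(n_rows):
                variants_per_row.append(tuple(col[r] for col in run if col[r] is not None))
            firsts: dict[tuple[str, ...], list[int]] = {}
            row_to_member = [middles.index(center)] + [middles.index(o) for o in nonempty_others]
            for r, v in enumerate(variants_per_row):
                firsts.setdefault(v, []).append(row_to_member[r])
            distinct = sorted(firsts, key=lambda v: var_key(v, firsts))
            optional = any(len(v) == 0 for v in distinct)
            nonempty_vars = tuple(v for v in distinct if v)
            if not nonempty_vars:
                run.clear()
                return
            if len(nonempty_vars) == 1 and not optional:
                for tokseq in nonempty_vars:
                    for t in tokseq:
                        elements.append(Literal(t))
            else:
                elements.append(Group(variants=nonempty_vars, optional=optional))
            run.clear()

        for col in columns:
            tokens = set(col)
            if None not in tokens and len(tokens) == 1:
                flush_run()
                elements.append(Literal(col[0]))
            else:
                run.append(col)
        flush_run()

        # an empty middle anywhere makes the whole interior optional only if
        # the interior is a single group element; otherwise wrap is impossible
        # in a linear expression — handled by treating the empty middle as an
        # empty variant of the single run when the interior is one run.
        if has_empty_middle:
            interior = elements[1:]
            if len(interior) == 1 and isinstance(interior[0], Group):
                g = interior[0]
                elements[1] = Group(variants=g.variants, optional=True)
            elif len(interior) >= 1:
                # collapse whole interior into one optional group variant set
                variants: list[tuple[str, ...]] = []
                for mid in middles:
                    if mid and mid not in variants:
                        variants.append(mid)
                firsts = {v: [middles.index(v)] for v in variants}
                variants.sort(key=lambda v: var_key(v, firsts))
                del elements[1:]
                elements.append(Group(variants=tuple(variants), optional=True))
    elements.append(Literal(last))
    return TokenRegex(elements=tuple(elements), members=tuple(members))


def _regex_match_at(elements: tuple, opts, pos: int) -> bool:
    if not elements:
        return True
    el = elements[0]
    if isinstance(el, Literal):
        if pos >= len(opts):
            return False
        for surf, _, nxt in opts[pos]:
            if surf == el.token and _regex_match_at(elements[1:], opts, nxt):
                return True
        return False
    for variant in el.variants:
        lits = tuple(Literal(t) for t in variant)
        if _regex_match_at(lits + elements[1:], opts, pos):
            return True
    if el.optional:
        return _regex_match_at(elements[1:], opts, pos)
    return False


def match_regex(regex: TokenRegex, corpus: Corpus) -> np.ndarray:
    """Case occurrence profile of a token regex: bit set iff some sentence
    contains a contiguous token subsequence matched by the elements."""
    profile = np.zeros(corpus.n_cases, dtype=bool)
    for ci, _, _, sent in corpus.iter_sentences():
        if profile[ci]:
            continue
        opts = sentence_options(sent)
        if any(_regex_match_at(regex.elements, opts, p) for p in range(len(opts))):
            profile[ci] = True
    return profile


def induce_and_rescore(results: Sequence[AssociationResult], corpus: Corpus,
                       outcome: Outcome) -> list[AssociationResult]:
    """Consolidate each candidate group of ranked n-gram features into a
    token regex, rebuild its profile, and re-run the association test.
    Returns the regex results only (merge with n-gram results upstream)."""
    features = [r.feature for r in results if isinstance(r.feature, BinaryFeature)]
    support_by_member = {}
    for f in features:
        if f.feature_type == "ngram":
            try:
                support_by_member[_surfaces(f.pattern)] = f.support
            except InductionError:
                continue
    out: list[AssociationResult] = []
    for key, group in sorted(group_candidates(features).items()):
        try:
            rx = consolidate(group, member_support=support_by_member)
        except InductionError:
            continue
        profile = match_regex(rx, corpus)
        feat = RegexFeature(regex=rx, profile=profile)
        res = associate(feat, outcome, corpus)
        if res is not None:
            res.pattern_type = "regex"
            out.append(res)
    return out


def render_regex(regex: TokenRegex) -> str:
    parts = []
    for el in regex.elements:
        if isinstance(el, Literal):
            parts.append(el.token)
        else:
            body = "|".join(" ".join(v) for v in el.variants)
            parts.append(f"({body})" + ("?" if el.optional else ""))
    return " ".join(parts)


_GROUP_RE = _re.compile(r"\(([^()]*)\)(\?)?")


def parse_regex(text: str) -> TokenRegex:
    """Parse the rendered notation back into a TokenRegex (round-trip with
    :func:`render_regex`)."""
    elements: list = []
    pos = 0
    n = len(text)
    while pos < n:
        if text[pos].isspace():
            pos += 1
            continue
        if text[pos] == "(":
            m = _GROUP_RE.match(text, pos)
            if not m:
                raise InductionError(f"malformed group at position {pos}")
            body, opt = m.group(1), bool(m.group(2))
            variants = tuple(tuple(v.split()) for v in body.split("|"))
            if any(not v for v in variants):
                raise InductionError(f"empty variant at position {pos}")
            elements.append(Group(variants=variants, optional=opt))
            pos = m.end()
        elif text[pos] in ")|?":
            raise InductionError(f"unexpected {text[pos]!r} at position {pos}")
        else:
            m = _re.match(r"[^\s()|?]+", text[pos:])
            elements.append(Literal(m.group(0)))
            pos += len(m.group(0))
    return TokenRegex(elements=tuple(elements))
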