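"""Case-labelled document collections: loading, sentence chunking, tokenization.

A *corpus* is an ordered list of cases; each case owns one or more plain-text
documents (MDT reports, clinic letters, pathology and imaging reports, ...)
and a map of outcome labels.  The fixed case order defines the coordinate
system of every occurrence profile downstream, so it is part of the
reproducibility contract: cases appear in manifest order of first appearance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "Token",
    "GroupSpan",
    "Sentence",
    "Document",
    "Case",
    "Outcome",
    "Corpus",
    "CorpusError",
    "chunk_sentences",
    "tokenize",
    "redact",
    "load_corpus",
]


class CorpusError(ValueError):
    """Fatal problem in corpus inputs (bad manifest row, missing file, ...)."""


@dataclass
class Token:
    """Atomic unit of pattern matching.

    ``tags`` holds namespaced labels such as ``NUM``, ``STEM:metastasi``,
    ``POS:JJ``, ``GRP:NP`` or ``CONCEPT:C12``.  ``numeric_value`` is set if
    and only if the ``NUM`` tag is present.
    """

    surface: str
    tags: set[str] = field(default_factory=set)
    numeric_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.surface or any(c.isspace() for c in self.surface):
            raise ValueError(f"token surface must be non-empty, no whitespace: {self.surface!r}")


@dataclass(frozen=True)
class GroupSpan:
    """A sequence-level group token covering tokens [start, end).

    Registered by parse-tree traversal or (optionally) vocabulary matching;
    available to the feature search as a single-position alternative.
    """

    start: int
    end: int
    surface: str
    tag: str


@dataclass
class Sentence:
    tokens: list[Token]
    char_span: tuple[int, int] = (0, 0)
    groups: list[GroupSpan] = field(default_factory=list)

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


@dataclass
class Document:
    doc_id: str
    case_id: str
    doc_type: str
    sentences: list[Sentence]


@dataclass
class Case:
    case_id: str
    documents: list[Document] = field(default_factory=list)
    outcomes: dict[str, float] = field(default_factory=dict)


@dataclass
class Outcome:
    """A named outcome variable over cases; missing cases are simply absent."""

    name: str
    kind: str  # "binary" | "numeric"
    values: dict[str, float]

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "numeric"):
            raise ValueError(f"outcome kind must be binary or numeric: {self.kind}")
        if self.kind == "binary":
            bad = {v for v in self.values.values() if v not in (0, 1)}
            if bad:
                raise ValueError(f"binary outcome {self.name} has non-0/1 values: {bad}")


class Corpus:
    """Ordered cases plus a token inverted index.

    The index maps a token surface to every ``(case_idx, doc_idx, sent_idx,
    token_idx)`` position at which it occurs, and is rebuilt on demand after
    annotation passes that change surfaces (e.g. vocabulary aggregation).
    """

    def __init__(self, cases: list[Case], outcomes: Optional[dict[str, Outcome]] = None):
        self.cases = cases
        self.outcomes: dict[str, Outcome] = outcomes or {}
        self._index: Optional[dict[str, list[tuple[int, int, int, int]]]] = None

    @property
    def case_ids(self) -> list[str]:
        return [c.case_id for c in self.cases]

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def iter_sentences(self) -> Iterator[tuple[int, int, int, Sentence]]:
        """Yield (case_idx, doc_idx, sent_idx, sentence) in corpus order."""
        for ci, case in enumerate(self.cases):
            for di, doc in enumerate(case.documents):
                for si, sent in enumerate(doc.sentences):
                    yield ci, di, si, sent

    @property
    def index(self) -> dict[str, list[tuple[int, int, int, int]]]:
        if self._index is None:
            idx: dict[str, list[tuple[int, int, int, int]]] = {}
            for ci, di, si, sent in self.iter_sentences():
                for ti, tok in enumerate(sent.tokens):
                    idx.setdefault(tok.surface, []).append((ci, di, si, ti))
            self._index = idx
        return self._index

    def invalidate_index(self) -> None:
        self._index = None

    def subset(self, case_indices: Iterable[int], id_suffixes: Optional[list[str]] = None) -> "Corpus":
        """A corpus view over the given case indices (repeats allowed).

        Used by bootstrap resampling: repeated cases receive distinct ids so
        the case axis stays well defined; documents are shared by reference.
        """
        indices = list(case_indices)
        suffixes = id_suffixes or [f"#{j}" for j in range(len(indices))]
        cases = []
        for j, ci in enumerate(indices):
            src = self.cases[ci]
            cases.append(Case(case_id=src.case_id + suffixes[j], documents=src.documents,
                              outcomes=dict(src.outcomes)))
        out: dict[str, Outcome] = {}
        for name, oc in self.outcomes.items():
            vals = {}
            for j, ci in enumerate(indices):
                cid = self.cases[ci].case_id
                if cid in oc.values:
                    vals[cid + suffixes[j]] = oc.values[cid]
            out[name] = Outcome(name=name, kind=oc.kind, values=vals)
        return Corpus(cases, out)


_TERMINATORS = ".!?:"

# a decimal number is one token; otherwise maximal word runs (hyphens allowed
# inside) and single punctuation characters
_TOKEN_RE = re.compile(r"\d+\.\d+|\w+(?:-\w+)*|[^\w\s]")


def chunk_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans (0-based, half-open character offsets).

    Breaks after ``. ! ? :`` followed by whitespace and at blank lines.  This
    is a deliberately naive rule-based splitter with no abbreviation
    dictionary ("Dr. Smith" splits after "Dr.").
    """
    if not text.strip():
        return []
    breaks = {0, len(text)}
    for i, c in enumerate(text):
        if c in _TERMINATORS and (i + 1 == len(text) or text[i + 1].isspace()):
            breaks.add(i + 1)
    for m in re.finditer(r"\n[ \t]*\n", text):
        breaks.add(m.start())
    spans: list[tuple[int, int]] = []
    points = sorted(breaks)
    for a, b in zip(points, points[1:]):
        seg = text[a:b]
        ls = len(seg) - len(seg.lstrip())
        rs = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append((a + ls, b - rs))
    return spans


def tokenize(sentence_text: str, fold_case: bool = False) -> list[Token]:
    """Tokenize one sentence: word runs (with internal hyphens and decimal
    points) become word tokens; every other punctuation character is its own
    token.  Case is preserved unless ``fold_case``."""
    toks = []
    for m in _TOKEN_RE.finditer(sentence_text):
        s = m.group(0)
        toks.append(Token(surface=s.lower() if fold_case else s))
    return toks


def redact(text: str, terms: list[str]) -> str:
    """Mask every case-insensitive occurrence of each term with ``XXXX``.

    Longest terms are matched first; substrings inside longer words are
    masked too (plain string matching, a documented limitation).
    """
    for term in sorted((t for t in terms if t), key=len, reverse=True):
        text = re.sub(re.escape(term), "XXXX", text, flags=re.IGNORECASE)
    return text


def text_to_document(text: str, doc_id: str, case_id: str, doc_type: str = "other",
                     fold_case: bool = False) -> Document:
    sentences = []
    for a, b in chunk_sentences(text):
        sentences.append(Sentence(tokens=tokenize(text[a:b], fold_case=fold_case), char_span=(a, b)))
    return Document(doc_id=doc_id, case_id=case_id, doc_type=doc_type, sentences=sentences)


_DOC_TYPES = {"mdt", "letter", "pathology", "imaging", "other"}


def _read_tsv(path: Path, required: list[str]) -> list[dict[str, str]]:
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise CorpusError(f"{path}: expected tab-separated columns {required}, got {reader.fieldnames}")
        return [dict(row) for row in reader]


def load_corpus(manifest_path: str | Path, labels_path: Optional[str | Path] = None,
                fold_case: bool = False) -> Corpus:
    """Load a corpus from a manifest TSV (`case_id doc_id doc_type path`) and
    an optional labels TSV (`case_id outcome value kind`).

    Case order is manifest order of first appearance.  Document paths are
    resolved relative to the manifest location.
    """
    manifest_path = Path(manifest_path)
    rows = _read_tsv(manifest_path, ["case_id", "doc_id", "doc_type", "path"])
    if not rows:
        raise CorpusError(f"{manifest_path}: no cases in manifest")
    cases: dict[str, Case] = {}
    seen_docs: set[str] = set()
    for i, row in enumerate(rows, start=2):
        cid, did, dtype, p = row["case_id"], row["doc_id"], row["doc_type"], row["path"]
        if did in seen_docs:
            raise CorpusError(f"{manifest_path} line {i}: duplicate doc_id {did!r}")
        seen_docs.add(did)
        if dtype not in _DOC_TYPES:
            dtype = "other"
        fpath = Path(p)
        if not fpath.is_absolute():
            fpath = manifest_path.parent / fpath
        try:
            text = fpath.read_text(encoding="utf-8")
        except OSError as exc:
            raise CorpusError(f"{manifest_path} line {i}: cannot read {p!r}: {exc}") from exc
        cases.setdefault(cid, Case(case_id=cid))
        cases[cid].documents.append(text_to_document(text, did, cid, dtype, fold_case=fold_case))

    outcomes: dict[str, Outcome] = {}
    if labels_path is not None:
        lrows = _read_tsv(Path(labels_path), ["case_id", "outcome", "value", "kind"])
        acc: dict[str, tuple[str, dict[str, float]]] = {}
        for i, row in enumerate(lrows, start=2):
            cid, name, val, kind = row["case_id"], row["outcome"], row["value"], row["kind"]
            if cid not in cases:
                raise CorpusError(f"{labels_path} line {i}: label for unknown case {cid!r}")
            kind0, vals = acc.setdefault(name, (kind, {}))
            if kind != kind0:
                raise CorpusError(f"{labels_path} line {i}: outcome {name!r} kind changed")
            if cid in vals:
                raise CorpusError(f"{labels_path} line {i}: duplicate ({cid!r}, {name!r}) label")
            try:
                vals[cid] = float(val)
            except ValueError as exc:
                raise CorpusError(f"{labels_path} line {i}: bad value {val!r}") from exc
            cases[cid].outcomes[name] = vals[cid]
        for name, (kind, vals) in acc.items():
            outcomes[name] = Outcome(name=name, kind=kind, values=vals)

    return Corpus(list(cases.values()), outcomes)
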