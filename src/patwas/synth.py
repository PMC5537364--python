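"""Synthetic case-labelled corpora with planted associations.

Background text is i.i.d. Zipf-distributed tokens (exponent 1.1 by default,
emulating natural-language frequency decay).  Binary patterns are planted as
contiguous phrases with class-conditional insertion probabilities (p1 in
class-1 cases, p0 in class-0); numeric patterns as "left <value> right" with
class-conditional Normal values rounded to one decimal.  Planted phrases use
reserved out-of-vocabulary tokens by default, so ground-truth counts are
unambiguous; ``collide=True`` mixes them into the vocabulary for realism.

The generator is fully deterministic given (spec, seed): identical inputs
yield byte-identical documents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .corpus import Case, Corpus, Outcome, text_to_document

__all__ = [
    "PlantedPattern",
    "PlantedNumeric",
    "SyntheticSpec",
    "generate",
    "write_corpus_files",
]


@dataclass(frozen=True)
class PlantedPattern:
    tokens: tuple[str, ...]
    p1: float  # insertion probability in class-1 cases
    p0: float  # insertion probability in class-0 cases

    def __post_init__(self) -> None:
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1):
            raise ValueError("insertion probabilities must be in [0, 1]")


@dataclass(frozen=True)
class PlantedNumeric:
    left: tuple[str, ...]
    right: tuple[str, ...]
    mean1: float
    mean0: float
    sd: float
    p_insert: float = 1.0  # probability the construct appears in a case


@dataclass
class SyntheticSpec:
    n_cases: int = 80
    docs_per_case: int = 1
    sentences_per_doc: int = 4
    sentence_len: tuple[int, int] = (6, 12)  # uniform bounds, inclusive
    vocab_size: int = 50
    zipf_exponent: float = 1.1
    planted_binary: tuple[PlantedPattern, ...] = ()
    planted_numeric: tuple[PlantedNumeric, ...] = ()
    class_balance: float = 0.5
    seed: int = 0
    collide: bool = False

    def __post_init__(self) -> None:
        if self.vocab_size < 10:
            raise ValueError("vocabulary size must be >= 10")
        if not (0 < self.class_balance < 1):
            raise ValueError("class balance must be in (0, 1)")


def _zipf_probs(n: int, a: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** a
    return w / w.sum()


def generate(spec: SyntheticSpec) -> tuple[Corpus, dict]:
    """Generate a corpus and its ground-truth manifest.

    The ground truth records, for every planted pattern, the realized
    per-class insertion counts and the implied (Haldane-corrected) odds
    ratio, plus per-case numeric values for numeric patterns.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = [f"w{i:03d}" for i in range(spec.vocab_size)]
    probs = _zipf_probs(spec.vocab_size, spec.zipf_exponent)

    n1 = int(round(spec.n_cases * spec.class_balance))
    labels = np.array([1] * n1 + [0] * (spec.n_cases - n1))
    rng.shuffle(labels)

    vocab_set = set(vocab)
    for p in spec.planted_binary:
        if not spec.collide and any(t in vocab_set for t in p.tokens):
            import warnings

            warnings.warn(f"planted phrase {p.tokens} collides with vocabulary; signal dilutes")

    cases: list[Case] = []
    gt_binary = [{"tokens": list(p.tokens), "n1": 0, "n0": 0} for p in spec.planted_binary]
    gt_numeric = [{"left": list(p.left), "right": list(p.right), "values": {}}
                  for p in spec.planted_numeric]
    lo, hi = spec.sentence_len
    for ci in range(spec.n_cases):
        cid = f"case{ci:04d}"
        y = int(labels[ci])
        case = Case(case_id=cid, outcomes={"status": float(y)})
        docs_sentences: list[list[list[str]]] = []
        for d in range(spec.docs_per_case):
            doc_sents = []
            for s in range(spec.sentences_per_doc):
                ln = int(rng.integers(lo, hi + 1))
                doc_sents.append([vocab[i] for i in rng.choice(spec.vocab_size, size=ln, p=probs)])
            docs_sentences.append(doc_sents)

        # each planted construct goes into its own sentence (sampled without
        # replacement while slots last) so one insertion cannot split another
        n_slots = spec.docs_per_case * spec.sentences_per_doc
        n_planted = len(spec.planted_binary) + len(spec.planted_numeric)
        slots = rng.permutation(n_slots)
        if n_planted > n_slots:
            slots = rng.integers(0, n_slots, size=n_planted)

        def splice(slot_i: int, fragment: list[str]) -> None:
            d, s = divmod(int(slots[slot_i % len(slots)]), spec.sentences_per_doc)
            sent = docs_sentences[d][s]
            pos = int(rng.integers(len(sent) + 1))
            docs_sentences[d][s] = sent[:pos] + fragment + sent[pos:]

        for pi, p in enumerate(spec.planted_binary):
            prob = p.p1 if y == 1 else p.p0
            if rng.random() < prob:
                gt_binary[pi]["n1" if y == 1 else "n0"] += 1
                splice(pi, list(p.tokens))

        for pi, p in enumerate(spec.planted_numeric):
            if rng.random() < p.p_insert:
                mean = p.mean1 if y == 1 else p.mean0
                value = round(float(rng.normal(mean, p.sd)), 1)
                gt_numeric[pi]["values"][cid] = value
                splice(len(spec.planted_binary) + pi,
                       list(p.left) + [f"{value:g}"] + list(p.right))

        for d, doc_sents in enumerate(docs_sentences):
            text = "\n".join(" ".join(s) + " ." for s in doc_sents) + "\n"
            case.documents.append(text_to_document(text, doc_id=f"{cid}_d{d}", case_id=cid,
                                                   doc_type="other"))
        cases.append(case)

    outcome = Outcome(name="status", kind="binary",
                      values={c.case_id: c.outcomes["status"] for c in cases})
    corpus = Corpus(cases, {"status": outcome})

    n1_total = int(labels.sum())
    n0_total = spec.n_cases - n1_total
    for g in gt_binary:
        a, b = g["n1"], g["n0"]
        c, d = n1_total - a, n0_total - b
        aa, bb, cc, dd = (x + 0.5 if 0 in (a, b, c, d) else x for x in (a, b, c, d))
        g["log_or"] = math.log((aa * dd) / (bb * cc))
    ground_truth = {
        "n_cases": spec.n_cases,
        "n_class1": n1_total,
        "seed": spec.seed,
        "binary": gt_binary,
        "numeric": gt_numeric,
    }
    return corpus, ground_truth


def write_corpus_files(corpus: Corpus, ground_truth: dict, out_dir: str | Path) -> None:
    """Write documents, manifest TSV, labels TSV and ground-truth JSON so the
    generated corpus can be re-loaded through :func:`patwas.corpus.load_corpus`."""
    out = Path(out_dir)
    (out / "docs").mkdir(parents=True, exist_ok=True)
    man_lines = ["case_id\tdoc_id\tdoc_type\tpath"]
    lab_lines = ["case_id\toutcome\tvalue\tkind"]
    for case in corpus.cases:
        for doc in case.documents:
            rel = f"docs/{doc.doc_id}.txt"
            text = "\n".join(" ".join(t.surface for t in s.tokens) for s in doc.sentences) + "\n"
            (out / rel).write_text(text, encoding="utf-8")
            man_lines.append(f"{case.case_id}\t{doc.doc_id}\t{doc.doc_type}\t{rel}")
    for name, oc in corpus.outcomes.items():
        for cid, v in oc.values.items():
            lab_lines.append(f"{cid}\t{name}\t{v:g}\t{oc.kind}")
    (out / "manifest.tsv").write_text("\n".join(man_lines) + "\n", encoding="utf-8")
    (out / "labels.tsv").write_text("\n".join(lab_lines) + "\n", encoding="utf-8")
    (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2), encoding="utf-8")
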