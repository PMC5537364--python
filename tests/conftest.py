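import numpy as np
import pytest

from patwas.corpus import Case, Corpus, Outcome, text_to_document


def corpus_from_texts(case_texts: dict[str, str | list[str]],
                      outcomes: dict[str, dict[str, float]] | None = None,
                      kinds: dict[str, str] | None = None) -> Corpus:
    """Build a corpus directly from {case_id: text or [texts]}."""
    cases = []
    for cid, texts in case_texts.items():
        if isinstance(texts, str):
            texts = [texts]
        docs = [text_to_document(t, doc_id=f"{cid}_d{i}", case_id=cid)
                for i, t in enumerate(texts)]
        cases.append(Case(case_id=cid, documents=docs))
    ocs = {}
    for name, vals in (outcomes or {}).items():
        kind = (kinds or {}).get(name, "binary")
        ocs[name] = Outcome(name=name, kind=kind, values=vals)
        for c in cases:
            if c.case_id in vals:
                c.outcomes[name] = vals[c.case_id]
    return Corpus(cases, ocs)


@pytest.fixture
def make_corpus():
    return corpus_from_texts


def random_corpus(rng: np.random.Generator, n_cases: int, n_sentences: int = 2,
                  sent_len: tuple[int, int] = (5, 10), alphabet: int = 6) -> Corpus:
    """A small random corpus over tokens t0..t{alphabet-1} (one doc/case)."""
    vocab = [f"t{i}" for i in range(alphabet)]
    texts = {}
    for ci in range(n_cases):
        sents = []
        for _ in range(n_sentences):
            ln = int(rng.integers(sent_len[0], sent_len[1] + 1))
            sents.append(" ".join(vocab[i] for i in rng.integers(0, alphabet, ln)) + " .")
        texts[f"c{ci}"] = "\n".join(sents)
    return corpus_from_texts(texts)
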