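"""Feature search: n-gram enumeration, tagged patterns, numeric features."""

import numpy as np
import pytest

from patwas.annotate import stem_tokens, tag_numbers
from patwas.search import (build_profile, enumerate_ngrams,
                           enumerate_tagged_patterns, extract_numeric_features,
                           lit, render_pattern, tag)
from conftest import corpus_from_texts, random_corpus


def brute_force_ngrams(corpus, min_support, max_len=None):
    """Oracle: every within-sentence window, tallied by case."""
    found: dict[tuple, set] = {}
    for ci, _, _, sent in corpus.iter_sentences():
        surfs = [t.surface for t in sent.tokens]
        top = len(surfs) if max_len is None else min(max_len, len(surfs))
        for n in range(1, top + 1):
            for i in range(len(surfs) - n + 1):
                found.setdefault(tuple(surfs[i:i + n]), set()).add(ci)
    return {pat: cs for pat, cs in found.items() if len(cs) >= min_support}


class TestEnumerateNgrams:
    def test_forced_enumeration(self):
        corpus = corpus_from_texts({"c1": "the right tonsil", "c2": "the right base"})
        feats = enumerate_ngrams(corpus, min_support=2)
        rendered = {f.rendered() for f in feats}
        assert rendered == {"the", "right", "the right"}
        assert all(f.profile.tolist() == [True, True] for f in feats)

    def test_sentence_boundary_blocks_ngram(self):
        corpus = corpus_from_texts({"c1": "a b . c", "c2": "a b . c"})
        feats = enumerate_ngrams(corpus, min_support=1)
        assert "b c" not in {f.rendered() for f in feats}

    def test_matches_brute_force_on_random_corpora(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            corpus = random_corpus(rng, n_cases=5, n_sentences=2, sent_len=(5, 20), alphabet=6)
            feats = enumerate_ngrams(corpus, min_support=2)
            got = {tuple(el.value for el in f.pattern):
                   {i for i, b in enumerate(f.profile) if b} for f in feats}
            assert got == brute_force_ngrams(corpus, 2)

    def test_anti_monotone_support(self):
        rng = np.random.default_rng(3)
        corpus = random_corpus(rng, n_cases=6, n_sentences=2, sent_len=(8, 15), alphabet=4)
        feats = enumerate_ngrams(corpus, min_support=1)
        by_pattern = {tuple(el.value for el in f.pattern): f.support for f in feats}
        for pat, sup in by_pattern.items():
            for ext, esup in by_pattern.items():
                if len(ext) > len(pat) and any(
                        ext[i:i + len(pat)] == pat for i in range(len(ext) - len(pat) + 1)):
                    assert esup <= sup

    def test_deterministic_order(self):
        rng = np.random.default_rng(5)
        corpus = random_corpus(rng, n_cases=4, alphabet=5)
        a = enumerate_ngrams(corpus, min_support=2)
        b = enumerate_ngrams(corpus, min_support=2)
        assert [f.rendered() for f in a] == [f.rendered() for f in b]
        keys = [(len(f.pattern), f.rendered()) for f in a]
        assert keys == sorted(keys)

    def test_group_tokens_participate(self, make_corpus):
        from patwas.annotate import group_from_parse
        corpus = make_corpus({"c1": "base of tongue", "c2": "base of tongue"})
        for _, _, _, s in corpus.iter_sentences():
            group_from_parse(s, "(NP (NN base) (PP (IN of) (NP (NN tongue))))")
        feats = enumerate_ngrams(corpus, min_support=2)
        assert "base_of_tongue" in {f.rendered() for f in feats}


def brute_force_tagged(corpus, min_support, max_len):
    from itertools import product
    found: dict[tuple, set] = {}
    for ci, _, _, sent in corpus.iter_sentences():
        reps = [[lit(t.surface)] + [tag(x) for x in sorted(t.tags)] for t in sent.tokens]
        for n in range(1, min(max_len, len(reps)) + 1):
            for i in range(len(reps) - n + 1):
                for combo in product(*reps[i:i + n]):
                    found.setdefault(combo, set()).add(ci)
    return {p: cs for p, cs in found.items()
            if len(cs) >= min_support and not all(el.kind == "lit" for el in p)}


class TestTaggedPatterns:
    def test_pos_generalisation(self, make_corpus):
        corpus = make_corpus({"c1": "right tonsil", "c2": "left tonsil"})
        for _, _, _, s in corpus.iter_sentences():
            s.tokens[0].tags.add("POS:JJ")
        feats = enumerate_tagged_patterns(corpus, min_support=2, max_len=3)
        rendered = {f.rendered() for f in feats}
        assert "<POS:JJ> tonsil" in rendered
        covering = [f for f in feats if f.rendered() == "<POS:JJ> tonsil"]
        assert covering[0].profile.tolist() == [True, True]

    def test_untagged_corpus_yields_nothing_extra(self):
        corpus = corpus_from_texts({"c1": "a b", "c2": "a b"})
        assert enumerate_tagged_patterns(corpus, min_support=2) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            corpus = random_corpus(rng, n_cases=3, n_sentences=1, sent_len=(4, 8), alphabet=4)
            for _, _, _, s in corpus.iter_sentences():
                for t in s.tokens:
                    if rng.random() < 0.5:
                        t.tags.add(f"A:{int(rng.integers(2))}")
                    if rng.random() < 0.3:
                        t.tags.add(f"B:{int(rng.integers(2))}")
            feats = enumerate_tagged_patterns(corpus, min_support=2, max_len=3)
            got = {f.pattern: {i for i, b in enumerate(f.profile) if b} for f in feats}
            assert got == brute_force_tagged(corpus, 2, 3)


class TestBuildProfile:
    def test_present_absent(self):
        corpus = corpus_from_texts({"c1": "a b c", "c2": "x a b", "c3": "c b a"})
        prof = build_profile((lit("a"), lit("b")), corpus)
        assert prof.tolist() == [True, True, False]

    def test_overlong_pattern_all_zero(self):
        corpus = corpus_from_texts({"c1": "a b"})
        prof = build_profile(tuple(lit(x) for x in "abcde"), corpus)
        assert not prof.any()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        corpus = random_corpus(rng, n_cases=6, n_sentences=2, sent_len=(5, 12), alphabet=5)
        sents = [[t.surface for t in s.tokens] for _, _, _, s in corpus.iter_sentences()]
        for _ in range(50):
            src = sents[int(rng.integers(len(sents)))]
            n = int(rng.integers(1, 4))
            i = int(rng.integers(0, max(1, len(src) - n)))
            pat = tuple(lit(x) for x in src[i:i + n])
            expected = np.zeros(corpus.n_cases, dtype=bool)
            for ci, _, _, s in corpus.iter_sentences():
                surfs = [t.surface for t in s.tokens]
                tokens = tuple(el.value for el in pat)
                if any(tuple(surfs[j:j + n]) == tokens for j in range(len(surfs) - n + 1)):
                    expected[ci] = True
            assert build_profile(pat, corpus).tolist() == expected.tolist()


class TestNumericFeatures:
    def _prep(self, texts):
        corpus = corpus_from_texts(texts)
        for _, _, _, s in corpus.iter_sentences():
            tag_numbers(s)
        return corpus

    def test_flank_extraction(self):
        corpus = self._prep({"c1": "contains 3 metastatic nodes",
                             "c2": "contains 5 metastatic nodes"})
        feats = extract_numeric_features(corpus, max_flank_len=2, min_support=2)
        by_name = {f.rendered(): f for f in feats}
        f = by_name["contains <NUMBER> metastatic nodes"]
        assert f.values == {"c1": 3.0, "c2": 5.0}

    def test_ambiguous_flank_discarded(self):
        corpus = self._prep({
            "c1": "contains 3 metastatic nodes and contains 5 metastatic nodes",
            "c2": "contains 7 metastatic nodes"})
        feats = extract_numeric_features(corpus, max_flank_len=2, min_support=2)
        assert "contains <NUMBER> metastatic" not in {f.rendered() for f in feats}

    def test_age_years_extraction(self):
        corpus = self._prep({f"c{k}": f"age {v} years old" for k, v in
                             enumerate([10, 20, 30, 40])})
        feats = extract_numeric_features(corpus, max_flank_len=1, min_support=4)
        f = {x.rendered(): x for x in feats}["age <NUMBER> years"]
        assert sorted(f.values.values()) == [10.0, 20.0, 30.0, 40.0]

    def test_at_most_one_value_per_case(self):
        rng = np.random.default_rng(13)
        corpus = random_corpus(rng, n_cases=5, n_sentences=3, sent_len=(5, 10), alphabet=4)
        # sprinkle numbers into the text
        for _, _, _, s in corpus.iter_sentences():
            for t in s.tokens:
                if rng.random() < 0.2:
                    t.surface = str(int(rng.integers(1, 50)))
            tag_numbers(s)
        for f in extract_numeric_features(corpus, max_flank_len=2, min_support=2):
            assert len(f.values) == len(set(f.values))


class TestRendering:
    def test_punctuation_attaches_left(self):
        assert render_pattern((lit("M0"), lit(","))) == "M0,"
        assert render_pattern((lit(":"), lit("Positive"))) == ": Positive"

    def test_tag_rendering(self):
        assert render_pattern((tag("POS:JJ"), lit("tonsil"))) == "<POS:JJ> tonsil"
        assert render_pattern((tag("NUM"),)) == "<NUM>"
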