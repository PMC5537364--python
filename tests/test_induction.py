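"""Token-regex induction: grouping, alignment, consolidation, matching."""

import itertools

import numpy as np
import pytest

from patwas.corpus import Outcome
from patwas.induction import (Group, InductionError, Literal, align_pair,
                              consolidate, group_candidates, induce_and_rescore,
                              match_regex, parse_regex, render_regex)
from patwas.search import BinaryFeature, build_profile, lit
from patwas.stats import AssociationResult, fisher_two_sided, ContingencyTable2x2
from conftest import corpus_from_texts, random_corpus


def feat(tokens, bits=(1, 0)):
    return BinaryFeature(pattern=tuple(lit(t) for t in tokens.split()),
                         profile=np.array(bits, dtype=bool))


class TestGroupCandidates:
    def test_shared_boundaries_grouped(self):
        groups = group_candidates([feat("a b c"), feat("a d c"), feat("a c")])
        assert set(groups) == {("a", "c")}
        assert len(groups[("a", "c")]) == 3

    def test_different_start_no_group(self):
        assert group_candidates([feat("a b"), feat("c b")]) == {}

    def test_metastasis_example(self):
        groups = group_candidates([feat("extensive bone metastasis"),
                                   feat("extensive liver metastasis")])
        assert set(groups) == {("extensive", "metastasis")}


class TestAlignPair:
    def test_gap_alignment(self):
        al = align_pair("a b c".split(), "a c".split())
        assert al.score == 1
        assert al.columns == [("a", "a"), ("b", None), ("c", "c")]

    def test_identical_sequences(self):
        al = align_pair("x y z".split(), "x y z".split())
        assert al.score == 3 and all(a == b for a, b in al.columns)

    def test_mismatch_preferred_over_two_gaps(self):
        al = align_pair(["a"], ["b"])
        assert al.score == -1 and al.columns == [("a", "b")]

    def test_optimal_vs_exhaustive(self):
        """NW score equals the best over all monotone alignments."""
        def best_score(a, b):
            # recursive exhaustive search
            def go(i, j):
                if i == len(a) and j == len(b):
                    return 0
                cands = []
                if i < len(a) and j < len(b):
                    cands.append((1 if a[i] == b[j] else -1) + go(i + 1, j + 1))
                if i < len(a):
                    cands.append(-1 + go(i + 1, j))
                if j < len(b):
                    cands.append(-1 + go(i, j + 1))
                return max(cands)
            return go(0, 0)

        rng = np.random.default_rng(41)
        sigma = list("wxyz")
        for _ in range(40):
            a = [sigma[i] for i in rng.integers(0, 4, rng.integers(1, 7))]
            b = [sigma[i] for i in rng.integers(0, 4, rng.integers(1, 6))]
            assert align_pair(a, b).score == best_score(a, b)


class TestConsolidate:
    def test_alternation(self):
        rx = consolidate([tuple("extensive bone metastasis".split()),
                          tuple("extensive liver metastasis".split())])
        assert render_regex(rx) == "extensive (bone|liver) metastasis"

    def test_optional(self):
        rx = consolidate([tuple("a reformed cigarette smoker".split()),
                          tuple("a cigarette smoker".split())])
        assert render_regex(rx) == "a (reformed)? cigarette smoker"

    def test_multivariant_multitoken(self):
        rx = consolidate([tuple("SCC of the right tonsil -".split()),
                          tuple("SCC of the right base of tongue -".split()),
                          tuple("SCC of the right glossotonsillar sulcus -".split())])
        assert render_regex(rx) == \
            "SCC of the right (tonsil|base of tongue|glossotonsillar sulcus) -"

    def test_identical_members_error(self):
        with pytest.raises(InductionError):
            consolidate([("a", "b"), ("a", "b")])

    def test_boundary_literals_invariant(self):
        rng = np.random.default_rng(43)
        sigma = ["p", "q", "r", "s"]
        for _ in range(50):
            members = set()
            while len(members) < 2:
                mid = tuple(sigma[i] for i in rng.integers(0, 4, rng.integers(0, 4)))
                members.add(("L",) + mid + ("R",))
            rx = consolidate(sorted(members))
            assert isinstance(rx.elements[0], Literal) and rx.elements[0].token == "L"
            assert isinstance(rx.elements[-1], Literal) and rx.elements[-1].token == "R"

    def test_soundness_every_member_matches(self):
        rng = np.random.default_rng(47)
        sigma = ["p", "q", "r"]
        for _ in range(50):
            members = set()
            while len(members) < int(rng.integers(2, 5)):
                mid = tuple(sigma[i] for i in rng.integers(0, 3, rng.integers(0, 4)))
                members.add(("L",) + mid + ("R",))
            rx = consolidate(sorted(members))
            corpus = corpus_from_texts(
                {f"m{i}": " ".join(m) for i, m in enumerate(sorted(members))})
            profile = match_regex(rx, corpus)
            assert profile.all(), f"{render_regex(rx)} missed a member"


def expand_regex(rx):
    """Oracle: all concrete token sequences a linear regex can match."""
    pools = []
    for el in rx.elements:
        if isinstance(el, Literal):
            pools.append([(el.token,)])
        else:
            pool = [tuple(v) for v in el.variants]
            if el.optional:
                pool.append(())
            pools.append(pool)
    return {tuple(itertools.chain.from_iterable(combo))
            for combo in itertools.product(*pools)}


class TestMatchRegex:
    def test_alternation_matches(self):
        corpus = corpus_from_texts({"c1": "x a c d y"})
        rx = parse_regex("a (b|c) d")
        assert match_regex(rx, corpus).tolist() == [True]

    def test_optional_semantics(self):
        corpus = corpus_from_texts({"c1": "a d", "c2": "a b d", "c3": "a c d"})
        rx = parse_regex("a (b)? d")
        assert match_regex(rx, corpus).tolist() == [True, True, False]

    def test_profiles_equal_expansion_oracle(self):
        rng = np.random.default_rng(53)
        corpus = random_corpus(rng, n_cases=6, n_sentences=2, sent_len=(6, 12), alphabet=4)
        sents = [[t.surface for t in s.tokens] for _, _, _, s in corpus.iter_sentences()]
        for _ in range(100):
            # induce a regex from random same-boundary substrings of the corpus
            members = set()
            for _ in range(int(rng.integers(2, 4))):
                src = sents[int(rng.integers(len(sents)))]
                n = int(rng.integers(2, min(5, len(src)) + 1))
                i = int(rng.integers(0, len(src) - n + 1))
                members.add(("L",) + tuple(src[i:i + n]) + ("R",))
            if len(members) < 2:
                continue
            rx = consolidate(sorted(members))
            got = match_regex(rx, corpus)
            expected = np.zeros(corpus.n_cases, dtype=bool)
            for variant in expand_regex(rx):
                expected |= build_profile(tuple(lit(t) for t in variant), corpus)
            assert got.tolist() == expected.tolist()


class TestRoundTrip:
    def test_table_style_expression_parses(self):
        rx = parse_regex("irradiation (and|with) (or without|concurrent) chemotherapy")
        assert len(rx.elements) == 4
        assert render_regex(rx) == \
            "irradiation (and|with) (or without|concurrent) chemotherapy"

    def test_render_forced_notation(self):
        rx = parse_regex("a (b|c d) e")
        assert rx.elements[1] == Group(variants=(("b",), ("c", "d")), optional=False)

    def test_random_round_trips(self):
        rng = np.random.default_rng(59)
        sigma = ["aa", "bb", "cc", "dd"]
        for _ in range(200):
            elements = [Literal(sigma[int(rng.integers(4))])]
            for _ in range(int(rng.integers(0, 4))):
                if rng.random() < 0.5:
                    elements.append(Literal(sigma[int(rng.integers(4))]))
                else:
                    n_var = int(rng.integers(1, 4))
                    variants = set()
                    while len(variants) < n_var:
                        variants.add(tuple(sigma[i] for i in
                                           rng.integers(0, 4, int(rng.integers(1, 3)))))
                    optional = bool(rng.random() < 0.5) or n_var == 1
                    elements.append(Group(variants=tuple(sorted(variants)), optional=optional))
            elements.append(Literal(sigma[int(rng.integers(4))]))
            from patwas.induction import TokenRegex
            rx = TokenRegex(elements=tuple(elements))
            assert parse_regex(render_regex(rx)) == rx

    def test_parse_error_positions(self):
        with pytest.raises(InductionError, match="position"):
            parse_regex("a ) b")


class TestInduceAndRescore:
    def test_disjoint_profiles_pool_support(self):
        # 6 positive, 6 negative cases; two member patterns each hit 3 positives
        texts = {}
        for i in range(3):
            texts[f"p{i}"] = "L xx R"
        for i in range(3, 6):
            texts[f"p{i}"] = "L yy R"
        for i in range(6):
            texts[f"n{i}"] = "filler words only"
        outcomes = {"y": {**{f"p{i}": 1.0 for i in range(6)},
                          **{f"n{i}": 0.0 for i in range(6)}}}
        corpus = corpus_from_texts(texts, outcomes=outcomes)
        fa = BinaryFeature(pattern=tuple(lit(t) for t in "L xx R".split()),
                           profile=build_profile(tuple(lit(t) for t in "L xx R".split()), corpus))
        fb = BinaryFeature(pattern=tuple(lit(t) for t in "L yy R".split()),
                           profile=build_profile(tuple(lit(t) for t in "L yy R".split()), corpus))
        outcome = corpus.outcomes["y"]
        member_results = []
        for f in (fa, fb):
            from patwas.stats import associate
            member_results.append(associate(f, outcome, corpus))
        regex_results = induce_and_rescore(member_results, corpus, outcome)
        assert len(regex_results) == 1
        rr = regex_results[0]
        assert rr.support == 6
        assert rr.p_value < min(r.p_value for r in member_results)
        # check against the exact tables: members 3/0 vs regex 6/0
        p_member = fisher_two_sided(ContingencyTable2x2(3, 0, 3, 6))
        p_regex = fisher_two_sided(ContingencyTable2x2(6, 0, 0, 6))
        assert member_results[0].p_value == pytest.approx(p_member)
        assert rr.p_value == pytest.approx(p_regex)

    def test_profile_dominates_members(self):
        rng = np.random.default_rng(61)
        corpus = random_corpus(rng, n_cases=6, n_sentences=2, sent_len=(6, 10), alphabet=4)
        from patwas.search import enumerate_ngrams
        from patwas.stats import associate_all
        outcome = Outcome(name="y", kind="binary",
                          values={cid: float(i % 2) for i, cid in enumerate(corpus.case_ids)})
        corpus.outcomes["y"] = outcome
        feats = enumerate_ngrams(corpus, min_support=2)
        results = associate_all(feats, outcome, corpus)
        by_pattern = {tuple(el.value for el in r.feature.pattern): r for r in results}
        for rr in induce_and_rescore(results, corpus, outcome):
            member_profiles = [by_pattern[m].feature.profile
                               for m in rr.feature.regex.members if m in by_pattern]
            if member_profiles:
                union = np.logical_or.reduce(member_profiles)
                assert (rr.feature.profile | union).tolist() == rr.feature.profile.tolist()
                assert rr.support >= max(int(p.sum()) for p in member_profiles)
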