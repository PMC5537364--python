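"""Univariate association statistics — the pattern-wide association scan.

Every feature is tested against the outcome with a non-parametric statistic
chosen by the type pair:

====================  =================  =========================================
feature               outcome            statistic
====================  =================  =========================================
binary (pattern)      binary             odds ratio + two-sided Fisher exact test
binary (pattern)      numeric            AUC (Mann-Whitney U, tie-corrected normal)
numeric (A <N> B)     binary             AUC (Mann-Whitney U)
numeric (A <N> B)     numeric            Spearman's rho (t approximation)
====================  =================  =========================================

Raw p-values are reported without multiple-testing correction: exhaustively
generated patterns are heavily dependent, so Bonferroni/BH assumptions do
not hold; an optional Benjamini-Hochberg column is available for reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .corpus import Corpus, Outcome
from .search import BinaryFeature, NumericFeature

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "fisher_two_sided",
    "odds_ratio",
    "rank_auc",
    "spearman",
    "associate",
    "associate_all",
    "fisher_rxc_montecarlo",
    "bh_adjust",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d) = (feat+/out+, feat+/out-; feat-/out+, feat-/out-)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class AssociationResult:
    feature: Union[BinaryFeature, NumericFeature, "object"]
    stat: str  # "OR" | "AUC" | "rho"
    estimate: float
    p_value: float
    n_used: int
    log_or: Optional[float] = None
    direction: int = 0
    pattern_type: str = "ngram"

    def rendered(self) -> str:
        return self.feature.rendered()

    @property
    def support(self) -> int:
        return self.feature.support

    def effect_magnitude(self) -> float:
        """|log OR|, |AUC - 0.5| or |rho| — for ranking ties."""
        if self.stat == "OR":
            return abs(self.log_or) if self.log_or is not None and math.isfinite(self.log_or) else math.inf
        if self.stat == "AUC":
            return abs(self.estimate - 0.5)
        return abs(self.estimate)


def fisher_two_sided(table: ContingencyTable2x2) -> float:
    """Exact two-sided Fisher p: the sum of hypergeometric probabilities of
    all same-margin tables no more probable than the observed one (relative
    tolerance 1 + 1e-7).  A zero margin carries no information: p = 1."""
    if min(table.a + table.b, table.c + table.d, table.a + table.c, table.b + table.d) == 0:
        return 1.0
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided").pvalue)


def odds_ratio(table: ContingencyTable2x2, zero_correction: bool = True) -> tuple[float, float]:
    """(OR, natural-log OR) = ad/bc; with ``zero_correction`` any zero cell
    triggers the Haldane-Anscombe +0.5 on all four cells.  Without
    correction a zero denominator yields +inf."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if zero_correction and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        est = math.inf if a * d > 0 else math.nan
        return est, math.log(est) if est == math.inf else math.nan
    est = (a * d) / (b * c)
    return est, math.log(est) if est > 0 else -math.inf


def rank_auc(group_pos: Sequence[float], group_neg: Sequence[float],
             exact_below: int = 0) -> tuple[float, float]:
    """AUC = P(pos > neg) with half-credit ties, plus the Mann-Whitney p
    (tie-corrected normal approximation with continuity correction; exact
    enumeration when the combined sample is below ``exact_below``)."""
    pos, neg = np.asarray(group_pos, float), np.asarray(group_neg, float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if 0 < len(pos) + len(neg) < exact_below else "asymptotic"
    res = sps.mannwhitneyu(pos, neg, alternative="two-sided",
                           use_continuity=True, method=method)
    auc = float(res.statistic) / (len(pos) * len(neg))
    return auc, float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho on mid-ranks with the t approximation (n - 2 df)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rho undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _binary_outcome_vector(outcome: Outcome, case_ids: Sequence[str]) -> dict[str, float]:
    return {cid: outcome.values[cid] for cid in case_ids if cid in outcome.values}


def associate(feature: Union[BinaryFeature, NumericFeature], outcome: Outcome,
              corpus: Corpus, zero_correction: bool = True) -> Optional[AssociationResult]:
    """Dispatch the appropriate test; returns None when the split is
    degenerate (a group is empty or a vector constant).

    Cases with a missing outcome — and, for numeric features, cases without
    an extracted value — are excluded (complete-case analysis); ``n_used``
    records the informative sample size.
    """
    case_ids = corpus.case_ids
    labelled = _binary_outcome_vector(outcome, case_ids)
    if hasattr(feature, "profile"):  # binary feature (pattern or token regex)
        present = {cid for cid, bit in zip(case_ids, feature.profile) if bit}
        if outcome.kind == "binary":
            a = sum(1 for c, v in labelled.items() if c in present and v == 1)
            b = sum(1 for c, v in labelled.items() if c in present and v == 0)
            c_ = sum(1 for c, v in labelled.items() if c not in present and v == 1)
            d = sum(1 for c, v in labelled.items() if c not in present and v == 0)
            if a + b == 0 or c_ + d == 0 or a + c_ == 0 or b + d == 0:
                return None
            table = ContingencyTable2x2(a, b, c_, d)
            est, lor = odds_ratio(table, zero_correction)
            p = fisher_two_sided(table)
            return AssociationResult(feature=feature, stat="OR", estimate=est, log_or=lor,
                                     p_value=p, n_used=len(labelled),
                                     direction=int(np.sign(lor)) if math.isfinite(lor) else 1,
                                     pattern_type=feature.feature_type)
        pos = [v for c, v in labelled.items() if c in present]
        neg = [v for c, v in labelled.items() if c not in present]
        if not pos or not neg:
            return None
        auc, p = rank_auc(pos, neg)
        return AssociationResult(feature=feature, stat="AUC", estimate=auc, p_value=p,
                                 n_used=len(labelled), direction=int(np.sign(auc - 0.5)),
                                 pattern_type=feature.feature_type)

    # numeric feature
    informative = {c: v for c, v in feature.values.items() if c in labelled}
    if outcome.kind == "binary":
        pos = [v for c, v in informative.items() if labelled[c] == 1]
        neg = [v for c, v in informative.items() if labelled[c] == 0]
        if not pos or not neg:
            return None
        auc, p = rank_auc(pos, neg)
        return AssociationResult(feature=feature, stat="AUC", estimate=auc, p_value=p,
                                 n_used=len(informative), direction=int(np.sign(auc - 0.5)),
                                 pattern_type="numeric")
    cids = sorted(informative)
    x = [informative[c] for c in cids]
    y = [labelled[c] for c in cids]
    try:
        rho, p = spearman(x, y)
    except ValueError:
        return None
    return AssociationResult(feature=feature, stat="rho", estimate=rho, p_value=p,
                             n_used=len(informative), direction=int(np.sign(rho)),
                             pattern_type="numeric")


def associate_all(features: Sequence[Union[BinaryFeature, NumericFeature]],
                  outcome: Outcome, corpus: Corpus) -> list[AssociationResult]:
    out = []
    for f in features:
        r = associate(f, outcome, corpus)
        if r is not None:
            out.append(r)
    return out


def fisher_rxc_montecarlo(table: Sequence[Sequence[int]], replicates: int = 100_000,
                          seed: int = 0) -> float:
    """Monte-Carlo Freeman-Halton p for an RxC table: sample ``replicates``
    tables from the fixed-margin null (Patefield's algorithm) and count those
    no more probable than the observed table; p = (1 + count)/(replicates + 1).
    All-zero rows/columns are dropped first."""
    t = np.asarray(table, dtype=np.int64)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    rm, cm = t.sum(axis=1), t.sum(axis=0)
    rng = np.random.default_rng(seed)
    samples = sps.random_table(rm, cm).rvs(replicates, random_state=rng)
    # log P(table) = const - sum log(cell!); larger sum(gammaln) == less probable
    obs = gammaln(t + 1).sum()
    samp = gammaln(samples + 1).sum(axis=(1, 2))
    count = int(np.sum(samp >= obs - 1e-9))
    return (1 + count) / (replicates + 1)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reference column only)."""
    p = np.asarray(p_values, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = n - rank_from_top
        prev = min(prev, p[idx] * n / i)
        adj[idx] = prev
    return adj
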