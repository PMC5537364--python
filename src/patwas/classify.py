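"""Phenotyping with learned text features.

Top-ranked patterns are decorrelated by UPGMA (average-linkage) clustering
of their occurrence profiles under Euclidean distance, cut into one-tenth of
the sample size (k = max(2, floor(N/10))) clusters; the minimum-p feature
per cluster enters a classifier as a 0/1 covariate.  Predictive accuracy is
the mean out-of-bag AUC over bootstrap runs (default 25).

Feature discovery, filtering, clustering and representative selection run
inside each bootstrap replicate on the resampled cases only, so out-of-bag
labels never leak into feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.naive_bayes import BernoulliNB

from .corpus import Corpus, Outcome
from .reduction import filter_threshold, remove_redundant
from .search import BinaryFeature, build_profile, enumerate_ngrams
from .stats import AssociationResult, associate_all, rank_auc

__all__ = [
    "BootstrapReport",
    "cluster_features",
    "select_representatives",
    "naive_bayes_fit_predict",
    "bootstrap_evaluate",
]


@dataclass
class BootstrapReport:
    n_runs: int
    aucs: list[float]
    mean_auc: float
    seed: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        assert len(self.aucs) == self.n_runs


def cluster_features(results: Sequence[AssociationResult], n_cases: int) -> np.ndarray:
    """UPGMA clustering of occurrence profiles (Euclidean), cut to
    k = max(2, floor(n_cases / 10)) clusters.  With fewer features than k,
    each feature is its own cluster.  Returns 1-based cluster labels."""
    if len(results) < 2:
        return np.ones(len(results), dtype=int)
    k = max(2, n_cases // 10)
    if len(results) <= k:
        return np.arange(1, len(results) + 1)
    X = np.stack([np.asarray(r.feature.profile, dtype=float) for r in results])
    Z = linkage(X, method="average", metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust")


def select_representatives(results: Sequence[AssociationResult],
                           clusters: np.ndarray) -> list[AssociationResult]:
    """Minimum-p feature per cluster; ties by larger support, then rendered
    pattern."""
    best: dict[int, AssociationResult] = {}
    for r, c in zip(results, clusters):
        cur = best.get(int(c))
        key = (r.p_value, -r.support, r.rendered())
        if cur is None or key < (cur.p_value, -cur.support, cur.rendered()):
            best[int(c)] = r
    return [best[c] for c in sorted(best)]


def naive_bayes_fit_predict(X_train: np.ndarray, y_train: np.ndarray,
                            X_test: np.ndarray) -> np.ndarray:
    """Bernoulli naive Bayes with Laplace add-1 smoothing; returns the
    posterior probability of class 1 for each test row."""
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if len(classes) == 1:
        return np.full(len(X_test), 1.0 if classes[0] == 1 else 0.0)
    clf = BernoulliNB(alpha=1.0)
    clf.fit(np.asarray(X_train, dtype=float), y_train)
    pos_col = int(np.where(clf.classes_ == 1)[0][0])
    return clf.predict_proba(np.asarray(X_test, dtype=float))[:, pos_col]


def _logreg_fit_predict(X_train, y_train, X_test) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) == 1:
        return np.full(len(X_test), float(y_train[0]))
    clf = LogisticRegression(max_iter=1000)
    clf.fit(np.asarray(X_train, dtype=float), y_train)
    pos_col = int(np.where(clf.classes_ == 1)[0][0])
    return clf.predict_proba(np.asarray(X_test, dtype=float))[:, pos_col]


CLASSIFIERS: dict[str, Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]] = {
    "nb": naive_bayes_fit_predict,
    "lr": _logreg_fit_predict,
}


@dataclass
class PipelineConfig:
    """Feature-discovery settings used inside each bootstrap replicate."""

    min_support: int = 2
    max_len: Optional[int] = None
    alpha: float = 0.0025
    fallback_top_k: int = 10  # used when no feature clears alpha in a replicate


def _discover_features(corpus: Corpus, outcome: Outcome,
                       config: PipelineConfig) -> list[AssociationResult]:
    feats = enumerate_ngrams(corpus, min_support=config.min_support, max_len=config.max_len)
    kept, _ = remove_redundant(feats)
    results = associate_all(kept, outcome, corpus)
    filtered = filter_threshold(results, config.alpha)
    if not filtered:
        results.sort(key=lambda r: (r.p_value, -r.effect_magnitude(), r.rendered()))
        filtered = results[: config.fallback_top_k]
    return filtered


def bootstrap_evaluate(corpus: Corpus, outcome: Outcome,
                       config: Optional[PipelineConfig] = None,
                       classifier: str | Callable = "nb", n_runs: int = 25,
                       seed: int = 0, nested: bool = True,
                       max_redraws: int = 100) -> BootstrapReport:
    """Bootstrap out-of-bag evaluation of outcome classification.

    Per run: draw cases with replacement; rediscover, filter, cluster and
    select features on the bootstrap sample only (unless ``nested=False``,
    which selects once on all data — optimistic); train the classifier;
    score out-of-bag cases; record the AUC of scores against labels.  Runs
    whose out-of-bag set lacks a class are redrawn.
    """
    config = config or PipelineConfig()
    clf = CLASSIFIERS[classifier] if isinstance(classifier, str) else classifier
    if outcome.kind != "binary":
        raise ValueError("bootstrap evaluation requires a binary outcome")
    labelled_idx = [i for i, cid in enumerate(corpus.case_ids) if cid in outcome.values]
    labels = {cid: outcome.values[cid] for cid in corpus.case_ids if cid in outcome.values}
    rng = np.random.default_rng(seed)

    whole_selection: Optional[list[AssociationResult]] = None
    if not nested:
        results = _discover_features(corpus, outcome, config)
        cl = cluster_features(results, len(labelled_idx))
        whole_selection = select_representatives(results, cl)

    aucs: list[float] = []
    n_redrawn = 0
    for _run in range(n_runs):
        for _try in range(max_redraws):
            draw = rng.choice(labelled_idx, size=len(labelled_idx), replace=True)
            oob = [i for i in labelled_idx if i not in set(draw.tolist())]
            oob_labels = [labels[corpus.case_ids[i]] for i in oob]
            if len(set(oob_labels)) == 2:
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a bootstrap sample with two-class out-of-bag set")

        boot = corpus.subset(draw.tolist())
        boot_outcome = boot.outcomes[outcome.name]
        if nested:
            results = _discover_features(boot, boot_outcome, config)
            if not results:
                aucs.append(0.5)
                continue
            cl = cluster_features(results, boot.n_cases)
            reps = select_representatives(results, cl)
        else:
            reps = whole_selection

        train_ids = boot.case_ids
        y_train = np.array([boot_outcome.values[cid] for cid in train_ids])
        if nested:
            X_train = np.stack([np.asarray(r.feature.profile, float) for r in reps], axis=1)
        else:
            prof_by_case = {cid: j for j, cid in enumerate(corpus.case_ids)}
            cols = [np.asarray(r.feature.profile, float) for r in reps]
            X_train = np.stack([[col[prof_by_case[cid.split('#')[0]]] for col in cols]
                                for cid in train_ids])

        # score out-of-bag cases by re-matching the selected patterns on the
        # full corpus (pattern matching uses text only, never labels)
        oob_cols = []
        for r in reps:
            feat = r.feature
            if nested:
                full_profile = _full_profile(feat, corpus)
            else:
                full_profile = np.asarray(feat.profile, float)
            oob_cols.append(full_profile[oob])
        X_test = np.stack(oob_cols, axis=1)
        scores = clf(X_train, y_train, X_test)
        pos = [s for s, yl in zip(scores, oob_labels) if yl == 1]
        neg = [s for s, yl in zip(scores, oob_labels) if yl == 0]
        auc, _ = rank_auc(pos, neg)
        aucs.append(auc)

    return BootstrapReport(n_runs=n_runs, aucs=aucs, mean_auc=float(np.mean(aucs)),
                           seed=seed, n_redrawn=n_redrawn)


def _full_profile(feature, corpus: Corpus) -> np.ndarray:
    from .induction import RegexFeature, match_regex

    if isinstance(feature, RegexFeature):
        return np.asarray(match_regex(feature.regex, corpus), float)
    return np.asarray(build_profile(feature.pattern, corpus), float)
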