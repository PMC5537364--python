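"""End-to-end discovery orchestration and tabular writers.

``discover`` chains annotation -> feature search -> association scan ->
threshold filter -> redundancy removal -> (optional) regex induction, and
returns ranked results plus per-stage counts.  Writers emit the ranked
results TSV and a volcano table (effect size vs -log10 p) — data only, no
plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (PreAnnotation, apply_preannotations, load_vocabulary,
                       prune_annotations, stem_tokens, tag_numbers,
                       vocab_aggregate)
from .corpus import Corpus, Outcome
from .induction import induce_and_rescore
from .reduction import filter_threshold, remove_redundant
from .search import (BinaryFeature, enumerate_ngrams, enumerate_tagged_patterns,
                     extract_numeric_features)
from .stats import AssociationResult, associate_all, bh_adjust

logger = logging.getLogger("patwas")

__all__ = ["RunConfig", "DiscoveryReport", "discover", "write_results", "write_volcano"]

_ANNOTATORS = ("num", "stem", "pos", "parse", "vocab")


@dataclass
class RunConfig:
    """Configuration axes of a discovery run; echoed into every output."""

    annotators: tuple[str, ...] = ("num",)
    min_support: int = 2
    max_len: Optional[int] = None
    tagged_max_len: int = 5
    max_flank_len: int = 3
    alpha: float = 0.0025
    regex_induction: bool = True
    fold_case: bool = False
    numeric_features: bool = True
    bh_column: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.annotators) - set(_ANNOTATORS)
        if bad:
            raise ValueError(f"unknown annotators {bad}; choose from {_ANNOTATORS}")

    def echo(self) -> str:
        return (f"annotators={','.join(self.annotators) or 'none'} min_support={self.min_support} "
                f"max_len={self.max_len} alpha={self.alpha} regex={self.regex_induction} "
                f"fold_case={self.fold_case} seed={self.seed} version={__version__}")


@dataclass
class DiscoveryReport:
    results: list[AssociationResult]
    config: RunConfig
    counts: dict[str, int] = field(default_factory=dict)


def annotate_corpus(corpus: Corpus, config: RunConfig,
                    preannotations: Sequence[PreAnnotation] = (),
                    vocabulary_path: Optional[str | Path] = None) -> Corpus:
    if "vocab" in config.annotators and vocabulary_path is not None:
        vocab = load_vocabulary(vocabulary_path)
        for _, _, _, sent in corpus.iter_sentences():
            vocab_aggregate(sent, vocab)
        corpus.invalidate_index()
    if "num" in config.annotators:
        for _, _, _, sent in corpus.iter_sentences():
            tag_numbers(sent)
    if "stem" in config.annotators:
        for _, _, _, sent in corpus.iter_sentences():
            stem_tokens(sent)
    if ("pos" in config.annotators or "parse" in config.annotators) and preannotations:
        apply_preannotations(corpus, preannotations)
    return corpus


def discover(corpus: Corpus, outcome_name: str, config: Optional[RunConfig] = None,
             preannotations: Sequence[PreAnnotation] = (),
             vocabulary_path: Optional[str | Path] = None) -> DiscoveryReport:
    """Run the full discovery pipeline against one outcome."""
    config = config or RunConfig()
    if outcome_name not in corpus.outcomes:
        raise ValueError(f"no labels for outcome {outcome_name!r}")
    outcome = corpus.outcomes[outcome_name]
    if not outcome.values:
        raise ValueError(f"outcome {outcome_name!r} labels no cases")

    annotate_corpus(corpus, config, preannotations, vocabulary_path)
    counts: dict[str, int] = {}

    tagged_search = bool({"stem", "pos", "parse"} & set(config.annotators))
    if tagged_search:
        counts["annotations_pruned"] = prune_annotations(corpus)

    features: list = list(enumerate_ngrams(corpus, config.min_support, config.max_len))
    counts["ngram_features"] = len(features)
    if tagged_search:
        tagged = enumerate_tagged_patterns(corpus, config.min_support, config.tagged_max_len)
        counts["tagged_features"] = len(tagged)
        features.extend(tagged)

    kept, removed = remove_redundant(features)
    counts["redundant_removed"] = len(removed)

    numeric = []
    if config.numeric_features and "num" in config.annotators:
        numeric = extract_numeric_features(corpus, config.max_flank_len, config.min_support)
        counts["numeric_features"] = len(numeric)

    results = associate_all(list(kept) + list(numeric), outcome, corpus)
    counts["tested"] = len(results)
    filtered = filter_threshold(results, config.alpha)
    counts["past_threshold"] = len(filtered)

    if config.regex_induction:
        regex_results = induce_and_rescore(filtered, corpus, outcome)
        counts["regexes_induced"] = len(regex_results)
        filtered = filter_threshold(list(filtered) + regex_results, config.alpha)

    if not filtered:
        logger.warning("no features passed alpha=%g", config.alpha)
    for stage, n in counts.items():
        logger.info("%s: %d", stage, n)
    return DiscoveryReport(results=filtered, config=config, counts=counts)


def _results_frame(results: Sequence[AssociationResult], config: RunConfig) -> pd.DataFrame:
    rows = []
    for rank, r in enumerate(results, start=1):
        rows.append({
            "rank": rank,
            "pattern": r.rendered(),
            "pattern_type": r.pattern_type,
            "stat": r.stat,
            "estimate": r.estimate,
            "log_or": r.log_or if r.log_or is not None else "",
            "p_value": r.p_value,
            "support": r.support,
            "n_used": r.n_used,
            "direction": r.direction,
        })
    df = pd.DataFrame(rows, columns=["rank", "pattern", "pattern_type", "stat", "estimate",
                                     "log_or", "p_value", "support", "n_used", "direction"])
    if config.bh_column and len(df):
        df["p_bh"] = bh_adjust(df["p_value"].to_numpy())
    return df


def write_results(results: Sequence[AssociationResult], path: str | Path,
                  config: Optional[RunConfig] = None) -> None:
    config = config or RunConfig()
    df = _results_frame(results, config)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {config.echo()}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_volcano(results: Sequence[AssociationResult], path: str | Path,
                  config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Volcano table: x = log OR (or signed AUC - 0.5), y = -log10 p.

    p = 0 is clamped to the smallest positive float and flagged.
    """
    config = config or RunConfig()
    rows = []
    tiny = np.finfo(float).tiny
    for r in results:
        if r.stat == "OR":
            x = r.log_or
        elif r.stat == "AUC":
            x = r.estimate - 0.5
        else:
            x = r.estimate
        clamped = r.p_value <= 0
        p = max(r.p_value, tiny)
        rows.append({"pattern": r.rendered(), "type": r.pattern_type, "x": x,
                     "y": -np.log10(p), "support": r.support,
                     "p_clamped": int(clamped)})
    df = pd.DataFrame(rows, columns=["pattern", "type", "x", "y", "support", "p_clamped"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {config.echo()}\n")
        df.to_csv(fh, sep="\t", index=False)
    return df
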