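"""Threshold filtering and redundancy removal.

Exhaustive search produces nested patterns with identical occurrence
profiles ("metastases" ⊃ "liver metastases" ⊃ "extensive liver metastases"
may all mark the same cases).  Since every association statistic depends on
the feature only through its profile, keeping more than the longest pattern
per profile adds nothing; the longest is the most explanatory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .search import BinaryFeature
from .stats import AssociationResult

__all__ = ["ReductionConfig", "filter_threshold", "remove_redundant"]


@dataclass
class ReductionConfig:
    alpha: float = 0.0025
    keep_ties: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


def filter_threshold(results: Sequence[AssociationResult], alpha: float) -> list[AssociationResult]:
    """Keep results with p <= alpha, sorted by ascending p; ties broken by
    descending effect magnitude, then rendered pattern."""
    kept = [r for r in results if r.p_value <= alpha]
    kept.sort(key=lambda r: (r.p_value, -r.effect_magnitude(), r.rendered()))
    return kept


def remove_redundant(features: Sequence[BinaryFeature],
                     keep_ties: bool = True) -> tuple[list[BinaryFeature], list[BinaryFeature]]:
    """Within each group of bit-identical profiles keep only the maximal-
    length patterns (all of them when tied and ``keep_ties``, else the
    lexicographically first).  Returns (kept, removed); input order of kept
    features is preserved."""
    groups: dict[bytes, list[BinaryFeature]] = {}
    for f in features:
        groups.setdefault(f.profile.tobytes(), []).append(f)
    keep: set[int] = set()
    for members in groups.values():
        maxlen = max(len(f.pattern) for f in members)
        best = [f for f in members if len(f.pattern) == maxlen]
        if not keep_ties:
            best = [min(best, key=lambda f: f.rendered())]
        keep.update(id(f) for f in best)
    kept = [f for f in features if id(f) in keep]
    removed = [f for f in features if id(f) not in keep]
    return kept, removed
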