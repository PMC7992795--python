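"""Fusion of the two score pools into one ranked network.

Each module's boosted-tree edge list and the ridge edge list are min–max
normalised *separately* (tree importances and |ridge coefficients| live on
incomparable scales), duplicate pairs arising from overlapping modules are
collapsed to their maximum normalised score, and the concatenation is
sorted descending with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ScoredEdgeList

__all__ = ["RankedNetwork", "minmax_normalize", "merge_and_rank"]


@dataclass
class RankedNetwork:
    """Final prediction: ordered (regulator, target, score ∈ [0, 1]) records."""

    records: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for _, _, score in self.records:
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"ranked score {score} outside [0, 1]")
        keys = [(-s, r, t) for r, t, s in self.records]
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("records are not sorted by (score desc, regulator, target)")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(r, t) for r, t, _ in self.records]

    def top_k(self, k: int) -> list[tuple[str, str, float]]:
        if k > len(self.records):
            raise ValueError(f"K={k} exceeds the {len(self.records)} ranked records")
        return self.records[:k]


def minmax_normalize(scores: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map scores to [0, 1] via (x − min)/(max − min).

    A constant vector maps to all zeros: a block whose scores do not
    discriminate carries no ranking evidence and must not be promoted.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty score vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def merge_and_rank(
    intra_lists: Sequence[ScoredEdgeList], inter_list: ScoredEdgeList | None
) -> RankedNetwork:
    """Normalise each block independently, merge, deduplicate and sort.

    Duplicate pairs across intra lists (overlapping modules) keep the
    maximum normalised score.  A pair appearing in both an intra list and
    the inter list violates the stage separation and raises.
    """
    best: dict[tuple[str, str], float] = {}
    intra_pairs: set[tuple[str, str]] = set()
    for block in intra_lists:
        if len(block) == 0:
            continue
        normalized = minmax_normalize([s for _, _, s in block.records])
        for (reg, tgt, _), score in zip(block.records, normalized):
            pair = (reg, tgt)
            intra_pairs.add(pair)
            if score > best.get(pair, -1.0):
                best[pair] = float(score)
    if inter_list is not None and len(inter_list) > 0:
        overlap = intra_pairs & inter_list.pairs
        if overlap:
            raise ValueError(
                f"{len(overlap)} pairs scored by both stages (e.g. {sorted(overlap)[0]}); "
                "intra and inter candidate sets must be disjoint"
            )
        normalized = minmax_normalize([s for _, _, s in inter_list.records])
        for (reg, tgt, _), score in zip(inter_list.records, normalized):
            best[(reg, tgt)] = float(score)
    records = sorted(
        ((reg, tgt, score) for (reg, tgt), score in best.items()),
        key=lambda rec: (-rec[2], rec[0], rec[1]),
    )
    return RankedNetwork(records=records)
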