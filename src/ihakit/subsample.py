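"""Seeded uniform subsampling of read pools.

Sampling is an explicit RNG permutation (not hash-based): a permutation of
the pool is drawn, elements are taken in permuted order until the target
count or byte budget is met, and the sample is returned in original pool
order. Pairs are sampled at pair granularity; mates are never split.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .formats import ReadPair, SequenceRecord

__all__ = ["subsample_pairs", "subsample_long"]


def _take(pool_size: int, order: np.ndarray, sizes: np.ndarray,
          target_count: Optional[int], target_bp: Optional[float],
          bp_slack: float) -> np.ndarray:
    if target_count is not None:
        chosen = order[: min(target_count, pool_size)]
    else:
        cum = np.cumsum(sizes[order])
        n = int(np.searchsorted(cum, target_bp * bp_slack, side="right"))
        chosen = order[:n]
    return np.sort(chosen)


def subsample_pairs(
    pairs: Sequence[ReadPair],
    target_count: Optional[int] = None,
    target_bp: Optional[float] = None,
    seed: int = 0,
) -> list[ReadPair]:
    """Uniform sample of read pairs without replacement.

    Exactly one of ``target_count`` / ``target_bp`` must be given. When the
    target meets or exceeds the pool, the pool is returned unchanged. For a
    byte target, whole pairs are taken while the running total stays within
    the target.
    """
    if (target_count is None) == (target_bp is None):
        raise ValueError("give exactly one of target_count / target_bp")
    n = len(pairs)
    if target_count is not None and target_count >= n:
        return list(pairs)
    sizes = np.fromiter((p.total_bp for p in pairs), dtype=np.int64, count=n)
    if target_bp is not None and target_bp >= sizes.sum():
        return list(pairs)
    order = np.random.default_rng(seed).permutation(n)
    idx = _take(n, order, sizes, target_count, target_bp, bp_slack=1.0)
    return [pairs[i] for i in idx]


def subsample_long(
    reads: Sequence[SequenceRecord],
    target_count: Optional[int] = None,
    target_bp: Optional[float] = None,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Uniform sample of long reads without replacement.

    For a byte target, reads are drawn until the next draw would push the
    total past target x 1.01 (long reads are big relative to the budget, so
    a small overshoot beats a systematic undershoot).
    """
    if (target_count is None) == (target_bp is None):
        raise ValueError("give exactly one of target_count / target_bp")
    n = len(reads)
    if target_count is not None and target_count >= n:
        return list(reads)
    sizes = np.fromiter((len(r) for r in reads), dtype=np.int64, count=n)
    if target_bp is not None and target_bp >= sizes.sum():
        return list(reads)
    order = np.random.default_rng(seed).permutation(n)
    idx = _take(n, order, sizes, target_count, target_bp, bp_slack=1.01)
    return [reads[i] for i in idx]
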