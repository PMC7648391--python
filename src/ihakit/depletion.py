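"""Read recruitment against qualified MAGs and residual-pool construction.

Each iteration cycle ends by recruiting the reads that belong to the
accumulated qualified MAGs and removing them, which raises the relative
abundance of everything not yet assembled. Short-read pairs are recruited by
a k-mer vote (a mate maps when >= 60% of its 21-mers occur in the MAG set);
a pair is recruited when both mates map, residual when neither maps, and
discarded when exactly one maps (mate orphans are filtered so the residual
pool stays properly paired). Long reads are recruited from alignment records
when any alignment reaches coverage >= 80% and identity >= 80% (inclusive);
alignments may come from the built-in anchor aligner or any external PAF.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from . import _kmers
from .evaluate import AnchorIndex, align_to_reference
from .formats import AlignmentRecord, ReadPair, SequenceRecord

__all__ = [
    "CyclePools",
    "KmerVoteMapper",
    "recruit_short",
    "recruit_long",
    "deplete",
]


@dataclasses.dataclass(slots=True)
class CyclePools:
    """Disjoint, exhaustive partition of a cycle's read pools."""

    recruited_pairs: list[ReadPair] = dataclasses.field(default_factory=list)
    residual_pairs: list[ReadPair] = dataclasses.field(default_factory=list)
    discarded_pairs: list[ReadPair] = dataclasses.field(default_factory=list)
    recruited_long: list[SequenceRecord] = dataclasses.field(default_factory=list)
    residual_long: list[SequenceRecord] = dataclasses.field(default_factory=list)

    def check_partition(self, n_pairs: int, n_long: int) -> None:
        got_p = len(self.recruited_pairs) + len(self.residual_pairs) + len(self.discarded_pairs)
        got_l = len(self.recruited_long) + len(self.residual_long)
        if got_p != n_pairs or got_l != n_long:
            raise AssertionError("cycle pools do not partition the input")


class KmerVoteMapper:
    """Built-in bowtie2 stand-in: canonical 21-mer membership voting.

    ``map_fractions`` returns the per-read fraction of k-mers present in the
    MAG set; ``attribute`` additionally assigns each mapped read to the MAG
    contributing most of its k-mers (ties broken lexicographically).
    """

    def __init__(
        self,
        mags: Sequence[tuple[str, Sequence[SequenceRecord]]],
        k: int = 21,
        min_fraction: float = 0.6,
        stride: int = 3,
    ):
        self.k = k
        self.min_fraction = min_fraction
        # reads are voted on a k-mer sample; MAG k-mers are indexed densely
        self.stride = stride
        self.mag_ids = [m for m, _ in mags]
        words_all, label_all = [], []
        for li, (_, records) in enumerate(mags):
            _, _, w = _kmers.multi_kmer_words([r.sequence for r in records], k)
            words_all.append(_kmers.canonical_words(w, k))
            label_all.append(np.full(w.size, li, dtype=np.int32))
        if words_all:
            words = np.concatenate(words_all)
            labels = np.concatenate(label_all)
            order = np.argsort(words, kind="stable")
            words, labels = words[order], labels[order]
            uniq_mask = np.ones(words.size, dtype=bool)
            uniq_mask[1:] = words[1:] != words[:-1]
            self.words = words[uniq_mask]
            self.labels = labels[uniq_mask]
        else:
            self.words = np.empty(0, dtype=np.uint64)
            self.labels = np.empty(0, dtype=np.int32)

    def map_fractions(self, seqs: list[str]) -> np.ndarray:
        return _kmers.presence_fraction(
            seqs, self.words, self.k, stride=self.stride
        )

    def attribute(self, seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """(mapped fraction, best MAG index or -1) per sequence."""
        n = len(seqs)
        frac = np.zeros(n)
        best = np.full(n, -1, dtype=np.int64)
        if n == 0 or self.words.size == 0:
            return frac, best
        idx, _, words = _kmers.multi_kmer_words(seqs, self.k, stride=self.stride)
        words = _kmers.canonical_words(words, self.k)
        pos = np.searchsorted(self.words, words)
        pos[pos >= self.words.size] = self.words.size - 1
        hit = self.words[pos] == words
        n_tot = np.bincount(idx, minlength=n)
        n_hit = np.bincount(idx[hit], minlength=n)
        ok = n_tot > 0
        frac[ok] = n_hit[ok] / n_tot[ok]
        if hit.any():
            lab = self.labels[pos[hit]].astype(np.int64)
            combo = idx[hit] * len(self.mag_ids) + lab
            votes = np.bincount(combo, minlength=n * len(self.mag_ids)).reshape(
                n, len(self.mag_ids)
            )
            has = votes.sum(axis=1) > 0
            best[has] = votes[has].argmax(axis=1)
        return frac, best


def recruit_short(
    pairs: Sequence[ReadPair],
    qualified_mags: Sequence[tuple[str, Sequence[SequenceRecord]]],
    mapper: Optional[KmerVoteMapper] = None,
    require_both_mates: bool = True,
    pools: Optional[CyclePools] = None,
) -> tuple[CyclePools, dict[str, int]]:
    """Partition pairs into recruited / residual / discarded.

    Returns the pools plus per-MAG recruited base counts (majority k-mer
    attribution) for coverage reporting. With ``require_both_mates`` False a
    pair is recruited when either mate maps and nothing is discarded.
    """
    pools = pools or CyclePools()
    per_mag: dict[str, int] = {}
    if not qualified_mags:
        pools.residual_pairs.extend(pairs)
        return pools, per_mag
    mapper = mapper or KmerVoteMapper(qualified_mags)
    seqs: list[str] = []
    for p in pairs:
        seqs.append(p.mate1.sequence)
        seqs.append(p.mate2.sequence)
    frac, best = mapper.attribute(seqs)
    mapped = frac >= mapper.min_fraction
    m1, m2 = mapped[0::2], mapped[1::2]
    for i, p in enumerate(pairs):
        if m1[i] and m2[i]:
            pools.recruited_pairs.append(p)
        elif not require_both_mates and (m1[i] or m2[i]):
            pools.recruited_pairs.append(p)
        elif m1[i] or m2[i]:
            pools.discarded_pairs.append(p)
            continue
        else:
            pools.residual_pairs.append(p)
            continue
        for j, mate_mapped in ((2 * i, m1[i]), (2 * i + 1, m2[i])):
            if mate_mapped and best[j] >= 0:
                mag = mapper.mag_ids[best[j]]
                per_mag[mag] = per_mag.get(mag, 0) + len(seqs[j])
    return pools, per_mag


def internal_long_alignments(
    long_reads: Sequence[SequenceRecord],
    mag_records: Sequence[SequenceRecord],
    k_anchor: int = 31,
    anchor_stride: int = 25,
    max_anchor_hits: int = 2,
    max_gap: int = 3000,
) -> list[AlignmentRecord]:
    """Align long reads to a MAG set with the built-in anchor aligner.

    Anchors are near-unique k-mers; the wide chain gap lets chains step
    over multi-copy regions (rRNA operons, long repeats) on their flanking
    anchors instead of expanding repeat hits.
    """
    index = AnchorIndex(mag_records, k=k_anchor, max_hits=max_anchor_hits)
    blocks = align_to_reference(
        long_reads, mag_records, index=index, anchor_stride=anchor_stride,
        max_gap=max_gap,
    )
    lens = {r.id: len(r) for r in long_reads}
    tlens = {r.id: len(r) for r in mag_records}
    out = []
    for b in blocks:
        cols = b.n_matches + b.n_mismatches + b.n_ins + b.n_del
        out.append(
            AlignmentRecord(
                query_id=b.contig_id,
                query_len=lens[b.contig_id],
                query_start=b.qstart,
                query_end=b.qend,
                strand=b.strand,
                target_id=b.ref_id,
                target_len=tlens[b.ref_id],
                target_start=b.rstart,
                target_end=b.rend,
                n_matches=b.n_matches,
                block_len=cols,
            )
        )
    return out


def recruit_long(
    long_reads: Sequence[SequenceRecord],
    qualified_mags: Sequence[tuple[str, Sequence[SequenceRecord]]],
    alignments: Optional[Sequence[AlignmentRecord]] = None,
    min_coverage: float = 0.80,
    min_identity: float = 0.80,
    pools: Optional[CyclePools] = None,
) -> tuple[CyclePools, dict[str, int]]:
    """Partition long reads by ANY-alignment coverage/identity filtering."""
    pools = pools or CyclePools()
    per_mag: dict[str, int] = {}
    if not qualified_mags:
        pools.residual_long.extend(long_reads)
        return pools, per_mag
    mag_of_contig = {}
    all_records = []
    for mag_id, records in qualified_mags:
        for r in records:
            mag_of_contig[r.id] = mag_id
            all_records.append(r)
    if alignments is None:
        alignments = internal_long_alignments(long_reads, all_records)
    known = {r.id for r in long_reads}
    recruited_ids: dict[str, str] = {}
    for a in alignments:
        if a.query_id not in known:
            raise ValueError(f"alignment references unknown read {a.query_id!r}")
        if a.query_coverage >= min_coverage and a.identity >= min_identity:
            recruited_ids.setdefault(a.query_id, mag_of_contig.get(a.target_id, "?"))
    for r in long_reads:
        if r.id in recruited_ids:
            pools.recruited_long.append(r)
            mag = recruited_ids[r.id]
            per_mag[mag] = per_mag.get(mag, 0) + len(r)
        else:
            pools.residual_long.append(r)
    return pools, per_mag


def deplete(pools: CyclePools) -> tuple[list[ReadPair], list[SequenceRecord], dict]:
    """Return the residual pools and a depletion report."""
    n_pairs = (
        len(pools.recruited_pairs) + len(pools.residual_pairs) + len(pools.discarded_pairs)
    )
    n_long = len(pools.recruited_long) + len(pools.residual_long)
    report = {
        "pairs_in": n_pairs,
        "pairs_recruited": len(pools.recruited_pairs),
        "pairs_discarded": len(pools.discarded_pairs),
        "pairs_residual": len(pools.residual_pairs),
        "pairs_recruited_fraction": len(pools.recruited_pairs) / n_pairs if n_pairs else 0.0,
        "long_in": n_long,
        "long_recruited": len(pools.recruited_long),
        "long_residual": len(pools.residual_long),
        "long_recruited_fraction": len(pools.recruited_long) / n_long if n_long else 0.0,
    }
    return list(pools.residual_pairs), list(pools.residual_long), report
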