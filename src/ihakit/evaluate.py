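"""Reference-based assembly evaluation.

Metrics follow the usual mock-community playbook: contigs are aligned to the
truth genomes with an exact-anchor chainer (unique k-mer seeds, colinear
chains with a 1 kbp gap bound, chain interiors scored by edit alignment),
and from the aligned blocks we derive NGA50 (the aligned-fragment length at
which cumulative aligned length reaches half the reference), aligned genome
fraction (AGF), purity (1 - fraction of contig bases outside any block),
misassembly counts (reference switch, strand flip, or a >1 kbp coordinate
jump between consecutive blocks of one contig), per-Mbp mismatch/indel
rates (per aligned Mbp), gene recovery (exact predicted-protein identity),
and the observed-versus-expected coverage correlation.

The same anchor aligner doubles as the in-package long-read and cassette
aligner used by read recruitment and marker scanning.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from scipy import stats

from . import _kmers
from .formats import SequenceRecord

__all__ = [
    "AlignedBlock",
    "AnchorIndex",
    "align_to_reference",
    "nga50",
    "agf_and_purity",
    "count_misassemblies",
    "gene_recovery",
    "expected_coverage",
    "coverage_correlation",
    "evaluate_mag",
    "contig_n50",
]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclasses.dataclass(slots=True)
class AlignedBlock:
    """One colinear aligned segment between a contig and a reference.

    Query coordinates are on the contig's forward strand regardless of
    alignment strand; all intervals are 0-based, half-open.
    """

    contig_id: str
    qstart: int
    qend: int
    ref_id: str
    rstart: int
    rend: int
    strand: str
    n_matches: int
    n_mismatches: int
    n_ins: int
    n_del: int

    @property
    def identity(self) -> float:
        cols = self.n_matches + self.n_mismatches + self.n_ins + self.n_del
        return self.n_matches / cols if cols else 0.0

    @property
    def ref_span(self) -> int:
        return self.rend - self.rstart


class AnchorIndex:
    """Positions of low-multiplicity k-mers across a reference set.

    ``max_hits`` bounds the multiplicity (canonical, both strands) of an
    indexed k-mer: 1 keeps only unique anchors (evaluation default), larger
    values admit repeats (used for cassette copy counting and read
    recruitment).
    """

    def __init__(self, refs: Sequence[SequenceRecord], k: int = 31, max_hits: int = 1):
        self.k = k
        self.max_hits = max_hits
        self.refs = list(refs)
        self.ref_lens = np.array([len(r) for r in self.refs], dtype=np.int64)
        seqs = [r.sequence for r in self.refs]
        ridx, pos, words = _kmers.multi_kmer_words(seqs, k)
        canon = _kmers.canonical_words(words, k)
        flipped = words != canon
        _, inverse, counts = np.unique(canon, return_inverse=True, return_counts=True)
        sel = counts[inverse] <= max_hits
        order = np.argsort(canon[sel], kind="stable")
        self.words = canon[sel][order]
        self.ref_idx = ridx[sel][order]
        self.pos = pos[sel][order]
        self.flipped = flipped[sel][order]

    def lookup(self, canon_words: np.ndarray):
        """Ranges [lo, hi) into the index arrays for each query word."""
        lo = np.searchsorted(self.words, canon_words, side="left")
        hi = np.searchsorted(self.words, canon_words, side="right")
        return lo, hi


def _cigar_counts(cigar: str) -> tuple[int, int, int, int]:
    m = x = i = d = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            m += n
        elif op == "X":
            x += n
        elif op == "I":
            i += n
        else:
            d += n
    return m, x, i, d


def _chain_hits(qpos, rpos, k, max_gap, minus: bool):
    """Greedy colinear chaining of anchor hits sorted by query position.

    Returns a list of (first, last) index pairs into the hit arrays.
    """
    # open chains tracked as (last_q, last_r, chain_index)
    open_chains: list[tuple[int, int, int]] = []
    chain_members: list[list[int]] = []
    for h in range(qpos.size):
        q, r = int(qpos[h]), int(rpos[h])
        placed = False
        for ci in range(len(open_chains) - 1, -1, -1):
            lq, lr, idx = open_chains[ci]
            dq = q - lq
            dr = (lr - r) if minus else (r - lr)
            if dq <= 0:
                continue
            if dq > max_gap + k:
                # this chain can never extend again (hits sorted by q)
                open_chains.pop(ci)
                continue
            if dr <= 0 or dr > max_gap + k or abs(dr - dq) > max_gap:
                continue
            chain_members[idx].append(h)
            open_chains[ci] = (q, r, idx)
            placed = True
            break
        if not placed:
            chain_members.append([h])
            open_chains.append((q, r, len(chain_members) - 1))
    return chain_members


def _refine_chain(
    qseq: str,
    ref_seq: str,
    contig_id: str,
    ref_id: str,
    strand: str,
    qs: int,
    qe: int,
    rs: int,
    re_: int,
    flank_limit: int,
) -> Optional[AlignedBlock]:
    """Edit-align the chained region (plus short flanks) against the ref."""
    qlen = len(qseq)
    left = min(qs, flank_limit)
    right = min(qlen - qe, flank_limit)
    if strand == "+":
        bqs, bqe = qs - left, qe + right
        seg = qseq[bqs:bqe]
    else:
        bqs, bqe = qs - left, qe + right
        seg = _kmers.revcomp(qseq[bqs:bqe])
        # on '-', the forward-query right flank extends the ref window left
        left, right = right, left
    slack = max(64, (bqe - bqs) // 20)
    ws = max(0, rs - left - slack)
    we = min(len(ref_seq), re_ + right + slack)
    window = ref_seq[ws:we]
    if not seg or not window:
        return None
    res = edlib.align(seg, window, task="path", mode="HW")
    if res["editDistance"] < 0 or not res.get("locations"):
        return None
    loc = res["locations"][0]
    m, x, i, d = _cigar_counts(res["cigar"] or "")
    return AlignedBlock(
        contig_id=contig_id,
        qstart=bqs,
        qend=bqe,
        ref_id=ref_id,
        rstart=ws + loc[0],
        rend=ws + loc[1] + 1,
        strand=strand,
        n_matches=m,
        n_mismatches=x,
        n_ins=i,
        n_del=d,
    )


def align_to_reference(
    contigs: Sequence[SequenceRecord],
    reference: Sequence[SequenceRecord] | SequenceRecord,
    k_anchor: int = 31,
    max_gap: int = 1000,
    max_anchor_hits: int = 1,
    anchor_stride: int = 1,
    min_chain_anchors: int = 2,
    index: Optional[AnchorIndex] = None,
) -> list[AlignedBlock]:
    """Anchor-seeded, chain-refined alignment of contigs to references.

    Chains cannot bridge regions devoid of anchors longer than ``max_gap``
    (e.g. long repeats when ``max_anchor_hits`` is 1); such regions split
    contigs into separate blocks, which downstream misassembly counting
    treats as breakpoints only when the coordinates actually jump.
    """
    if isinstance(reference, SequenceRecord):
        reference = [reference]
    idx = index if index is not None else AnchorIndex(reference, k_anchor, max_anchor_hits)
    k = idx.k
    blocks: list[AlignedBlock] = []
    for contig in contigs:
        qlen = len(contig)
        if qlen < k:
            continue
        positions, words = _kmers.rolling_kmers(_kmers.encode(contig.sequence), k)
        if anchor_stride > 1 and positions.size:
            keep = (positions % anchor_stride == 0) | (positions == positions[-1])
            positions, words = positions[keep], words[keep]
        canon = _kmers.canonical_words(words, k)
        q_flip = words != canon
        lo, hi = idx.lookup(canon)
        n_hits = hi - lo
        has = n_hits > 0
        if not has.any():
            continue
        # expand hits
        reps = n_hits[has]
        q_sel = np.repeat(positions[has], reps)
        qf_sel = np.repeat(q_flip[has], reps)
        flat = np.concatenate(
            [np.arange(a, b) for a, b in zip(lo[has], hi[has])]
        ) if reps.size else np.empty(0, dtype=np.int64)
        r_ref = idx.ref_idx[flat]
        r_pos = idx.pos[flat]
        r_flip = idx.flipped[flat]
        minus = qf_sel != r_flip
        for ref_i in np.unique(r_ref):
            ref_rec = idx.refs[ref_i]
            for is_minus in (False, True):
                sel = (r_ref == ref_i) & (minus == is_minus)
                if not sel.any():
                    continue
                qp, rp = q_sel[sel], r_pos[sel]
                order = np.lexsort((rp, qp))
                qp, rp = qp[order], rp[order]
                for members in _chain_hits(qp, rp, k, max_gap, is_minus):
                    if len(members) < min_chain_anchors:
                        continue
                    qs = int(qp[members[0]])
                    qe = int(qp[members[-1]]) + k
                    if is_minus:
                        rs = int(rp[members[-1]])
                        re_ = int(rp[members[0]]) + k
                    else:
                        rs = int(rp[members[0]])
                        re_ = int(rp[members[-1]]) + k
                    blk = _refine_chain(
                        contig.sequence,
                        ref_rec.sequence,
                        contig.id,
                        ref_rec.id,
                        "-" if is_minus else "+",
                        qs, qe, rs, re_,
                        flank_limit=max(2 * anchor_stride + k, 100),
                    )
                    if blk is not None:
                        blocks.append(blk)
    blocks.sort(key=lambda b: (b.contig_id, b.qstart, b.ref_id, b.rstart))
    return blocks


def nga50(blocks: Iterable[AlignedBlock], reference_len: int) -> int:
    """Aligned-fragment length at which cumulative aligned length reaches
    half the reference; 0 (undefined) when total aligned < 50%."""
    lens = sorted((b.ref_span for b in blocks), reverse=True)
    half = 0.5 * reference_len
    cum = 0
    for ln in lens:
        cum += ln
        if cum >= half:
            return ln
    return 0


def _union_len(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cs, ce = intervals[0]
    for s, e in intervals[1:]:
        if s > ce:
            total += ce - cs
            cs, ce = s, e
        else:
            ce = max(ce, e)
    return total + (ce - cs)


def agf_and_purity(
    blocks: Sequence[AlignedBlock],
    contigs: Sequence[SequenceRecord],
    reference_len: int,
) -> tuple[float, float]:
    """Aligned genome fraction (%) and purity.

    AGF counts each reference position once (union semantics); purity is
    1 minus the fraction of contig bases lying outside every block.
    """
    agf = 100.0 * _union_len([(b.rstart, b.rend) for b in blocks]) / reference_len
    total_bp = sum(len(c) for c in contigs)
    aligned_bp = 0
    for c in contigs:
        aligned_bp += _union_len(
            [(b.qstart, b.qend) for b in blocks if b.contig_id == c.id]
        )
    purity = 1.0 - (total_bp - aligned_bp) / total_bp if total_bp else 0.0
    return agf, purity


def count_misassemblies(blocks: Sequence[AlignedBlock], max_jump: int = 1000) -> int:
    """Breakpoints between consecutive blocks of each contig."""
    by_contig: dict[str, list[AlignedBlock]] = {}
    for b in blocks:
        by_contig.setdefault(b.contig_id, []).append(b)
    n = 0
    for blist in by_contig.values():
        blist.sort(key=lambda b: b.qstart)
        for a, b in zip(blist, blist[1:]):
            if a.ref_id != b.ref_id or a.strand != b.strand:
                n += 1
                continue
            dq = b.qstart - a.qend
            dr = (b.rstart - a.rend) if a.strand == "+" else (a.rstart - b.rend)
            if abs(dr - dq) > max_jump:
                n += 1
    return n


def gene_recovery(
    reference_proteins: Sequence[str], mag_contigs: Sequence[SequenceRecord]
) -> float:
    """Percent of reference genes with an identical predicted protein in the
    MAG (100% amino-acid identity and coverage, i.e. exact string match)."""
    from .orfs import proteins_of

    if not reference_proteins:
        raise ValueError("empty reference gene set")
    mag_prots = set(proteins_of(mag_contigs))
    hits = sum(1 for p in reference_proteins if p in mag_prots)
    return 100.0 * hits / len(reference_proteins)


def expected_coverage(
    abundance_weights: dict[str, float],
    genome_sizes: dict[str, int],
    total_bp: float,
) -> dict[str, float]:
    """Expected mean depth per genome: weight x total bases / genome size."""
    wsum = sum(abundance_weights.values())
    return {
        name: (w / wsum) * total_bp / genome_sizes[name]
        for name, w in abundance_weights.items()
    }


def coverage_correlation(
    observed: Sequence[float], expected: Sequence[float]
) -> tuple[float, bool]:
    """Spearman rank correlation (ties mid-ranked).

    Returns (rho, defined); fewer than 3 points or a constant vector yields
    (nan, False).
    """
    if len(observed) < 3 or len(observed) != len(expected):
        return float("nan"), False
    if len(set(observed)) == 1 or len(set(expected)) == 1:
        return float("nan"), False
    rho = stats.spearmanr(observed, expected).statistic
    return float(rho), True


def contig_n50(lengths: Sequence[int]) -> int:
    lens = sorted(lengths, reverse=True)
    half = 0.5 * sum(lens)
    cum = 0
    for ln in lens:
        cum += ln
        if cum >= half:
            return ln
    return 0


def evaluate_mag(
    mag_contigs: Sequence[SequenceRecord],
    reference: SequenceRecord,
    reference_proteins: Optional[Sequence[str]] = None,
    **align_kwargs,
) -> dict:
    """Per-MAG reference metrics bundle (one reference genome)."""
    blocks = align_to_reference(mag_contigs, reference, **align_kwargs)
    ref_len = len(reference)
    agf, purity = agf_and_purity(blocks, mag_contigs, ref_len)
    n_mis = count_misassemblies(blocks)
    aligned_cols = sum(
        b.n_matches + b.n_mismatches + b.n_ins + b.n_del for b in blocks
    )
    mbp = aligned_cols / 1e6 if aligned_cols else float("nan")
    out = {
        "nga50": nga50(blocks, ref_len),
        "agf_pct": agf,
        "purity": purity,
        "n_misassemblies": n_mis,
        "misassemblies_per_mbp": n_mis / mbp if aligned_cols else float("nan"),
        "mismatches_per_mbp": sum(b.n_mismatches for b in blocks) / mbp
        if aligned_cols else float("nan"),
        "indels_per_mbp": sum(b.n_ins + b.n_del for b in blocks) / mbp
        if aligned_cols else float("nan"),
    }
    if reference_proteins is not None:
        out["gene_recovery_pct"] = gene_recovery(reference_proteins, mag_contigs)
    return out
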