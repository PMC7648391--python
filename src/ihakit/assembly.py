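"""Built-in hybrid assembly and binning backends.

The toy hybrid assembler follows the short-read-first hybrid strategy: a de
Bruijn graph is built from short-read k-mers (low-count k-mers dropped),
maximal unitigs are extracted, and long reads then bridge unitigs across
branch points. Bridging chains exact k-mer anchors along each long read into
an ordered walk of oriented unitigs and votes, with one-unitig context, for
the successor at every junction; junction sequence is always taken from the
unitig copy, so the assembler never emits a k-mer absent from the short
reads. A contig is circular when its unitig walk closes on itself (or the
graph itself is an isolated cycle).

This backend targets error-free or low-error synthetic short reads: there is
no error correction, and at high long-read error rates bridging relies on
enough intact anchors per read. Real assemblers plug in through the adapter
contract (callable(pairs, long_reads, workdir, seed) -> contigs).

The toy binner clusters contigs greedily on (tetranucleotide frequency,
log short-read depth) centroids with a cosine + depth distance.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kmers
from .formats import ReadPair, SequenceRecord

__all__ = [
    "Contig",
    "Bin",
    "AssemblerAdapter",
    "toy_hybrid_assemble",
    "toy_bin",
    "refine_bins",
    "estimate_depths",
    "external_assembler",
]


@dataclasses.dataclass(slots=True)
class Contig:
    record: SequenceRecord
    mean_sr_depth: float = 0.0

    def __len__(self) -> int:
        return len(self.record)


@dataclasses.dataclass(slots=True)
class Bin:
    bin_id: str
    contigs: list[Contig]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("a bin must contain at least one contig")

    @property
    def size_bp(self) -> int:
        return sum(len(c) for c in self.contigs)


AssemblerAdapter = Callable[..., list[Contig]]


# ---------------------------------------------------------------- unitigs


def _solid_kmers(seqs: list[str], k: int, min_depth: int):
    """Sorted solid k-mer words (both strands counted) and their counts."""
    _, _, words = _kmers.multi_kmer_words(seqs, k)
    both = np.concatenate([words, _kmers.revcomp_words(words, k)])
    uniq, counts = np.unique(both, return_counts=True)
    keep = counts >= min_depth
    return uniq[keep], counts[keep]


def _neighbor_index(S: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Index of each candidate word in sorted S, or -1."""
    pos = np.searchsorted(S, cand)
    pos[pos >= S.size] = S.size - 1 if S.size else 0
    ok = S.size > 0
    hit = ok & (S[pos] == cand) if S.size else np.zeros(cand.size, bool)
    out = np.where(hit, pos, -1)
    return out


@dataclasses.dataclass(slots=True)
class _Unitig:
    seq: str
    depth: float
    circular: bool


def _extract_unitigs(S: np.ndarray, counts: np.ndarray, k: int) -> list[_Unitig]:
    """Maximal non-branching paths (and isolated cycles) of the k-mer graph."""
    n = S.size
    mask = np.uint64((1 << (2 * k)) - 1)
    shift_hi = np.uint64(2 * (k - 1))

    out_idx = np.full((4, n), -1, dtype=np.int64)
    in_idx = np.full((4, n), -1, dtype=np.int64)
    for b in range(4):
        bu = np.uint64(b)
        out_idx[b] = _neighbor_index(S, ((S << np.uint64(2)) & mask) | bu)
        in_idx[b] = _neighbor_index(S, (S >> np.uint64(2)) | (bu << shift_hi))
    outdeg = (out_idx >= 0).sum(axis=0)
    indeg = (in_idx >= 0).sum(axis=0)

    nxt = np.full(n, -1, dtype=np.int64)
    one_out = outdeg == 1
    succ = out_idx.max(axis=0)  # the single successor where outdeg == 1
    valid = one_out & (succ >= 0) & (indeg[succ] == 1)
    nxt[valid] = succ[valid]

    # a node starts a chain unless its unique predecessor points to it
    prev_ok = np.zeros(n, dtype=bool)
    tgt = nxt[nxt >= 0]
    prev_ok[tgt] = True

    visited = np.zeros(n, dtype=bool)
    unitigs: list[tuple[list[int], bool]] = []
    for start in np.nonzero(~prev_ok)[0]:
        if visited[start]:
            continue
        chain = [int(start)]
        visited[start] = True
        cur = int(nxt[start])
        while cur >= 0 and not visited[cur]:
            chain.append(cur)
            visited[cur] = True
            cur = int(nxt[cur])
        unitigs.append((chain, False))
    # leftovers are pure cycles
    for start in np.nonzero(~visited)[0]:
        if visited[start]:
            continue
        chain = [int(start)]
        visited[start] = True
        cur = int(nxt[start])
        while cur != int(start):
            chain.append(cur)
            visited[cur] = True
            cur = int(nxt[cur])
        unitigs.append((chain, True))

    out: list[_Unitig] = []
    seen: set[str] = set()
    for chain, is_cycle in unitigs:
        words = S[chain]
        first = _kmers.word_to_kmer(int(words[0]), k)
        tail = _kmers.decode((words[1:] & np.uint64(3)).astype(np.int64)) if len(chain) > 1 else ""
        seq = first + tail
        if is_cycle:
            seq = seq[: len(chain)]
            key = _kmers.canonical_circular(seq)
        else:
            key = min(seq, _kmers.revcomp(seq))
        if key in seen:
            continue
        seen.add(key)
        depth = float(counts[chain].mean())
        out.append(_Unitig(seq=seq, depth=depth, circular=is_cycle))
    out.sort(key=lambda u: (-len(u.seq), u.seq))
    return out


# ------------------------------------------------------------- bridging


class _OrientedIndex:
    """word -> (unitig id, orientation, offset) over both orientations."""

    def __init__(self, unitigs: list[_Unitig], k: int):
        self.k = k
        words_all, uid_all, orient_all, off_all = [], [], [], []
        for uid, u in enumerate(unitigs):
            for orient, seq in ((0, u.seq), (1, _kmers.revcomp(u.seq))):
                _, w = _kmers.rolling_kmers(_kmers.encode(seq), k)
                words_all.append(w)
                uid_all.append(np.full(w.size, uid, dtype=np.int32))
                orient_all.append(np.full(w.size, orient, dtype=np.int8))
                off_all.append(np.arange(w.size, dtype=np.int64))
        words = np.concatenate(words_all)
        order = np.argsort(words, kind="stable")
        self.words = words[order]
        self.uid = np.concatenate(uid_all)[order]
        self.orient = np.concatenate(orient_all)[order]
        self.off = np.concatenate(off_all)[order]

    def lookup_first(self, query: np.ndarray):
        """First index entry per query word (or -1)."""
        pos = np.searchsorted(self.words, query)
        pos[pos >= self.words.size] = max(self.words.size - 1, 0)
        hit = self.words.size > 0
        ok = (self.words[pos] == query) if hit else np.zeros(query.size, bool)
        return np.where(ok, pos, -1)

    def start_unit(self, word: int) -> Optional[tuple[int, int]]:
        """Oriented unitig starting with this word, if any."""
        w = np.uint64(word)
        lo = int(np.searchsorted(self.words, w, side="left"))
        hi = int(np.searchsorted(self.words, w, side="right"))
        for i in range(lo, hi):
            if self.off[i] == 0:
                return int(self.uid[i]), int(self.orient[i])
        return None


def _read_chain(index: _OrientedIndex, seq: str, min_anchors: int = 1, stride: int = 7):
    """Ordered oriented-unitig walk evidenced by one long read.

    Anchors are sampled every ``stride`` positions; runs of hits on the same
    oriented unitig compress to one walk step, and runs with fewer than
    ``min_anchors`` anchors are discarded before adjacent equal steps merge.
    """
    _, words = _kmers.rolling_kmers(_kmers.encode(seq), index.k, stride=stride)
    if words.size == 0:
        return []
    pos = index.lookup_first(words)
    sel = pos >= 0
    if not sel.any():
        return []
    uid = index.uid[pos[sel]].astype(np.int64)
    orient = index.orient[pos[sel]].astype(np.int64)
    key = uid * 2 + orient
    change = np.flatnonzero(key[1:] != key[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [key.size]))
    chain: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if e - s < min_anchors:
            continue
        step = (int(uid[s]), int(orient[s]))
        if not chain or chain[-1] != step:
            chain.append(step)
    return chain


def _flip(oriented: tuple[int, int]) -> tuple[int, int]:
    return (oriented[0], 1 - oriented[1])


def _connect(a, b, succ, tiny, max_hops: int = 8):
    """Unique path a -> b through tiny unitigs only, or None.

    Read chains only reliably detect unitigs long enough to carry several
    anchors; short boundary unitigs at junctions are invisible to them and
    are filled back in here, provided the graph offers exactly one way.
    """
    paths: list[list] = []
    stack = [(a, [])]
    while stack:
        cur, inter = stack.pop()
        for c in succ.get(cur, []):
            if c == b:
                paths.append(inter)
                if len(paths) > 1:
                    return None
            elif len(inter) < max_hops and tiny[c[0]] and c != a and c not in inter:
                stack.append((c, inter + [c]))
    return paths[0] if len(paths) == 1 else None


def _collect_votes(
    index: _OrientedIndex,
    long_reads,
    min_anchors: int,
    succ,
    tiny,
    repeat_like,
):
    """Vote tallies from long-read walks.

    ``pair_votes`` counts direct transitions; ``ctx_votes`` counts, for each
    (context, current) pair, the observed successor, where the context is
    the last non-repeat unitig seen along the walk - one unique flank of
    context disambiguates the exits of a shared cassette.
    """
    pair_votes: dict = {}
    ctx_votes: dict = {}
    connect_cache: dict = {}

    def expand(chain):
        out = [chain[0]]
        for a, b in zip(chain, chain[1:]):
            key = (a, b)
            if key not in connect_cache:
                if b in succ.get(a, []):
                    connect_cache[key] = []
                else:
                    connect_cache[key] = _connect(a, b, succ, tiny)
            inter = connect_cache[key]
            if inter:
                out.extend(inter)
            out.append(b)
        return out

    def add(chain):
        ctx = None
        for i, cur in enumerate(chain[:-1]):
            if not repeat_like[cur[0]]:
                ctx = cur
            nxt = chain[i + 1]
            pair_votes[(cur, nxt)] = pair_votes.get((cur, nxt), 0) + 1
            if ctx is not None:
                key = (ctx, cur)
                ctx_votes.setdefault(key, {})
                ctx_votes[key][nxt] = ctx_votes[key].get(nxt, 0) + 1

    for read in long_reads:
        chain = _read_chain(index, read.sequence, min_anchors)
        if len(chain) >= 2:
            expanded = expand(chain)
            add(expanded)
            add([_flip(x) for x in reversed(expanded)])
    return pair_votes, ctx_votes


def _dbg_successors(index: _OrientedIndex, unitigs, k: int):
    """Oriented-unitig adjacency implied by the k-mer graph."""
    succ: dict[tuple[int, int], list[tuple[int, int]]] = {}
    mask = (1 << (2 * k)) - 1
    for uid, u in enumerate(unitigs):
        for orient, seq in ((0, u.seq), (1, _kmers.revcomp(u.seq))):
            if len(seq) < k:
                continue
            last = 0
            for ch in seq[-k:]:
                last = ((last << 2) | "ACGT".index(ch)) & mask
            cands = []
            for b in range(4):
                w = ((last << 2) & mask) | b
                hit = index.start_unit(w)
                if hit is not None:
                    cands.append(hit)
            succ[(uid, orient)] = cands
    return succ


def _pick_next(cur, ctx, cands, pair_votes, ctx_votes, min_votes):
    if len(cands) == 1:
        return cands[0]
    votes = None
    if ctx is not None:
        votes = ctx_votes.get((ctx, cur))
    if votes is None:
        votes = {c: pair_votes.get((cur, c), 0) for c in cands}
    scored = sorted(
        ((votes.get(c, 0), c) for c in cands), key=lambda t: (-t[0], t[1])
    )
    if not scored:
        return None
    best_v, best = scored[0]
    second_v = scored[1][0] if len(scored) > 1 else 0
    if best_v >= min_votes and best_v > second_v:
        return best
    return None


def toy_hybrid_assemble(
    pairs: Sequence[ReadPair],
    long_reads: Sequence[SequenceRecord] = (),
    k: int = 31,
    min_depth: int = 3,
    min_contig_len: int = 1000,
    seed: int = 0,
    min_bridge_votes: int = 2,
    min_chain_anchors: int = 1,
) -> list[Contig]:
    """Short-read de Bruijn assembly with long-read unitig bridging.

    ``seed`` is accepted for adapter-contract compatibility; the algorithm
    is fully deterministic (lexicographic tie-breaks throughout).
    """
    if k % 2 == 0 or k < 15:
        raise ValueError("k must be odd and >= 15")
    if not pairs:
        raise ValueError("no short reads supplied")
    seqs: list[str] = []
    for p in pairs:
        seqs.append(p.mate1.sequence)
        seqs.append(p.mate2.sequence)
    S, counts = _solid_kmers(seqs, k, min_depth)
    if S.size == 0:
        return []
    unitigs = _extract_unitigs(S, counts, k)

    paths: list[tuple[list[tuple[int, int]], bool]] = []  # (walk, circular)
    if long_reads:
        index = _OrientedIndex(unitigs, k)
        succ = _dbg_successors(index, unitigs, k)

        lens = np.array([len(u.seq) for u in unitigs], dtype=np.float64)
        depths = np.array([u.depth for u in unitigs], dtype=np.float64)
        # a repeat unitig branches on both sides; depth only sizes its reuse cap
        n_out = np.array([len(succ.get((u, 0), [])) for u in range(len(unitigs))])
        n_in = np.array([len(succ.get((u, 1), [])) for u in range(len(unitigs))])
        tiny = lens < 2 * k
        repeat_like = ((n_out >= 2) & (n_in >= 2)) | tiny
        order = np.argsort(depths)
        uniq_sel = ~repeat_like
        if uniq_sel.any():
            o = order[uniq_sel[order]]
            cum = np.cumsum(lens[o])
            base_depth = float(depths[o][np.searchsorted(cum, cum[-1] / 2)])
        else:
            base_depth = float(np.median(depths))
        multiplicity = np.maximum(
            1, np.ceil(depths / max(base_depth, 1e-9)).astype(int)
        )
        multiplicity[repeat_like] = np.maximum(multiplicity[repeat_like], 2)

        pair_votes, ctx_votes = _collect_votes(
            index, long_reads, min_chain_anchors, succ, tiny, repeat_like
        )

        visited = np.zeros(len(unitigs), dtype=bool)

        def extend(path: list[tuple[int, int]], use_counts) -> bool:
            """Extend path rightward; returns True when it closed a circle."""
            guard = 0
            ctx = None
            for x in reversed(path):
                if not repeat_like[x[0]]:
                    ctx = x
                    break
            while guard < 10 * len(unitigs) + 100:
                guard += 1
                cur = path[-1]
                cands = []
                for c in succ.get(cur, []):
                    if c == path[0] and len(path) > 1:
                        cands.append(c)
                    elif repeat_like[c[0]]:
                        if use_counts.get(c[0], 0) < multiplicity[c[0]] + 1:
                            cands.append(c)
                    elif not visited[c[0]]:
                        cands.append(c)
                nxt = _pick_next(cur, ctx, cands, pair_votes, ctx_votes, min_bridge_votes)
                if nxt is None:
                    return False
                if nxt == path[0] and len(path) > 1:
                    return True
                path.append(nxt)
                use_counts[nxt[0]] = use_counts.get(nxt[0], 0) + 1
                if not repeat_like[nxt[0]]:
                    visited[nxt[0]] = True
                    ctx = nxt
            return False

        for uid in range(len(unitigs)):
            if visited[uid] or repeat_like[uid] or unitigs[uid].circular:
                continue
            visited[uid] = True
            use_counts = {uid: 1}
            path = [(uid, 0)]
            circular = extend(path, use_counts)
            if not circular:
                # extend the other way: walk right from the flipped path
                path = [_flip(x) for x in reversed(path)]
                circular = extend(path, use_counts)
                path = [_flip(x) for x in reversed(path)]
            paths.append((path, circular))
        for uid, u in enumerate(unitigs):
            if u.circular and not visited[uid]:
                visited[uid] = True
                paths.append(([(uid, 0)], True))
        for uid in range(len(unitigs)):
            if not visited[uid] and not repeat_like[uid]:
                paths.append(([(uid, 0)], False))
        # repeat unitigs never placed in a walk are still reported once
        placed = {u for walk, _ in paths for u, _ in walk}
        for uid in range(len(unitigs)):
            if repeat_like[uid] and uid not in placed:
                paths.append(([(uid, 0)], unitigs[uid].circular))
    else:
        paths = [([(uid, 0)], u.circular) for uid, u in enumerate(unitigs)]

    contigs: list[Contig] = []
    for walk, circular in paths:
        parts = []
        total_len = 0
        depth_sum = 0.0
        for i, (uid, orient) in enumerate(walk):
            u = unitigs[uid]
            s = u.seq if orient == 0 else _kmers.revcomp(u.seq)
            parts.append(s if i == 0 else s[k - 1 :])
            total_len += len(s)
            depth_sum += u.depth * len(s)
        seq = "".join(parts)
        is_circ = circular or (len(walk) == 1 and unitigs[walk[0][0]].circular)
        if circular and len(walk) > 1:
            seq = seq[: -(k - 1)]
        if len(seq) < min_contig_len:
            continue
        contigs.append(
            Contig(
                record=SequenceRecord(
                    id="x", sequence=seq, circular=bool(is_circ)
                ),
                mean_sr_depth=depth_sum / total_len,
            )
        )
    contigs.sort(key=lambda c: (-len(c), c.record.sequence))
    for i, c in enumerate(contigs):
        c.record.id = f"ctg_{i + 1:05d}"
    return contigs


# --------------------------------------------------------------- binning


def _tetra_freq(seq: str) -> np.ndarray:
    words = _kmers.kmer_words(seq, 4)
    counts = np.bincount(words.astype(np.int64), minlength=256).astype(np.float64)
    total = counts.sum()
    return counts / total if total else counts


def toy_bin(
    contigs: Sequence[Contig],
    pairs: Optional[Sequence[ReadPair]] = None,
    k_feature: int = 4,
    max_clusters: Optional[int] = None,
    seed: int = 0,
    distance_threshold: float = 0.06,
    depth_weight: float = 0.2,
) -> list[Bin]:
    """Greedy centroid clustering on composition + depth.

    Per-contig features are the L1-normalised tetranucleotide frequency
    vector and log10 mean short-read depth; distance to a centroid is
    cosine distance plus ``depth_weight`` x |delta log depth|. Contigs are
    processed longest-first and deterministic throughout.
    """
    if not contigs:
        raise ValueError("no contigs to bin")
    if k_feature != 4:
        raise ValueError("only tetranucleotide features are supported")
    order = sorted(range(len(contigs)), key=lambda i: (-len(contigs[i]), contigs[i].record.id))
    tnf = [_tetra_freq(contigs[i].record.sequence) for i in order]
    logd = [np.log10(max(contigs[i].mean_sr_depth, 1e-3)) for i in order]
    lens = [float(len(contigs[i])) for i in order]

    centroids: list[tuple[np.ndarray, float, float]] = []  # (tnf, logd, weight)
    assign: list[list[int]] = []
    for j, ci in enumerate(order):
        best, best_d = -1, np.inf
        for m, (ct, cd, _) in enumerate(centroids):
            denom = np.linalg.norm(tnf[j]) * np.linalg.norm(ct)
            cos = 1.0 - float(np.dot(tnf[j], ct) / denom) if denom else 1.0
            d = cos + depth_weight * abs(logd[j] - cd)
            if d < best_d:
                best, best_d = m, d
        full = max_clusters is not None and len(centroids) >= max_clusters
        if best >= 0 and (best_d <= distance_threshold or full):
            ct, cd, w = centroids[best]
            nw = w + lens[j]
            centroids[best] = (
                (ct * w + tnf[j] * lens[j]) / nw,
                (cd * w + logd[j] * lens[j]) / nw,
                nw,
            )
            assign[best].append(ci)
        else:
            centroids.append((tnf[j].copy(), logd[j], lens[j]))
            assign.append([ci])
    return [
        Bin(bin_id=f"bin_{m + 1:03d}", contigs=[contigs[i] for i in members])
        for m, members in enumerate(assign)
    ]


def refine_bins(
    bins: Sequence[Bin],
    quality_assessor,
    min_completeness: float = 70.0,
    max_contamination: float = 10.0,
    return_unbinned: bool = False,
):
    """Quality-gate bins and strip duplicate-marker contigs.

    A bin survives only with completeness > ``min_completeness`` and
    contamination < ``max_contamination``. Within survivors, a contig
    carrying a marker already present on a larger contig of the same bin is
    reassigned to the unbinned pool.
    """
    kept: list[Bin] = []
    unbinned: list[Contig] = []
    for b in bins:
        qa = quality_assessor(b)
        if not (qa.completeness_pct > min_completeness and qa.contamination_pct < max_contamination):
            continue
        counts = (
            quality_assessor.marker_counts(b)
            if hasattr(quality_assessor, "marker_counts")
            else {}
        )
        dup_markers = sorted(m for m, c in counts.items() if c > 1)
        if dup_markers:
            per_contig = {}
            for c in sorted(b.contigs, key=lambda c: (-len(c), c.record.id)):
                single = Bin(bin_id="tmp", contigs=[c])
                per_contig[c.record.id] = quality_assessor.marker_counts(single)
            seen: set[str] = set()
            keep_contigs, dropped = [], []
            for c in sorted(b.contigs, key=lambda c: (-len(c), c.record.id)):
                mine = {m for m in dup_markers if per_contig[c.record.id].get(m, 0) >= 1}
                if mine & seen:
                    dropped.append(c)
                else:
                    keep_contigs.append(c)
                    seen |= mine
            if keep_contigs:
                kept.append(Bin(bin_id=b.bin_id, contigs=keep_contigs))
            unbinned.extend(dropped)
        else:
            kept.append(b)
    if return_unbinned:
        return kept, unbinned
    return kept


def estimate_depths(
    contigs: Sequence[Contig], pairs: Sequence[ReadPair], k: int = 31, min_depth: int = 1
) -> None:
    """Fill mean_sr_depth for externally assembled contigs (in place)."""
    seqs: list[str] = []
    for p in pairs:
        seqs.append(p.mate1.sequence)
        seqs.append(p.mate2.sequence)
    S, counts = _solid_kmers(seqs, k, min_depth)
    for c in contigs:
        _, words = _kmers.rolling_kmers(_kmers.encode(c.record.sequence), k)
        if words.size == 0:
            c.mean_sr_depth = 0.0
            continue
        pos = np.searchsorted(S, words)
        pos[pos >= S.size] = max(S.size - 1, 0)
        hit = (S[pos] == words) if S.size else np.zeros(words.size, bool)
        c.mean_sr_depth = float(np.where(hit, counts[pos], 0).mean())


def external_assembler(contigs_fasta: str) -> AssemblerAdapter:
    """Adapter ingesting contigs an external assembler left in the workdir."""
    from .formats import read_fasta

    def run(pairs, long_reads, workdir=None, seed=0) -> list[Contig]:
        records = read_fasta(contigs_fasta)
        contigs = [Contig(record=r) for r in records if len(r) >= 1000]
        if pairs:
            estimate_depths(contigs, pairs)
        return contigs

    return run
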