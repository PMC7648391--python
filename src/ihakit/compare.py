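"""MAG-pair analytics: MinHash distances, pairing, gene-inventory
comparison, and dereplication.

Genome distance uses a bottom-s MinHash sketch over canonical 21-mers with
the usual Mash conversion d = -(1/k) ln(2j / (1 + j)), where j is the
Jaccard index estimated from the bottom-s sketch of the union (d = 1 when
no hashes are shared). Gene comparison is exact: two genes are identical
only at 100% amino-acid identity and coverage, i.e. equal predicted-protein
strings. Per-function copy counts split the shared inventory into set I
(same), set II (more copies in the hybrid MAG), set III (hybrid-only) and
set IV (short-read-only).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kmers
from .formats import SequenceRecord
from .orfs import proteins_of

__all__ = [
    "MinHashSketch",
    "sketch",
    "distance",
    "find_pairs",
    "PairComparison",
    "classify_genes",
    "dereplicate",
]


@dataclasses.dataclass(slots=True)
class MinHashSketch:
    k: int
    sketch_size: int
    hashes: np.ndarray  # sorted ascending, <= sketch_size entries

    def __post_init__(self) -> None:
        if self.hashes.size > self.sketch_size:
            raise ValueError("sketch larger than sketch_size")


def sketch(
    genome: Sequence[SequenceRecord] | SequenceRecord | str,
    k: int = 21,
    s: int = 1000,
) -> MinHashSketch:
    """Bottom-s MinHash sketch over canonical k-mers."""
    if isinstance(genome, SequenceRecord):
        seqs = [genome.sequence]
    elif isinstance(genome, str):
        seqs = [genome]
    else:
        seqs = [r.sequence for r in genome]
    if sum(len(x) for x in seqs) <= k:
        raise ValueError("genome shorter than k")
    _, _, words = _kmers.multi_kmer_words(seqs, k)
    if words.size == 0:
        raise ValueError("no valid k-mers")
    canon = np.unique(_kmers.canonical_words(words, k))
    hashes = np.unique(_kmers.splitmix64(canon))
    return MinHashSketch(k=k, sketch_size=s, hashes=hashes[:s])


def distance(a: MinHashSketch, b: MinHashSketch) -> float:
    """Mash distance between two sketches (capped at 1 when j = 0)."""
    if a.k != b.k or a.sketch_size != b.sketch_size:
        raise ValueError("sketches are not comparable")
    s = a.sketch_size
    union = np.union1d(a.hashes, b.hashes)[:s]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    n_shared = int(np.isin(union, shared, assume_unique=True).sum())
    denom = min(s, union.size)
    j = n_shared / denom if denom else 0.0
    if j <= 0:
        return 1.0
    return float(min(1.0, max(0.0, -np.log(2 * j / (1 + j)) / a.k)))


def find_pairs(
    set_a: dict[str, MinHashSketch],
    set_b: dict[str, MinHashSketch],
    max_distance: float = 0.05,
) -> list[tuple[str, str, float]]:
    """Greedy minimum-distance 1-to-1 matching between two MAG sets."""
    cand = []
    for na, sa in set_a.items():
        for nb, sb in set_b.items():
            d = distance(sa, sb)
            if d <= max_distance:
                cand.append((d, na, nb))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    out = []
    for d, na, nb in cand:
        if na in used_a or nb in used_b:
            continue
        used_a.add(na)
        used_b.add(nb)
        out.append((na, nb, d))
    return out


@dataclasses.dataclass(slots=True)
class PairComparison:
    mag_a: str
    mag_b: str
    distance: float
    identical_gene_count: int
    identical_ratio_vs_a: float   # % of MAG A's predicted genes
    identical_ratio_vs_b: float
    set_weighted: dict            # I..IV -> gene-count tallies
    set_unweighted: dict          # I..IV -> distinct-function tallies


def classify_genes(
    mag_a_contigs: Sequence[SequenceRecord],
    mag_b_contigs: Sequence[SequenceRecord],
    annotator: Callable[[str], Optional[tuple[str, str]]] | dict,
    mag_a: str = "hybrid",
    mag_b: str = "sr_only",
    pair_distance: float = float("nan"),
) -> PairComparison:
    """Compare the predicted gene inventories of a MAG pair.

    ``annotator`` maps a protein string to (gene id, function) or None;
    unannotated proteins are treated like hypothetical proteins and are
    excluded from the functional sets (identical-gene counting uses the
    full inventories). MAG A plays the hybrid role, MAG B the short-read
    role. Weighted tallies count genes (per function, the larger of the two
    copy counts, so sets I-IV sum to the multiset-union gene count);
    unweighted tallies count distinct functions.
    """
    if isinstance(annotator, dict):
        lookup = annotator.get
    else:
        lookup = annotator
    prots_a = proteins_of(mag_a_contigs)
    prots_b = proteins_of(mag_b_contigs)
    count_a, count_b = Counter(prots_a), Counter(prots_b)
    identical = sum(min(c, count_b[p]) for p, c in count_a.items())

    func_a: Counter = Counter()
    func_b: Counter = Counter()
    for p, c in count_a.items():
        ann = lookup(p)
        if ann is not None:
            func_a[ann[1]] += c
    for p, c in count_b.items():
        ann = lookup(p)
        if ann is not None:
            func_b[ann[1]] += c

    weighted = {"I": 0, "II": 0, "III": 0, "IV": 0}
    unweighted = {"I": 0, "II": 0, "III": 0, "IV": 0}
    for f in sorted(set(func_a) | set(func_b)):
        ca, cb = func_a.get(f, 0), func_b.get(f, 0)
        if ca > 0 and cb == 0:
            key = "III"
        elif ca == 0 and cb > 0:
            key = "IV"
        elif ca > cb:
            key = "II"
        else:  # equal, or more copies on the short-read side
            key = "I"
        weighted[key] += max(ca, cb)
        unweighted[key] += 1
    return PairComparison(
        mag_a=mag_a,
        mag_b=mag_b,
        distance=pair_distance,
        identical_gene_count=identical,
        identical_ratio_vs_a=100.0 * identical / len(prots_a) if prots_a else 0.0,
        identical_ratio_vs_b=100.0 * identical / len(prots_b) if prots_b else 0.0,
        set_weighted=weighted,
        set_unweighted=unweighted,
    )


def _quality_score(mag) -> float:
    # dRep-style score: completeness - 5 x contamination
    return mag.qa.completeness_pct - 5.0 * mag.qa.contamination_pct


def dereplicate(mags: Sequence, max_distance: float = 0.05, k: int = 21, s: int = 1000):
    """Single-linkage dereplication; one representative per cluster.

    Representatives maximise (completeness - 5 x contamination), then fewer
    contigs, then larger N50, then lexicographic id. Input objects must
    expose ``mag_id``, ``qa`` and ``contig_records`` (MagRecord does).
    """
    mags = sorted(mags, key=lambda m: m.mag_id)
    n = len(mags)
    if n <= 1:
        return list(mags)
    sketches = [sketch(m.contig_records, k=k, s=s) for m in mags]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if distance(sketches[i], sketches[j]) <= max_distance:
                parent[find(i)] = find(j)
    clusters: dict[int, list] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(mags[i])
    reps = []
    for members in clusters.values():
        members.sort(
            key=lambda m: (
                -_quality_score(m),
                m.qa.n_contigs,
                -m.qa.n50,
                m.mag_id,
            )
        )
        reps.append(members[0])
    reps.sort(key=lambda m: m.mag_id)
    return reps
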