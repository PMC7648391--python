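"""Low-level 2-bit k-mer machinery shared across the toolkit.

Sequences are encoded as int8 arrays (A=0, C=1, G=2, T=3, anything else -1);
k-mers (k <= 31) pack into uint64 words, two bits per base, leftmost base in
the highest bits. All routines are vectorised; the only per-sequence Python
loops in the package iterate over reads, never over bases.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes; non-ACGT becomes -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode int8/int64 base codes (0..3) back to a DNA string."""
    return _DECODE[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    c = encode(seq)
    if (c < 0).any():
        # preserve Ns positionally
        out = np.full(c.size, ord("N"), dtype=np.uint8)
        ok = c >= 0
        out[ok] = _DECODE[3 - c[ok]]
        return out[::-1].tobytes().decode("ascii")
    return decode((3 - c)[::-1])


def rolling_kmers(
    codes: np.ndarray, k: int, stride: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """k-mer words of an encoded sequence, optionally every ``stride``-th.

    Returns (positions, words); windows containing an invalid base are
    dropped. Empty result when the sequence is shorter than k.
    """
    if not 0 < k <= 31:
        raise ValueError("k must be in 1..31")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    bad = codes < 0
    any_bad = bool(bad.any())
    safe = np.where(bad, 0, codes).astype(np.uint64) if any_bad else codes.astype(np.uint64)
    pos = np.arange(0, n, stride) if stride > 1 else np.arange(n)
    words = np.zeros(pos.size, dtype=np.uint64)
    if stride > 1:
        for j in range(k):
            words = (words << np.uint64(2)) | safe[pos + j]
    else:
        for j in range(k):
            words = (words << np.uint64(2)) | safe[j : j + n]
    if any_bad:
        cs = np.concatenate(([0], np.cumsum(bad.astype(np.int64))))
        valid = (cs[pos + k] - cs[pos]) == 0
        return pos[valid], words[valid]
    return pos, words


def kmer_words(seq: str, k: int) -> np.ndarray:
    return rolling_kmers(encode(seq), k)[1]


def revcomp_words(words: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer words (vectorised bit reversal)."""
    x = (~words.astype(np.uint64)) & np.uint64((1 << (2 * k)) - 1)
    # reverse the order of 2-bit groups within the 64-bit word
    x = ((x >> np.uint64(2)) & _M2) | ((x & _M2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _M4) | ((x & _M4) << np.uint64(4))
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def canonical_words(words: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(words, revcomp_words(words, k))


def word_to_kmer(word: int, k: int) -> str:
    out = []
    for j in range(k - 1, -1, -1):
        out.append(BASES[(int(word) >> (2 * j)) & 3])
    return "".join(out)


def splitmix64(words: np.ndarray) -> np.ndarray:
    """64-bit mixing hash (splitmix64 finaliser), vectorised."""
    with np.errstate(over="ignore"):
        z = words.astype(np.uint64) + np.uint64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def concat_encoded(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate sequences with a separator sentinel.

    Returns (codes, offsets) where offsets[i] is the start of sequence i in
    the code array; a -1 sentinel sits between sequences so k-mer windows
    never straddle a boundary.
    """
    n = len(seqs)
    lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    total = int(lens.sum()) + max(n - 1, 0)
    codes = np.full(total, -1, dtype=np.int8)
    offsets = np.zeros(n, dtype=np.int64)
    pos = 0
    for i, s in enumerate(seqs):
        offsets[i] = pos
        codes[pos : pos + len(s)] = encode(s)
        pos += len(s) + 1
    return codes, offsets


def multi_kmer_words(
    seqs: list[str], k: int, stride: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """k-mer words for many sequences in one pass.

    Returns (seq_index, position_within_seq, words). A stride > 1 samples
    every stride-th window (the separator sentinel still keeps windows from
    crossing sequence boundaries).
    """
    if not seqs:
        e = np.empty(0, dtype=np.int64)
        return e, e, np.empty(0, dtype=np.uint64)
    codes, offsets = concat_encoded(seqs)
    pos, words = rolling_kmers(codes, k, stride=stride)
    idx = np.searchsorted(offsets, pos, side="right") - 1
    return idx, pos - offsets[idx], words


def presence_fraction(
    seqs: list[str],
    sorted_set: np.ndarray,
    k: int,
    canonical: bool = True,
    stride: int = 1,
) -> np.ndarray:
    """Per-sequence fraction of (sampled) k-mers found in a sorted word set.

    Sequences shorter than k score 0.
    """
    frac = np.zeros(len(seqs), dtype=np.float64)
    if not seqs or sorted_set.size == 0:
        return frac
    idx, _, words = multi_kmer_words(seqs, k, stride=stride)
    if canonical:
        words = canonical_words(words, k)
    if words.size == 0:
        return frac
    loc = np.searchsorted(sorted_set, words)
    loc[loc >= sorted_set.size] = sorted_set.size - 1
    hit = sorted_set[loc] == words
    n_tot = np.bincount(idx, minlength=len(seqs))
    n_hit = np.bincount(idx, weights=hit.astype(np.float64), minlength=len(seqs))
    ok = n_tot > 0
    frac[ok] = n_hit[ok] / n_tot[ok]
    return frac


def booth_least_rotation(s: str) -> str:
    """Lexicographically least rotation (Booth's algorithm), O(n)."""
    n = len(s)
    if n == 0:
        return s
    t = s + s
    f = [-1] * len(t)
    least = 0
    for j in range(1, len(t)):
        sj = t[j]
        i = f[j - least - 1]
        while i != -1 and sj != t[least + i + 1]:
            if sj < t[least + i + 1]:
                least = j - i - 1
            i = f[i]
        if sj != t[least + i + 1]:
            if sj < t[least]:
                least = j
            f[j - least] = -1
        else:
            f[j - least] = i + 1
    return t[least : least + n]


def canonical_circular(seq: str) -> str:
    """Strand- and rotation-invariant canonical form of a circular sequence."""
    return min(booth_least_rotation(seq), booth_least_rotation(revcomp(seq)))
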