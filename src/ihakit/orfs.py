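"""Minimal prokaryotic ORF caller.

Six-frame scan with start codons {ATG, GTG, TTG}, standard genetic code,
and the longest-ORF-per-stop convention: for each stop codon the ORF starts
at the first start codon after the previous in-frame stop. ORFs shorter than
``min_len`` nucleotides (stop codon included) are dropped. This is the
single gene-prediction routine used for gene-recovery and MAG-pair
comparisons; it is not a Prodigal replacement.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from Bio.Seq import Seq

from . import _kmers

_STOPS = frozenset((48, 50, 56))   # TAA, TAG, TGA
_STARTS = frozenset((14, 46, 62))  # ATG, GTG, TTG


@dataclasses.dataclass(slots=True, frozen=True)
class Orf:
    """A predicted gene on the forward coordinates of its source sequence."""

    seq_id: str
    start: int       # 0-based, half-open, on the forward strand
    end: int
    strand: str
    protein: str     # translation, stop codon excluded


def _frame_orfs(codes: np.ndarray, frame: int, min_len: int):
    """Yield (start_nt, end_nt) per-strand ORFs for one frame, coordinates on
    the given code array."""
    usable = codes.size - frame
    n_codons = usable // 3
    if n_codons < 2:
        return
    c = codes[frame : frame + n_codons * 3].reshape(n_codons, 3)
    if (c < 0).any():
        valid = (c >= 0).all(axis=1)
    else:
        valid = None
    vals = c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
    is_stop = np.isin(vals, list(_STOPS))
    is_start = np.isin(vals, list(_STARTS))
    if valid is not None:
        is_stop &= valid
        is_start &= valid
    stops = np.nonzero(is_stop)[0]
    starts = np.nonzero(is_start)[0]
    prev = -1
    for s in stops:
        j = np.searchsorted(starts, prev + 1)
        if j < starts.size and starts[j] < s:
            first = int(starts[j])
            length_nt = (s - first + 1) * 3
            if length_nt >= min_len:
                yield frame + first * 3, frame + (int(s) + 1) * 3
        prev = int(s)


def find_orfs(seq_id: str, sequence: str, min_len: int = 90) -> list[Orf]:
    """All ORFs on both strands of a sequence, forward coordinates."""
    out: list[Orf] = []
    fwd = _kmers.encode(sequence)
    rc_seq = _kmers.revcomp(sequence)
    rev = _kmers.encode(rc_seq)
    n = len(sequence)
    for frame in range(3):
        for s, e in _frame_orfs(fwd, frame, min_len):
            prot = str(Seq(sequence[s : e - 3]).translate())
            out.append(Orf(seq_id, s, e, "+", prot))
        for s, e in _frame_orfs(rev, frame, min_len):
            prot = str(Seq(rc_seq[s : e - 3]).translate())
            out.append(Orf(seq_id, n - e, n - s, "-", prot))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def proteins_of(records) -> list[str]:
    """Predicted protein inventory of a set of sequence records."""
    prots: list[str] = []
    for rec in records:
        prots.extend(o.protein for o in find_orfs(rec.id, rec.sequence))
    return prots
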