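"""Sequence and alignment interchange: FASTA, paired FASTQ, PAF, TSV.

Conventions used throughout the toolkit:

* all coordinates are 0-based, half-open; conversions happen only at file
  boundaries (PAF is already 0-based half-open);
* FASTA is written 60 columns wide; circularity, which FASTA cannot express,
  is carried as a trailing ``circular=true`` key in the description;
* FASTQ is 4-line, phred-33 (modern Illumina/ONT).

FASTA and PAF readers are deliberately local code: the contract here includes
line-numbered parse errors and byte-exact round trips. FASTQ goes through
Bio.SeqIO.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "ReadPair",
    "AlignmentRecord",
    "ParseError",
    "PairingError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_paired_fastq",
    "write_paired_fastq",
    "parse_paf",
    "write_paf",
    "read_tsv",
    "write_tsv",
]

_VALID = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class PairingError(ValueError):
    """Mate files disagree (record counts or read ids)."""


@dataclasses.dataclass(slots=True)
class SequenceRecord:
    """A DNA sequence with optional phred qualities and a circular flag."""

    id: str
    sequence: str
    description: str = ""
    quality: Optional[np.ndarray] = None
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"sequence id {self.id!r} must be non-empty, no whitespace")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        if not set(seq) <= _VALID:
            bad = sorted(set(seq) - _VALID)
            raise ValueError(f"record {self.id!r}: invalid characters {bad}")
        self.sequence = seq
        if self.quality is not None:
            q = np.asarray(self.quality, dtype=np.int16)
            if q.size != len(seq):
                raise ValueError(
                    f"record {self.id!r}: quality length {q.size} != sequence length {len(seq)}"
                )
            if (q < 0).any():
                raise ValueError(f"record {self.id!r}: negative phred score")
            self.quality = q

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(slots=True)
class ReadPair:
    """A synchronised mate pair; mate ids derive from pair_id by /1 and /2."""

    pair_id: str
    mate1: SequenceRecord
    mate2: SequenceRecord

    def __post_init__(self) -> None:
        if self.mate1.id == self.mate2.id:
            raise ValueError(f"pair {self.pair_id!r}: identical mate ids")

    @property
    def total_bp(self) -> int:
        return len(self.mate1) + len(self.mate2)


@dataclasses.dataclass(slots=True)
class AlignmentRecord:
    """PAF-semantics query-to-target alignment (0-based, half-open)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int

    def __post_init__(self) -> None:
        for which, start, end, ln in (
            ("query", self.query_start, self.query_end, self.query_len),
            ("target", self.target_start, self.target_end, self.target_len),
        ):
            if not 0 <= start < end <= ln:
                raise ValueError(
                    f"{self.query_id} vs {self.target_id}: bad {which} interval "
                    f"[{start}, {end}) on length {ln}"
                )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.n_matches > self.block_len:
            raise ValueError("n_matches exceeds block_len")

    @property
    def identity(self) -> float:
        return self.n_matches / self.block_len if self.block_len else 0.0

    @property
    def query_coverage(self) -> float:
        return (self.query_end - self.query_start) / self.query_len


_CIRC_KEY = "circular=true"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse FASTA; a trailing ``circular=true`` description key sets the flag."""
    records: list[SequenceRecord] = []
    header: Optional[tuple[str, str, int]] = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid, desc, lineno = header
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: empty sequence for {rid!r} at line {lineno}")
        circular = False
        if desc.split()[-1:] == [_CIRC_KEY]:
            circular = True
            desc = desc[: -len(_CIRC_KEY)].rstrip()
        records.append(
            SequenceRecord(id=rid, sequence=seq, description=desc, circular=circular)
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                chunks = []
                fields = line[1:].split(maxsplit=1)
                if not fields:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                rid = fields[0]
                desc = fields[1] if len(fields) > 1 else ""
                header = (rid, desc, lineno)
            else:
                if header is None:
                    raise ParseError(
                        f"{path}: sequence before any '>' header at line {lineno}"
                    )
                chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = rec.description
            if rec.circular:
                desc = f"{desc} {_CIRC_KEY}".strip()
            head = f">{rec.id} {desc}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _from_bio(rec) -> SequenceRecord:
    qual = rec.letter_annotations.get("phred_quality")
    return SequenceRecord(
        id=rec.id,
        sequence=str(rec.seq),
        description=rec.description[len(rec.id) :].strip() if rec.description else "",
        quality=np.asarray(qual, dtype=np.int16) if qual is not None else None,
    )


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Parse a 4-line FASTQ file (phred-33)."""
    return [_from_bio(r) for r in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write 4-line FASTQ; records without qualities get phred 40 ('I')."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                qstr = "I" * len(rec.sequence)
            else:
                qstr = "".join(chr(min(int(q), 93) + 33) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qstr}\n")


def _strip_mate_suffix(read_id: str) -> str:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def read_paired_fastq(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Parse two synchronised FASTQ files into mate pairs."""
    m1 = read_fastq(path1)
    m2 = read_fastq(path2)
    if len(m1) != len(m2):
        raise PairingError(
            f"{path1} has {len(m1)} records but {path2} has {len(m2)}"
        )
    pairs = []
    for a, b in zip(m1, m2):
        pa, pb = _strip_mate_suffix(a.id), _strip_mate_suffix(b.id)
        if pa != pb:
            raise PairingError(f"mate id mismatch: {a.id!r} vs {b.id!r}")
        if a.id == b.id:
            a = dataclasses.replace(a, id=f"{pa}/1")
            b = dataclasses.replace(b, id=f"{pb}/2")
        pairs.append(ReadPair(pair_id=pa, mate1=a, mate2=b))
    return pairs


def write_paired_fastq(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    pairs = list(pairs)
    write_fastq((p.mate1 for p in pairs), path1)
    write_fastq((p.mate2 for p in pairs), path2)


def parse_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse minimap2-style PAF (>= 12 tab-separated columns; extras ignored)."""
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 12 PAF columns, got {len(cols)}"
                )
            try:
                rec = AlignmentRecord(
                    query_id=cols[0],
                    query_len=int(cols[1]),
                    query_start=int(cols[2]),
                    query_end=int(cols[3]),
                    strand=cols[4],
                    target_id=cols[5],
                    target_len=int(cols[6]),
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    n_matches=int(cols[9]),
                    block_len=int(cols[10]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            out.append(rec)
    return out


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.query_len, r.query_start, r.query_end,
                        r.strand,
                        r.target_id, r.target_len, r.target_start, r.target_end,
                        r.n_matches, r.block_len, 255,
                    )
                )
                + "\n"
            )


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
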