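"""MAG quality assessment and tier classification.

Completeness and contamination are estimated from a library of planted
single-copy marker genes, mirroring the single-copy core-gene convention:
completeness is the percent of markers present at least once, contamination
the percent of extra marker copies. Tier definitions:

* FINISHED - a single circular sequence that also meets the HQ thresholds;
* HQ       - >90% complete, <5% contaminated, all of 5S/16S/23S present,
             >= 18 tRNAs;
* DQ       - >70% complete, <10% contaminated, 16S present, >= 18 tRNAs;
* LQ       - all DQ criteria except the 16S;
* UNQUALIFIED otherwise.

High contiguity (HC) means <= 5 contigs. The iteration gate keeps
FINISHED/HQ MAGs that are also HC. All inequalities are strict exactly as
stated (> 90, < 5, > 70, < 10, >= 18, <= 5).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assembly import Bin
from .evaluate import AnchorIndex, align_to_reference, contig_n50
from .formats import SequenceRecord
from .synthetic import MarkerLibrary

__all__ = [
    "QualityAssessment",
    "MagRecord",
    "marker_scan",
    "cassette_counts",
    "completeness_contamination",
    "classify_tier",
    "assess_bin",
    "MarkerQualityAssessor",
    "is_qualified",
    "summarize_manifest",
    "load_table1",
    "classify_table1",
]

TIERS = ("FINISHED", "HQ", "DQ", "LQ", "UNQUALIFIED")


@dataclasses.dataclass(slots=True)
class QualityAssessment:
    completeness_pct: float
    contamination_pct: float
    n_contigs: int
    genome_size: int
    n50: int
    gc_fraction: float
    circular_single: bool
    rrna_counts: dict
    trna_count: int
    tier: str
    high_contiguity: bool


@dataclasses.dataclass(slots=True)
class MagRecord:
    """A binned genome under the H{cycle}_{label} naming convention."""

    mag_id: str
    bin: Bin
    qa: QualityAssessment

    @property
    def contig_records(self) -> list[SequenceRecord]:
        return [c.record for c in self.bin.contigs]


def _count_copies(
    query: SequenceRecord,
    contigs: Sequence[SequenceRecord],
    index: AnchorIndex,
    min_identity: float,
    min_coverage: float,
) -> int:
    blocks = align_to_reference(
        [query], contigs, index=index, min_chain_anchors=1
    )
    n = 0
    for b in blocks:
        if (
            b.identity >= min_identity
            and (b.qend - b.qstart) / len(query) >= min_coverage
        ):
            n += 1
    return n


def marker_scan(
    bin_or_contigs,
    lib: MarkerLibrary,
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> dict[str, int]:
    """Per-marker copy counts in a bin, by cassette alignment."""
    contigs = _as_records(bin_or_contigs)
    index = AnchorIndex(contigs, k=15, max_hits=512)
    return {
        name: _count_copies(
            SequenceRecord(id=name, sequence=seq), contigs, index,
            min_identity, min_coverage,
        )
        for name, seq in sorted(lib.markers.items())
    }


def cassette_counts(
    bin_or_contigs,
    lib: MarkerLibrary,
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> tuple[dict[str, int], int]:
    """(rRNA counts per gene, tRNA count) by cassette alignment."""
    contigs = _as_records(bin_or_contigs)
    index = AnchorIndex(contigs, k=15, max_hits=512)
    rrna = {
        gene: _count_copies(
            SequenceRecord(id=gene, sequence=seq), contigs, index,
            min_identity, min_coverage,
        )
        for gene, seq in sorted(lib.rrna_cassettes.items())
    }
    trna = _count_copies(
        SequenceRecord(id="trna", sequence=lib.trna_cassette), contigs, index,
        min_identity, min_coverage,
    )
    return rrna, trna


def _as_records(bin_or_contigs) -> list[SequenceRecord]:
    if isinstance(bin_or_contigs, Bin):
        return [c.record for c in bin_or_contigs.contigs]
    out = []
    for c in bin_or_contigs:
        out.append(c.record if hasattr(c, "record") else c)
    return out


def completeness_contamination(
    copy_counts: dict[str, int] | Sequence[int], n_markers: Optional[int] = None
) -> tuple[float, float]:
    """CheckM-style formulas on marker copy counts.

    completeness = 100 x (markers present) / K;
    contamination = 100 x (extra copies) / K.
    """
    counts = list(copy_counts.values()) if isinstance(copy_counts, dict) else list(copy_counts)
    k = n_markers if n_markers is not None else len(counts)
    if k <= 0:
        raise ValueError("marker count must be positive")
    present = sum(1 for c in counts if c >= 1)
    extra = sum(max(c - 1, 0) for c in counts)
    return 100.0 * present / k, 100.0 * extra / k


def classify_tier(
    completeness_pct: float,
    contamination_pct: float,
    n_contigs: int,
    circular_single: bool,
    rrna_counts: dict,
    trna_count: int,
    genome_size: int = 0,
    n50: int = 0,
    gc_fraction: float = float("nan"),
) -> QualityAssessment:
    """Assign the quality tier and the high-contiguity flag."""
    r5, r16, r23 = (
        rrna_counts.get("5S", 0),
        rrna_counts.get("16S", 0),
        rrna_counts.get("23S", 0),
    )
    hq = (
        completeness_pct > 90
        and contamination_pct < 5
        and r5 >= 1 and r16 >= 1 and r23 >= 1
        and trna_count >= 18
    )
    dq_core = completeness_pct > 70 and contamination_pct < 10 and trna_count >= 18
    if hq and n_contigs == 1 and circular_single:
        tier = "FINISHED"
    elif hq:
        tier = "HQ"
    elif dq_core and r16 >= 1:
        tier = "DQ"
    elif dq_core:
        tier = "LQ"
    else:
        tier = "UNQUALIFIED"
    return QualityAssessment(
        completeness_pct=completeness_pct,
        contamination_pct=contamination_pct,
        n_contigs=n_contigs,
        genome_size=genome_size,
        n50=n50,
        gc_fraction=gc_fraction,
        circular_single=circular_single,
        rrna_counts=dict(rrna_counts),
        trna_count=trna_count,
        tier=tier,
        high_contiguity=n_contigs <= 5,
    )


def is_qualified(qa: QualityAssessment, gate: str = "hq_hc") -> bool:
    """The iteration gate: which MAGs are reserved and depleted."""
    if gate == "hq_hc":
        return qa.tier in ("FINISHED", "HQ") and qa.high_contiguity
    if gate == "dq_hc":
        return qa.tier in ("FINISHED", "HQ", "DQ") and qa.high_contiguity
    raise ValueError(f"unknown gate {gate!r}")


def assess_bin(
    bin_: Bin,
    lib: MarkerLibrary,
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> QualityAssessment:
    """Full assessment of a bin against a marker library.

    The identity threshold must sit below the library-to-genome cassette
    divergence of the data at hand (planted cassettes are verbatim by
    default; diverged homolog communities need a looser setting).
    """
    contigs = [c.record for c in bin_.contigs]
    copy_counts = marker_scan(bin_, lib, min_identity, min_coverage)
    comp, cont = completeness_contamination(copy_counts, lib.n_markers)
    rrna, trna = cassette_counts(bin_, lib, min_identity, min_coverage)
    sizes = [len(c) for c in contigs]
    gc = sum(s.count("G") + s.count("C") for s in (c.sequence for c in contigs))
    return classify_tier(
        comp,
        cont,
        n_contigs=len(contigs),
        circular_single=len(contigs) == 1 and contigs[0].circular,
        rrna_counts=rrna,
        trna_count=trna,
        genome_size=sum(sizes),
        n50=contig_n50(sizes),
        gc_fraction=gc / sum(sizes),
    )


class MarkerQualityAssessor:
    """Callable bin -> QualityAssessment bound to one marker library."""

    def __init__(
        self,
        lib: MarkerLibrary,
        min_identity: float = 0.95,
        min_coverage: float = 0.95,
    ):
        self.lib = lib
        self.min_identity = min_identity
        self.min_coverage = min_coverage

    def __call__(self, bin_: Bin) -> QualityAssessment:
        return assess_bin(bin_, self.lib, self.min_identity, self.min_coverage)

    def marker_counts(self, bin_: Bin) -> dict[str, int]:
        return marker_scan(bin_, self.lib, self.min_identity, self.min_coverage)


def summarize_manifest(
    mags: Sequence[MagRecord] | pd.DataFrame,
    id_pattern: Optional[str] = None,
    tiers: Optional[Sequence[str]] = None,
    exclude_ids: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict]:
    """Manifest table plus aggregate statistics over a selected subset.

    Standard deviations are sample (n-1); a single-row subset reports sd 0
    with ``sd_defined`` False.
    """
    if isinstance(mags, pd.DataFrame):
        frame = mags.copy()
    else:
        frame = pd.DataFrame(
            {
                "mag_id": m.mag_id,
                "status": "Circular" if m.qa.circular_single else "",
                "genome_size": m.qa.genome_size,
                "n50": m.qa.n50,
                "n_contigs": m.qa.n_contigs,
                "gc": m.qa.gc_fraction,
                "completeness": m.qa.completeness_pct,
                "contamination": m.qa.contamination_pct,
                "rrna": sum(m.qa.rrna_counts.values()),
                "trna": m.qa.trna_count,
                "tier": m.qa.tier,
                "hc": m.qa.high_contiguity,
            }
            for m in mags
        )
    sub = frame
    if id_pattern is not None:
        sub = sub[sub.mag_id.str.match(id_pattern)]
    if tiers is not None:
        sub = sub[sub.tier.isin(tiers)]
    if len(exclude_ids):
        sub = sub[~sub.mag_id.isin(exclude_ids)]
    stats: dict = {
        "n": int(len(sub)),
        "tier_counts": sub.tier.value_counts().to_dict() if len(sub) else {},
        "n_circular": int((sub.status == "Circular").sum()) if len(sub) else 0,
        "sd_defined": len(sub) > 1,
    }
    for col in ("n50", "completeness", "contamination"):
        if len(sub):
            stats[f"mean_{col}"] = float(sub[col].mean())
            stats[f"sd_{col}"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0
        else:
            stats[f"mean_{col}"] = float("nan")
            stats[f"sd_{col}"] = float("nan")
    return sub.reset_index(drop=True), stats


def load_table1() -> pd.DataFrame:
    """The packaged 27-MAG manifest fixture (sizes in Mbp)."""
    with resources.files("ihakit.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t").fillna({"status": ""})


def classify_table1(table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Run tier classification over the packaged manifest.

    The fixture prints one total rRNA feature count per MAG; it is split
    evenly over 5S/16S/23S (3 -> one of each).
    """
    t = table if table is not None else load_table1()
    rows = []
    for _, r in t.iterrows():
        per_gene = int(r.rrna) // 3
        qa = classify_tier(
            completeness_pct=float(r.completeness),
            contamination_pct=float(r.contamination),
            n_contigs=int(r.n_contigs),
            circular_single=str(r.status) == "Circular",
            rrna_counts={"5S": per_gene, "16S": per_gene, "23S": per_gene},
            trna_count=int(r.trna),
            genome_size=int(round(float(r.size_mbp) * 1e6)),
            n50=int(round(float(r.n50_mbp) * 1e6)),
            gc_fraction=float(r.gc),
        )
        rows.append(
            {
                "mag_id": r.mag_id,
                "status": r.status,
                "n50": qa.n50,
                "n_contigs": qa.n_contigs,
                "completeness": qa.completeness_pct,
                "contamination": qa.contamination_pct,
                "tier": qa.tier,
                "hc": qa.high_contiguity,
                "qualified": is_qualified(qa),
            }
        )
    return pd.DataFrame(rows)
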