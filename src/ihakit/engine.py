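"""The iterative hybrid assembly (IHA) loop.

Each cycle: subsample the residual pools, hybrid-assemble, bin, refine,
assess, keep the qualified (by default high-quality and high-contiguity)
MAGs, then recruit and remove the reads belonging to every qualified MAG
accumulated so far, so the next cycle sees a residual pool enriched for
whatever has not been assembled yet. MAGs are named H{cycle}_{label}.

The loop stops when max_cycles is reached, a cycle yields no newly
qualified MAG, or the residual pools empty. The final genome set is the
accumulated qualified MAGs plus the last cycle's DQ-or-better leftovers,
dereplicated by MinHash distance.

Cycle-1 subsample sizes default to the study proportions (6 Gbp short reads
and 22 Gbp long reads; later cycles 20 million pairs and 1 million long
reads) times a user scale factor, so desk-scale runs keep the same shape.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from functools import partial
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .assembly import Bin, Contig, toy_bin, toy_hybrid_assemble, refine_bins
from .depletion import CyclePools, deplete, recruit_long, recruit_short
from .formats import ReadPair, SequenceRecord, write_fasta
from .quality import MagRecord, MarkerQualityAssessor, is_qualified
from .subsample import subsample_long, subsample_pairs
from .synthetic import Community, MarkerLibrary

__all__ = [
    "IhaConfig",
    "RunState",
    "stable_seed",
    "run_cycle",
    "run_iha",
    "normalized_coverage",
    "pool_composition",
    "rare_recovery_benchmark",
]

PAPER_CYCLE1_SR_BP = 6e9
PAPER_CYCLE1_LR_BP = 22e9
PAPER_LATER_SR_PAIRS = 20_000_000
PAPER_LATER_LR_READS = 1_000_000


def stable_seed(seed: int, *labels) -> int:
    """Derive a child seed from stable stage labels (< 2**31)."""
    text = "|".join([str(seed), *map(str, labels)])
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclasses.dataclass
class IhaConfig:
    cycle1_sr_bp: float = PAPER_CYCLE1_SR_BP
    cycle1_lr_bp: float = PAPER_CYCLE1_LR_BP
    later_sr_pairs: int = PAPER_LATER_SR_PAIRS
    later_lr_reads: int = PAPER_LATER_LR_READS
    max_cycles: int = 5
    gate: str = "hq_hc"
    seed: int = 0
    assembler: Optional[Callable] = None  # adapter; default = toy backend
    assembler_k: int = 31
    assembler_min_depth: int = 3
    min_contig_len: int = 1000
    marker_min_identity: float = 0.95
    marker_min_coverage: float = 0.95
    workdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        for v in (self.cycle1_sr_bp, self.cycle1_lr_bp, self.later_sr_pairs, self.later_lr_reads):
            if v <= 0:
                raise ValueError("all subsample sizes must be positive")

    @classmethod
    def scaled(cls, scale: float, **overrides) -> "IhaConfig":
        """Config at the study proportions times ``scale``."""
        base = dict(
            cycle1_sr_bp=PAPER_CYCLE1_SR_BP * scale,
            cycle1_lr_bp=PAPER_CYCLE1_LR_BP * scale,
            later_sr_pairs=max(1, int(PAPER_LATER_SR_PAIRS * scale)),
            later_lr_reads=max(1, int(PAPER_LATER_LR_READS * scale)),
        )
        base.update(overrides)
        return cls(**base)

    def make_assembler(self) -> Callable:
        if self.assembler is not None:
            return self.assembler
        return partial(
            toy_hybrid_assemble,
            k=self.assembler_k,
            min_depth=self.assembler_min_depth,
            min_contig_len=self.min_contig_len,
        )


@dataclasses.dataclass
class RunState:
    residual_pairs: list[ReadPair]
    residual_long: list[SequenceRecord]
    cycle: int = 0
    qualified: list[MagRecord] = dataclasses.field(default_factory=list)
    last_cycle_mags: list[MagRecord] = dataclasses.field(default_factory=list)
    logs: list[dict] = dataclasses.field(default_factory=list)
    recruited_sr_bp: dict = dataclasses.field(default_factory=dict)
    recruited_lr_bp: dict = dataclasses.field(default_factory=dict)
    sr_pool_bp: float = 0.0
    lr_pool_bp: float = 0.0

    def __post_init__(self) -> None:
        if not self.sr_pool_bp:
            self.sr_pool_bp = float(sum(p.total_bp for p in self.residual_pairs))
        if not self.lr_pool_bp:
            self.lr_pool_bp = float(sum(len(r) for r in self.residual_long))


def normalized_coverage(mean_depth: float, total_bp: float) -> float:
    """Mean depth normalised to 10 Gbp of sequencing of that read class."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    return mean_depth * (1e10 / total_bp)


def pool_composition(
    pairs: Sequence[ReadPair], truth: pd.DataFrame
) -> dict[str, float]:
    """Per-genome base fractions of a pair pool from a truth table."""
    src = truth.drop_duplicates("pair_id").set_index("pair_id")["genome"]
    bases: dict[str, float] = {}
    total = 0
    for p in pairs:
        g = src.get(p.pair_id, "?")
        bases[g] = bases.get(g, 0) + p.total_bp
        total += p.total_bp
    return {g: b / total for g, b in bases.items()} if total else {}


def run_cycle(
    state: RunState,
    config: IhaConfig,
    lib: MarkerLibrary,
    sr_truth: Optional[pd.DataFrame] = None,
) -> RunState:
    """Execute one IHA cycle in place: subsample, assemble, bin, refine,
    assess, gate, and deplete against all accumulated qualified MAGs."""
    if not state.residual_pairs:
        raise RuntimeError("residual short-read pool is empty; run finished")
    cycle = state.cycle + 1
    if cycle == 1:
        sub_pairs = subsample_pairs(
            state.residual_pairs, target_bp=config.cycle1_sr_bp,
            seed=stable_seed(config.seed, "sr_subsample", cycle),
        )
        sub_long = subsample_long(
            state.residual_long, target_bp=config.cycle1_lr_bp,
            seed=stable_seed(config.seed, "lr_subsample", cycle),
        )
    else:
        sub_pairs = subsample_pairs(
            state.residual_pairs, target_count=config.later_sr_pairs,
            seed=stable_seed(config.seed, "sr_subsample", cycle),
        )
        sub_long = subsample_long(
            state.residual_long, target_count=config.later_lr_reads,
            seed=stable_seed(config.seed, "lr_subsample", cycle),
        )

    assembler = config.make_assembler()
    contigs = assembler(sub_pairs, sub_long, seed=stable_seed(config.seed, "assemble", cycle))
    assessor = MarkerQualityAssessor(
        lib, config.marker_min_identity, config.marker_min_coverage
    )
    mags: list[MagRecord] = []
    n_bins = 0
    if contigs:
        bins = toy_bin(contigs, sub_pairs, seed=stable_seed(config.seed, "bin", cycle))
        n_bins = len(bins)
        refined = refine_bins(bins, assessor)
        refined.sort(key=lambda b: (-b.size_bp, b.bin_id))
        for i, b in enumerate(refined):
            qa = assessor(b)
            mag_id = f"H{cycle}_MAG{i + 1:02d}"
            for c in b.contigs:  # namespace contig ids across cycles and MAGs
                c.record.id = f"{mag_id}.{c.record.id}"
            mags.append(MagRecord(mag_id=mag_id, bin=b, qa=qa))
    newly_qualified = [m for m in mags if is_qualified(m.qa, config.gate)]
    state.qualified.extend(newly_qualified)
    state.last_cycle_mags = mags

    mag_sets = [(m.mag_id, m.contig_records) for m in state.qualified]
    pools = CyclePools()
    pools, sr_bases = recruit_short(state.residual_pairs, mag_sets, pools=pools)
    pools, lr_bases = recruit_long(state.residual_long, mag_sets, pools=pools)
    residual_pairs, residual_long, depl_report = deplete(pools)

    for mag, b in sr_bases.items():
        state.recruited_sr_bp[mag] = state.recruited_sr_bp.get(mag, 0) + b
    for mag, b in lr_bases.items():
        state.recruited_lr_bp[mag] = state.recruited_lr_bp.get(mag, 0) + b

    log = {
        "cycle": cycle,
        "sub_pairs": len(sub_pairs),
        "sub_long": len(sub_long),
        "n_contigs": len(contigs),
        "n_bins": n_bins,
        "n_mags_refined": len(mags),
        "n_newly_qualified": len(newly_qualified),
        "qualified_ids": [m.mag_id for m in newly_qualified],
        **depl_report,
    }
    if sr_truth is not None:
        log["residual_composition"] = pool_composition(residual_pairs, sr_truth)
    state.logs.append(log)
    state.residual_pairs = residual_pairs
    state.residual_long = residual_long
    state.cycle = cycle

    if config.workdir:
        wd = Path(config.workdir) / f"cycles/H{cycle}"
        wd.mkdir(parents=True, exist_ok=True)
        for m in mags:
            write_fasta(m.contig_records, wd / f"{m.mag_id}.fa")
        with open(wd / "log.json", "w") as fh:
            json.dump(log, fh, indent=1, default=str)
    return state


def _final_mag_set(state: RunState) -> list[MagRecord]:
    from .compare import dereplicate

    qualified_ids = {m.mag_id for m in state.qualified}
    pool = list(state.qualified)
    for m in state.last_cycle_mags:
        if m.mag_id not in qualified_ids and m.qa.tier in ("FINISHED", "HQ", "DQ"):
            pool.append(m)
    return dereplicate(pool)


def run_iha(
    short_pairs: Sequence[ReadPair],
    long_reads: Sequence[SequenceRecord],
    config: IhaConfig,
    lib: MarkerLibrary,
    sr_truth: Optional[pd.DataFrame] = None,
) -> tuple[list[MagRecord], pd.DataFrame, RunState]:
    """Run the full IHA loop.

    Returns (final dereplicated MAG set, per-MAG report, run state). The
    report includes per-MAG mean depths normalised per 10 Gbp of the
    original pools.
    """
    state = RunState(residual_pairs=list(short_pairs), residual_long=list(long_reads))
    while state.cycle < config.max_cycles:
        if not state.residual_pairs:
            break
        run_cycle(state, config, lib, sr_truth=sr_truth)
        if state.logs[-1]["n_newly_qualified"] == 0 and state.cycle > 1:
            break
    final = _final_mag_set(state)
    rows = []
    for m in final:
        size = m.qa.genome_size
        sr_depth = state.recruited_sr_bp.get(m.mag_id, 0) / size if size else 0.0
        lr_depth = state.recruited_lr_bp.get(m.mag_id, 0) / size if size else 0.0
        rows.append(
            {
                "mag_id": m.mag_id,
                "tier": m.qa.tier,
                "hc": m.qa.high_contiguity,
                "n_contigs": m.qa.n_contigs,
                "genome_size": size,
                "n50": m.qa.n50,
                "completeness": m.qa.completeness_pct,
                "contamination": m.qa.contamination_pct,
                "sr_cov_per_10gbp": normalized_coverage(sr_depth, state.sr_pool_bp)
                if state.sr_pool_bp else 0.0,
                "lr_cov_per_10gbp": normalized_coverage(lr_depth, state.lr_pool_bp)
                if state.lr_pool_bp else 0.0,
            }
        )
    report = pd.DataFrame(rows)
    return final, report, state


def rare_recovery_benchmark(seed: int = 1) -> dict:
    """Study conditions for the six-genome rare-recovery benchmark.

    90 Mbp of error-free short-read pairs and 45 Mbp of 2%-error long reads
    over the ~2.8 Mbp six-genome community (abundances 40/25/15/10/7/3 %);
    cycle subsamples of 35 Mbp short reads and 15 Mbp long reads so only the
    dominant genomes assemble cleanly in cycle 1. The assembler counts every
    error-free short-read k-mer (min_depth 1).
    """
    from .synthetic import (
        rare_recovery_community,
        simulate_long_reads,
        simulate_short_reads,
    )

    community = rare_recovery_community(seed=stable_seed(seed, "community"))
    pairs, sr_truth = simulate_short_reads(
        community, total_bp=90e6, sub_error_rate=0.0,
        seed=stable_seed(seed, "short_reads"),
    )
    reads, lr_truth = simulate_long_reads(
        community, total_bp=45e6, error_rate=0.02,
        seed=stable_seed(seed, "long_reads"),
    )
    n_pairs_later = int(35e6 // 300)
    config = IhaConfig(
        cycle1_sr_bp=35e6,
        cycle1_lr_bp=15e6,
        later_sr_pairs=n_pairs_later,
        later_lr_reads=2000,
        max_cycles=5,
        assembler_min_depth=1,
        # the benchmark community's cassette homologs are ~10% diverged from
        # the library consensus, so scan at the matching identity level
        marker_min_identity=0.85,
        marker_min_coverage=0.90,
        seed=seed,
    )
    return {
        "community": community,
        "pairs": pairs,
        "sr_truth": sr_truth,
        "long_reads": reads,
        "lr_truth": lr_truth,
        "config": config,
    }
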