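"""Truth-known synthetic communities and read simulation.

The generator emulates the structure of a deeply sequenced enrichment
metagenome: a handful of circular/linear genomes spanning a wide abundance
range (down to a few percent and below), planted single-copy marker genes
(the completeness/contamination currency), 5S/16S/23S rRNA operons and tRNA
cassettes (the quality-tier currency), long intragenomic repeats (such as a
>2.1 kbp element at 13 copies), and plasmids at elevated copy number. Short
reads are 150 bp pairs with a ~350 bp insert; long reads are log-normal with
an N50 near 23 kbp, minimum 1 kbp, and a substitution/insertion/deletion
error mix of 60/20/20.

Every simulated read carries a truth record (source replicon, start, strand),
so downstream stages can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kmers
from ._kmers import _DECODE
from .formats import ReadPair, SequenceRecord

__all__ = [
    "GenomeSpec",
    "MarkerLibrary",
    "Genome",
    "Community",
    "GenerationError",
    "generate_genome",
    "build_community",
    "simulate_short_reads",
    "simulate_long_reads",
    "rare_recovery_community",
]

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]


class GenerationError(RuntimeError):
    """Planted elements could not be placed without overlap."""


@dataclasses.dataclass(slots=True)
class GenomeSpec:
    """Blueprint for one synthetic genome.

    ``abundance_weight`` is the genome's relative DNA (base) abundance in the
    community; weights are normalised over a community. ``repeats`` is a list
    of (unit_length, copy_count) long intragenomic repeats; ``plasmids`` a
    list of (length, copy_number) extrachromosomal circular replicons whose
    copy number multiplies their read-sampling weight.
    """

    name: str
    length: int
    gc_fraction: float = 0.5
    circular: bool = False
    abundance_weight: float = 1.0
    repeats: Sequence[tuple[int, int]] = ()
    plasmids: Sequence[tuple[int, int]] = ()
    marker_count: int = 20
    rrna_operons: int = 1
    trna_count: int = 18
    cassette_divergence: float = 0.0

    def __post_init__(self) -> None:
        if not 0.25 <= self.gc_fraction <= 0.75:
            raise ValueError("gc_fraction must be in [0.25, 0.75]")
        if self.abundance_weight <= 0:
            raise ValueError("abundance_weight must be positive")


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _kmers.decode(rng.choice(4, size=length, p=p))


def _random_gene(rng: np.random.Generator, length_nt: int) -> str:
    """A random ORF-structured gene: ATG + non-stop codons + TAA."""
    if length_nt % 3 or length_nt < 9:
        raise ValueError("gene length must be a multiple of 3, >= 9")
    n_codons = length_nt // 3 - 2
    body = "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons))
    return "ATG" + body + "TAA"


def _nt_diffs(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _diverge_gene(rng: np.random.Generator, gene: str, divergence: float) -> str:
    """A genome-specific homolog at close to the requested nt divergence.

    Interior codons are replaced by random non-stop codons until the
    nucleotide distance reaches the target, so the reading frame, start and
    stop stay intact and no internal stop appears.
    """
    if divergence <= 0:
        return gene
    target = int(round(len(gene) * divergence))
    codons = [gene[i : i + 3] for i in range(0, len(gene), 3)]
    for _ in range(20 * len(codons)):
        if _nt_diffs("".join(codons), gene) >= target:
            break
        i = int(rng.integers(1, len(codons) - 1))
        codons[i] = _CODONS[int(rng.integers(0, len(_CODONS)))]
    return "".join(codons)


def _diverge_seq(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """A cassette variant with exactly round(len x divergence) substitutions."""
    if divergence <= 0:
        return seq
    n = int(round(len(seq) * divergence))
    codes = _kmers.encode(seq).copy()
    pos = rng.choice(codes.size, size=min(n, codes.size), replace=False)
    codes[pos] = (codes[pos] + rng.integers(1, 4, pos.size)) % 4
    return _kmers.decode(codes)


@dataclasses.dataclass(slots=True)
class MarkerLibrary:
    """The synthetic stand-in for a universal single-copy marker set.

    ``markers`` are ORF-structured genes expected exactly once per genome;
    ``rrna_cassettes`` hold the 5S/16S/23S sequences planted as one operon;
    ``trna_cassette`` is the (short) tRNA stand-in; ``function_labels`` maps
    planted gene ids to function strings for gene-inventory comparisons.
    """

    markers: dict[str, str]
    rrna_cassettes: dict[str, str]
    trna_cassette: str
    function_labels: dict[str, str]

    def __post_init__(self) -> None:
        seqs = list(self.markers.values()) + list(self.rrna_cassettes.values())
        if len(set(seqs + [self.trna_cassette])) != len(seqs) + 1:
            raise ValueError("cassette sequences must be pairwise distinct")
        for s in seqs:
            if len(s) < 100:
                raise ValueError("markers and rRNA cassettes must be >= 100 bp")
        if len(self.trna_cassette) < 70:
            raise ValueError("tRNA cassette must be >= 70 bp")

    @classmethod
    def generate(
        cls,
        n_markers: int = 20,
        marker_len: int = 300,
        seed: int = 0,
        rrna_lens: tuple[int, int, int] = (120, 1500, 2900),
        trna_len: int = 75,
    ) -> "MarkerLibrary":
        rng = np.random.default_rng(seed)
        markers = {
            f"marker_{i:02d}": _random_gene(rng, marker_len) for i in range(n_markers)
        }
        rrna = {
            "5S": _random_seq(rng, rrna_lens[0]),
            "16S": _random_seq(rng, rrna_lens[1]),
            "23S": _random_seq(rng, rrna_lens[2]),
        }
        trna = _random_seq(rng, trna_len)
        labels = {name: f"function_{name}" for name in markers}
        return cls(markers, rrna, trna, labels)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def to_yaml(self, path) -> None:
        import yaml

        data = {
            "markers": self.markers,
            "rrna_cassettes": self.rrna_cassettes,
            "trna_cassette": self.trna_cassette,
            "function_labels": self.function_labels,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "MarkerLibrary":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            markers=data["markers"],
            rrna_cassettes=data["rrna_cassettes"],
            trna_cassette=data["trna_cassette"],
            function_labels=data.get("function_labels", {}),
        )

    def protein_annotator(self) -> dict[str, tuple[str, str]]:
        """Map from planted-gene protein string to (gene id, function)."""
        from Bio.Seq import Seq

        out = {}
        for name, gene in self.markers.items():
            prot = str(Seq(gene[:-3]).translate())
            out[prot] = (name, self.function_labels[name])
        return out


@dataclasses.dataclass(slots=True)
class Genome:
    spec: GenomeSpec
    chromosome: SequenceRecord
    plasmids: list[SequenceRecord]
    features: pd.DataFrame  # feature, kind, start, end, copy

    @property
    def replicons(self) -> list[SequenceRecord]:
        return [self.chromosome] + list(self.plasmids)


@dataclasses.dataclass(slots=True)
class Community:
    genomes: list[Genome]
    library: MarkerLibrary

    def genome(self, name: str) -> Genome:
        for g in self.genomes:
            if g.spec.name == name:
                return g
        raise KeyError(name)

    def protein_annotator(self) -> dict[str, tuple[str, str]]:
        """protein string -> (gene id, function) over all planted homologs."""
        out = dict(self.library.protein_annotator())
        for g in self.genomes:
            markers = g.features[g.features.kind == "marker"]
            for _, row in markers.iterrows():
                out[row.protein] = (row.feature, self.library.function_labels[row.feature])
        return out

    def replicon_weights(self) -> list[tuple[SequenceRecord, str, float]]:
        """(replicon, genome name, base-fraction weight) for read sampling.

        Genome weights are the normalised abundance weights (relative DNA
        fractions); within a genome, replicons weigh length x copy number.
        """
        total_w = sum(g.spec.abundance_weight for g in self.genomes)
        out = []
        for g in self.genomes:
            reps = [(g.chromosome, 1)]
            for rec, (_, cn) in zip(g.plasmids, g.spec.plasmids):
                reps.append((rec, cn))
            mass = sum(len(r) * cn for r, cn in reps)
            for rec, cn in reps:
                w = (g.spec.abundance_weight / total_w) * (len(rec) * cn / mass)
                out.append((rec, g.spec.name, w))
        return out


def _place_elements(
    rng: np.random.Generator,
    genome_len: int,
    elements: list[tuple[str, str, str, int]],
    max_retries: int = 500,
) -> list[tuple[str, str, str, int, int]]:
    """Choose non-overlapping start positions for (name, kind, seq, copy)."""
    placed: list[tuple[int, int]] = []
    out = []
    for name, kind, seq, copy in sorted(
        elements, key=lambda e: (-len(e[2]), e[0], e[3])
    ):
        ln = len(seq)
        if ln >= genome_len:
            raise GenerationError(f"element {name} longer than genome")
        for _ in range(max_retries):
            start = int(rng.integers(0, genome_len - ln))
            if all(start + ln <= s or start >= e for s, e in placed):
                placed.append((start, start + ln))
                out.append((name, kind, seq, copy, start))
                break
        else:
            raise GenerationError(
                f"could not place element {name!r} after {max_retries} retries"
            )
    out.sort(key=lambda x: x[4])
    return out


def generate_genome(
    spec: GenomeSpec, lib: MarkerLibrary, seed: int = 0
) -> tuple[SequenceRecord, list[SequenceRecord], pd.DataFrame]:
    """Build one genome with planted markers, cassettes, repeats, plasmids.

    Marker genes are planted with an in-frame stop immediately upstream so
    the ORF caller recovers exactly the planted gene. Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    if spec.marker_count > lib.n_markers:
        raise ValueError("marker_count exceeds library size")

    # cassettes are planted verbatim by default; with cassette_divergence > 0
    # each genome gets its own homolog (detectable by alignment, but with a
    # diverged k-mer set, as between real community members)
    div = spec.cassette_divergence
    elements: list[tuple[str, str, str, int]] = []
    gene_variants: dict[str, str] = {}
    marker_names = sorted(lib.markers)[: spec.marker_count]
    for name in marker_names:
        variant = _diverge_gene(rng, lib.markers[name], div)
        gene_variants[name] = variant
        elements.append((name, "marker", "TAA" + variant, 0))
    operon = "".join(
        _diverge_seq(rng, lib.rrna_cassettes[g], div) for g in ("5S", "16S", "23S")
    )
    for i in range(spec.rrna_operons):
        elements.append(("rrna_operon", "rrna", operon, i))
    trna_variant = _diverge_seq(rng, lib.trna_cassette, div)
    for i in range(spec.trna_count):
        elements.append(("trna", "trna", trna_variant, i))
    for r, (unit_len, copies) in enumerate(spec.repeats):
        unit = _random_seq(rng, unit_len, spec.gc_fraction)
        for c in range(copies):
            elements.append((f"repeat_{r}", "repeat", unit, c))

    if sum(len(e[2]) for e in elements) >= spec.length:
        raise GenerationError("planted elements exceed genome length")

    placements = _place_elements(rng, spec.length, elements)
    codes = rng.choice(
        4,
        size=spec.length,
        p=[
            (1 - spec.gc_fraction) / 2,
            spec.gc_fraction / 2,
            spec.gc_fraction / 2,
            (1 - spec.gc_fraction) / 2,
        ],
    ).astype(np.int8)
    from Bio.Seq import Seq

    rows = []
    for name, kind, seq, copy, start in placements:
        codes[start : start + len(seq)] = _kmers.encode(seq)
        protein = (
            str(Seq(gene_variants[name][:-3]).translate()) if kind == "marker" else ""
        )
        rows.append(
            {
                "feature": name, "kind": kind, "start": start,
                "end": start + len(seq), "copy": copy, "protein": protein,
            }
        )
    chromosome = SequenceRecord(
        id=spec.name, sequence=_kmers.decode(codes), circular=spec.circular
    )
    plasmids = []
    for i, (plen, _cn) in enumerate(spec.plasmids):
        plasmids.append(
            SequenceRecord(
                id=f"{spec.name}_p{i + 1}",
                sequence=_random_seq(rng, plen, spec.gc_fraction),
                circular=True,
            )
        )
    features = pd.DataFrame(
        rows, columns=["feature", "kind", "start", "end", "copy", "protein"]
    )
    return chromosome, plasmids, features


def community_from_config(config: dict, seed: int = 0) -> Community:
    """Build a community from a structured (YAML-style) configuration.

    Expected shape: a ``library`` block with MarkerLibrary.generate keyword
    arguments and a ``genomes`` list of GenomeSpec fields (repeats and
    plasmids as [length, count] pairs).
    """
    lib_kwargs = dict(config.get("library", {}))
    lib_kwargs.setdefault("seed", seed)
    lib = MarkerLibrary.generate(**lib_kwargs)
    specs = []
    for g in config["genomes"]:
        g = dict(g)
        g["repeats"] = [tuple(r) for r in g.get("repeats", [])]
        g["plasmids"] = [tuple(p) for p in g.get("plasmids", [])]
        specs.append(GenomeSpec(**g))
    return build_community(specs, lib, seed=seed)


def build_community(
    specs: Sequence[GenomeSpec], lib: Optional[MarkerLibrary] = None, seed: int = 0
) -> Community:
    lib = lib or MarkerLibrary.generate(seed=seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(specs))
    genomes = []
    for spec, child in zip(specs, child_seeds):
        chrom, plasmids, feats = generate_genome(spec, lib, seed=int(child) % (2**31))
        genomes.append(Genome(spec, chrom, plasmids, feats))
    return Community(genomes, lib)


def _rows_to_strings(mat: np.ndarray) -> list[str]:
    """Decode an (n, L) base-code matrix into n strings."""
    n, ln = mat.shape
    raw = _DECODE[mat].tobytes()
    return [raw[i * ln : (i + 1) * ln].decode("ascii") for i in range(n)]


def simulate_short_reads(
    community: Community,
    total_bp: float,
    read_len: int = 150,
    insert_mean: int = 350,
    insert_sd: float = 35.0,
    sub_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Paired-end short reads with a Gaussian insert-size distribution.

    Replicons are sampled by abundance weight (see
    :meth:`Community.replicon_weights`); circular replicons are sampled
    across the origin; substitution errors only. Returns the pairs and a
    per-mate truth table.
    """
    if total_bp <= 0 or read_len >= insert_mean:
        raise ValueError("need total_bp > 0 and read_len < insert_mean")
    rng = np.random.default_rng(seed)
    reps = community.replicon_weights()
    usable = []
    for rec, gname, w in reps:
        if not rec.circular and len(rec) < insert_mean:
            warnings.warn(
                f"replicon {rec.id} shorter than the insert size; skipped", stacklevel=2
            )
            continue
        usable.append((rec, gname, w))
    wsum = sum(w for _, _, w in usable)
    probs = np.array([w / wsum for _, _, w in usable])
    n_pairs = int(round(total_bp / (2 * read_len)))
    counts = rng.multinomial(n_pairs, probs)

    pairs: list[ReadPair] = []
    truth_rows = {
        "read_id": [], "pair_id": [], "genome": [], "replicon": [],
        "start": [], "strand": [],
    }
    serial = 0
    for (rec, gname, _), n in zip(usable, counts):
        if n == 0:
            continue
        L = len(rec)
        codes = _kmers.encode(rec.sequence)
        max_ins = int(insert_mean + 6 * insert_sd)
        if rec.circular:
            ext = np.concatenate([codes, codes[: min(max_ins, L)]])
            starts = rng.integers(0, L, size=n)
            inserts = np.clip(
                np.rint(rng.normal(insert_mean, insert_sd, size=n)).astype(np.int64),
                2 * read_len,
                min(max_ins, L),
            )
        else:
            ext = codes
            inserts = np.clip(
                np.rint(rng.normal(insert_mean, insert_sd, size=n)).astype(np.int64),
                2 * read_len,
                min(max_ins, L),
            )
            starts = (rng.random(n) * (L - inserts + 1)).astype(np.int64)
        offs = np.arange(read_len)
        m1 = ext[starts[:, None] + offs]
        m2_start = starts + inserts - read_len
        m2 = ext[m2_start[:, None] + offs]
        m2 = 3 - m2[:, ::-1]  # reverse strand mate
        if sub_error_rate > 0:
            for mat in (m1, m2):
                mask = rng.random(mat.shape) < sub_error_rate
                shift = rng.integers(1, 4, size=int(mask.sum()))
                mat[mask] = (mat[mask] + shift) % 4
        flip = rng.random(n) < 0.5
        # flipping reads the fragment from the opposite strand: swap mates
        m1f = m1.copy()
        m1[flip] = m2[flip]
        m2[flip] = m1f[flip]
        s1 = _rows_to_strings(m1)
        s2 = _rows_to_strings(m2)
        p1 = np.where(flip, (m2_start % L), (starts % L))
        p2 = np.where(flip, (starts % L), (m2_start % L))
        st1 = np.where(flip, "-", "+")
        st2 = np.where(flip, "+", "-")
        for i in range(n):
            pid = f"sr_{serial:08d}"
            serial += 1
            pairs.append(
                ReadPair(
                    pair_id=pid,
                    mate1=SequenceRecord(id=f"{pid}/1", sequence=s1[i]),
                    mate2=SequenceRecord(id=f"{pid}/2", sequence=s2[i]),
                )
            )
            truth_rows["read_id"] += [f"{pid}/1", f"{pid}/2"]
            truth_rows["pair_id"] += [pid, pid]
            truth_rows["genome"] += [gname, gname]
            truth_rows["replicon"] += [rec.id, rec.id]
            truth_rows["start"] += [int(p1[i]), int(p2[i])]
            truth_rows["strand"] += [str(st1[i]), str(st2[i])]
    truth = pd.DataFrame(truth_rows)
    return pairs, truth


def simulate_long_reads(
    community: Community,
    total_bp: float,
    length_n50_target: int = 23000,
    min_len: int = 1000,
    error_rate: float = 0.10,
    seed: int = 0,
    length_sigma: float = 0.55,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Nanopore-style long reads: log-normal lengths, 60/20/20 sub/ins/del.

    Lengths are calibrated so the length-weighted median (N50) of the
    retained (>= min_len) set sits near the target; reads shorter than
    min_len are discarded before output.
    """
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    rng = np.random.default_rng(seed)
    mu = np.log(length_n50_target) - length_sigma**2

    lengths: list[int] = []
    cum = 0
    while cum < total_bp:
        draw = np.exp(rng.normal(mu, length_sigma, size=256))
        for ln in draw:
            ln = int(round(ln))
            if ln < min_len:
                continue
            lengths.append(ln)
            cum += ln
            if cum >= total_bp:
                break
    reps = community.replicon_weights()
    probs = np.array([w for _, _, w in reps])
    probs = probs / probs.sum()
    choice = rng.choice(len(reps), size=len(lengths), p=probs)

    reads: list[SequenceRecord] = []
    truth_rows = {"read_id": [], "genome": [], "replicon": [], "start": [], "strand": []}
    enc_cache: dict[str, np.ndarray] = {}
    for i, (ln, ci) in enumerate(zip(lengths, choice)):
        rec, gname, _ = reps[ci]
        L = len(rec)
        if ln > L:
            ln = L
        if rec.id not in enc_cache:
            enc_cache[rec.id] = _kmers.encode(rec.sequence)
        codes = enc_cache[rec.id]
        if rec.circular:
            start = int(rng.integers(0, L))
            idx = (start + np.arange(ln)) % L
            frag = codes[idx]
        else:
            start = int(rng.integers(0, L - ln + 1))
            frag = codes[start : start + ln].copy()
        strand = "+"
        if rng.random() < 0.5:
            frag = 3 - frag[::-1]
            strand = "-"
        if error_rate > 0:
            n_ev = rng.binomial(frag.size, error_rate)
            if n_ev:
                kinds = rng.choice(3, size=n_ev, p=[0.6, 0.2, 0.2])  # sub/ins/del
                pos = rng.integers(0, frag.size, size=n_ev)
                sub_pos = pos[kinds == 0]
                frag[sub_pos] = (frag[sub_pos] + rng.integers(1, 4, sub_pos.size)) % 4
                ins_pos = np.sort(pos[kinds == 1])
                del_pos = np.unique(pos[kinds == 2])
                if del_pos.size:
                    frag = np.delete(frag, del_pos)
                if ins_pos.size:
                    ins_pos = np.minimum(ins_pos, frag.size)
                    frag = np.insert(frag, ins_pos, rng.integers(0, 4, ins_pos.size))
        if frag.size < min_len:
            continue
        rid = f"lr_{i:07d}"
        reads.append(SequenceRecord(id=rid, sequence=_kmers.decode(frag)))
        truth_rows["read_id"].append(rid)
        truth_rows["genome"].append(gname)
        truth_rows["replicon"].append(rec.id)
        truth_rows["start"].append(start)
        truth_rows["strand"].append(strand)
    return reads, pd.DataFrame(truth_rows)


def rare_recovery_community(seed: int = 1) -> Community:
    """The six-genome rare-recovery benchmark community.

    ~2.8 Mbp of genomes at base abundances 40/25/15/10/7/3 %, GC spread wide
    enough for composition binning, a 13-copy >2.1 kbp repeat on the dominant
    (circular) genome, and one multi-copy plasmid. Read pools and cycle
    sizes for the benchmark live in :mod:`ihakit.engine`.
    """
    div = 0.10  # cross-genome homolog divergence, typical of distinct taxa
    specs = [
        GenomeSpec("g1_dom", 800_000, gc_fraction=0.45, circular=True,
                   abundance_weight=0.40, repeats=[(2100, 13)], plasmids=[(30_000, 2)],
                   cassette_divergence=div),
        GenomeSpec("g2", 650_000, gc_fraction=0.28, abundance_weight=0.25,
                   cassette_divergence=div),
        GenomeSpec("g3", 500_000, gc_fraction=0.62, abundance_weight=0.15,
                   cassette_divergence=div),
        GenomeSpec("g4", 400_000, gc_fraction=0.36, circular=True, abundance_weight=0.10,
                   cassette_divergence=div),
        GenomeSpec("g5", 300_000, gc_fraction=0.52, abundance_weight=0.07,
                   cassette_divergence=div),
        GenomeSpec("g6_rare", 150_000, gc_fraction=0.72, circular=True,
                   abundance_weight=0.03, cassette_divergence=div),
    ]
    return build_community(specs, seed=seed)
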