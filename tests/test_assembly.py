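import numpy as np
import pytest

from ihakit import _kmers as K
from ihakit.assembly import (
    Bin,
    Contig,
    external_assembler,
    toy_bin,
    toy_hybrid_assemble,
    refine_bins,
)
from ihakit.formats import SequenceRecord, write_fasta
from ihakit.quality import QualityAssessment, classify_tier
from ihakit.synthetic import (
    GenomeSpec,
    build_community,
    simulate_long_reads,
    simulate_short_reads,
)


@pytest.fixture(scope="module")
def plain_circular(lib):
    """50 kbp circular genome, no repeats >= k, with 30x error-free reads."""
    spec = GenomeSpec("c1", 50_000, circular=True, marker_count=0,
                      rrna_operons=0, trna_count=0)
    comm = build_community([spec], lib, seed=5)
    pairs, _ = simulate_short_reads(comm, 50_000 * 30, seed=6)
    return comm.genomes[0].chromosome.sequence, pairs


@pytest.fixture(scope="module")
def repeat_genome(lib):
    """Same size genome with a 5 kbp repeat x2 (tangles without long reads)."""
    spec = GenomeSpec("c2", 50_000, circular=True, marker_count=0,
                      rrna_operons=0, trna_count=0, repeats=[(5000, 2)])
    comm = build_community([spec], lib, seed=7)
    pairs, _ = simulate_short_reads(comm, 50_000 * 30, seed=8)
    return comm, pairs


class TestToyAssembler:
    def test_clean_circular_genome_reconstructed_exactly(self, plain_circular):
        genome, pairs = plain_circular
        contigs = toy_hybrid_assemble(pairs, min_depth=3)
        assert len(contigs) == 1
        assert contigs[0].record.circular
        assert K.canonical_circular(contigs[0].record.sequence) == K.canonical_circular(genome)

    def test_repeat_tangles_without_long_reads(self, repeat_genome):
        _, pairs = repeat_genome
        contigs = toy_hybrid_assemble(pairs, min_depth=3)
        assert len(contigs) >= 2

    def test_long_reads_bridge_the_repeat(self, repeat_genome):
        comm, pairs = repeat_genome
        lrs, _ = simulate_long_reads(comm, 50_000 * 20, length_n50_target=15_000,
                                     error_rate=0.0, seed=9)
        contigs = toy_hybrid_assemble(pairs, lrs, min_depth=3)
        assert len(contigs) == 1
        genome = comm.genomes[0].chromosome.sequence
        assert K.canonical_circular(contigs[0].record.sequence) == K.canonical_circular(genome)

    def test_no_invented_kmers(self, repeat_genome):
        comm, pairs = repeat_genome
        lrs, _ = simulate_long_reads(comm, 50_000 * 20, length_n50_target=15_000,
                                     error_rate=0.0, seed=10)
        contigs = toy_hybrid_assemble(pairs, lrs, min_depth=3)
        read_words = set()
        for p in pairs:
            for s in (p.mate1.sequence, p.mate2.sequence):
                w = K.kmer_words(s, 31)
                read_words.update(K.canonical_words(w, 31).tolist())
        for c in contigs:
            seq = c.record.sequence
            if c.record.circular:
                seq = seq + seq[:30]
            w = K.canonical_words(K.kmer_words(seq, 31), 31)
            assert set(w.tolist()) <= read_words

    def test_min_contig_length_filter(self, plain_circular):
        _, pairs = plain_circular
        contigs = toy_hybrid_assemble(pairs, min_depth=3, min_contig_len=1000)
        assert all(len(c) >= 1000 for c in contigs)

    @pytest.mark.parametrize("k", [30, 13])
    def test_bad_k_rejected(self, plain_circular, k):
        _, pairs = plain_circular
        with pytest.raises(ValueError):
            toy_hybrid_assemble(pairs, k=k)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            toy_hybrid_assemble([])


def _fragment(seq, n_pieces, seed, prefix):
    rng = np.random.default_rng(seed)
    cuts = sorted(int(c) for c in rng.integers(5000, len(seq) - 5000, n_pieces - 1))
    bounds = [0] + cuts + [len(seq)]
    return [
        SequenceRecord(id=f"{prefix}_{i}", sequence=seq[s:e])
        for i, (s, e) in enumerate(zip(bounds, bounds[1:]))
        if e - s >= 1000
    ]


class TestToyBin:
    def test_two_genomes_separate_and_pure(self, lib):
        specs = [
            GenomeSpec("low", 60_000, gc_fraction=0.35),
            GenomeSpec("high", 60_000, gc_fraction=0.65),
        ]
        comm = build_community(specs, lib, seed=20)
        contigs = []
        for g, depth in zip(comm.genomes, (50.0, 5.0)):
            for rec in _fragment(g.chromosome.sequence, 5, 21, g.spec.name):
                contigs.append(Contig(rec, mean_sr_depth=depth))
        bins = toy_bin(contigs)
        assert len(bins) == 2
        for b in bins:
            sources = {c.record.id.rsplit("_", 1)[0] for c in b.contigs}
            assert len(sources) == 1

    def test_single_contig_single_bin(self, random_dna):
        contigs = [Contig(SequenceRecord(id="c", sequence=random_dna(5000)), 10.0)]
        assert len(toy_bin(contigs)) == 1

    def test_deterministic(self, lib, random_dna):
        contigs = [
            Contig(SequenceRecord(id=f"c{i}", sequence=random_dna(4000, seed=i)), 10.0)
            for i in range(8)
        ]
        a = toy_bin(contigs, seed=1)
        b = toy_bin(contigs, seed=1)
        assert [[c.record.id for c in x.contigs] for x in a] == [
            [c.record.id for c in x.contigs] for x in b
        ]


class _StubAssessor:
    """Maps bin_id to a prebuilt assessment; refine_bins only needs the call."""

    def __init__(self, table):
        self.table = table

    def __call__(self, b):
        comp, cont = self.table[b.bin_id]
        return classify_tier(comp, cont, n_contigs=len(b.contigs),
                             circular_single=False, rrna_counts={}, trna_count=0)


class TestRefineBins:
    def _bin(self, bin_id, n=2):
        recs = [
            SequenceRecord(id=f"{bin_id}_c{i}", sequence="ACGT" * 300) for i in range(n)
        ]
        return Bin(bin_id, [Contig(r, 10.0) for r in recs])

    def test_low_completeness_dropped(self):
        bins = [self._bin("a")]
        out = refine_bins(bins, _StubAssessor({"a": (69.9, 0.0)}))
        assert out == []

    def test_contamination_at_threshold_dropped(self):
        bins = [self._bin("a")]
        out = refine_bins(bins, _StubAssessor({"a": (95.0, 10.0)}))
        assert out == []

    def test_clean_bins_pass_unchanged(self):
        bins = [self._bin("a"), self._bin("b")]
        out = refine_bins(
            bins, _StubAssessor({"a": (95.0, 1.0), "b": (80.0, 9.9)})
        )
        assert [b.bin_id for b in out] == ["a", "b"]
        assert [len(b.contigs) for b in out] == [2, 2]

    def test_duplicate_marker_contig_unbinned(self, lib):
        from ihakit.quality import MarkerQualityAssessor

        name = sorted(lib.markers)[0]
        marker = lib.markers[name]
        spec = GenomeSpec("g", 60_000)
        comm = build_community([spec], lib, seed=30)
        big = comm.genomes[0].chromosome
        # a small contig duplicating one marker already on the big contig
        dup = SequenceRecord(id="dup", sequence="ACGT" * 200 + "TAA" + marker + "GGCC" * 200)
        b = Bin("b1", [Contig(big, 10.0), Contig(dup, 10.0)])
        kept, unbinned = refine_bins(
            [b], MarkerQualityAssessor(lib), return_unbinned=True
        )
        assert len(kept) == 1
        assert [c.record.id for c in unbinned] == ["dup"]
        assert all(c.record.id != "dup" for c in kept[0].contigs)


def test_external_assembler_adapter_matches_builtin(tmp_path, plain_circular):
    genome, pairs = plain_circular
    builtin = toy_hybrid_assemble(pairs, min_depth=3)
    fa = tmp_path / "contigs.fa"
    write_fasta([c.record for c in builtin], fa)
    adapter = external_assembler(str(fa))
    external = adapter(pairs, [], seed=0)
    assert [c.record.sequence for c in external] == [c.record.sequence for c in builtin]
    # depth re-estimated from the same reads agrees closely
    assert external[0].mean_sr_depth == pytest.approx(builtin[0].mean_sr_depth, rel=0.1)
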