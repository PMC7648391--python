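import numpy as np
import pytest

from ihakit import _kmers as K
from ihakit.evaluate import (
    AlignedBlock,
    agf_and_purity,
    align_to_reference,
    count_misassemblies,
    coverage_correlation,
    evaluate_mag,
    expected_coverage,
    gene_recovery,
    nga50,
)
from ihakit.formats import SequenceRecord
from ihakit.synthetic import GenomeSpec, build_community, simulate_short_reads


@pytest.fixture(scope="module")
def reference(random_dna):
    return SequenceRecord(id="ref", sequence=random_dna(100_000, seed=7))


def sub(seq, pos):
    out = list(seq)
    out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


class TestAligner:
    def test_exact_substring_single_full_block(self, reference):
        c = SequenceRecord(id="c", sequence=reference.sequence[1000:41000])
        (b,) = align_to_reference([c], reference)
        assert b.identity == 1.0
        assert (b.qstart, b.qend) == (0, 40000)
        assert (b.rstart, b.rend) == (1000, 41000)

    def test_three_substitutions_counted(self, reference):
        seq = reference.sequence[20000:30000]
        for p in (2500, 5000, 7500):
            seq = sub(seq, p)
        (b,) = align_to_reference([SequenceRecord(id="c", sequence=seq)], reference)
        assert b.n_mismatches == 3
        assert b.identity == pytest.approx(0.9997, abs=1e-4)
        m = evaluate_mag([SequenceRecord(id="c", sequence=seq)], reference)
        assert m["mismatches_per_mbp"] == pytest.approx(300.0, rel=0.01)

    def test_reverse_complement_minus_strand(self, reference):
        c = SequenceRecord(id="c", sequence=K.revcomp(reference.sequence[5000:25000]))
        (b,) = align_to_reference([c], reference)
        assert b.strand == "-" and b.identity == 1.0
        assert (b.rstart, b.rend) == (5000, 25000)

    def test_indels_counted(self, reference):
        seq = list(reference.sequence[10000:25000])
        seq.insert(7000, "A")
        del seq[2000]
        c = SequenceRecord(id="c", sequence="".join(seq))
        (b,) = align_to_reference([c], reference, anchor_stride=25)
        assert b.n_ins == 1 and b.n_del == 1


class TestNga50:
    def _block(self, rs, re_):
        return AlignedBlock("c", 0, 1 + re_ - rs, "r", rs, re_, "+", re_ - rs, 0, 0, 0)

    def test_single_full_block(self):
        assert nga50([self._block(0, 70_000)], 70_000) == 70_000

    def test_60_30_10_split(self):
        blocks = [self._block(0, 60_000), self._block(60_000, 90_000),
                  self._block(90_000, 100_000)]
        assert nga50(blocks, 100_000) == 60_000

    def test_below_half_coverage_undefined(self):
        assert nga50([self._block(0, 40_000)], 100_000) == 0

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            ref_len = int(rng.integers(50_000, 200_000))
            n = int(rng.integers(1, 12))
            spans = sorted(int(x) for x in rng.integers(100, 30_000, n))
            blocks = []
            pos = 0
            for s in spans:
                if pos + s > ref_len:
                    break
                blocks.append(self._block(pos, pos + s))
                pos += s + int(rng.integers(0, 500))
            # oracle: sort fragment lengths descending, cumulate to half
            lens = sorted((b.rend - b.rstart for b in blocks), reverse=True)
            cum, expect = 0, 0
            for ln in lens:
                cum += ln
                if cum >= 0.5 * ref_len:
                    expect = ln
                    break
            assert nga50(blocks, ref_len) == expect

    def test_nga50_never_exceeds_n50_of_same_contigs(self, reference):
        # breaking at misassemblies can only shorten fragments
        from ihakit.evaluate import contig_n50

        piece1 = reference.sequence[0:30_000]
        piece2 = reference.sequence[60_000:75_000]
        fused = SequenceRecord(id="f", sequence=piece1 + piece2)
        blocks = align_to_reference([fused], reference)
        assert nga50(blocks, len(reference)) <= contig_n50([len(fused)])


class TestAgfPurity:
    def test_perfect_reconstruction(self, reference):
        c = SequenceRecord(id="c", sequence=reference.sequence)
        blocks = align_to_reference([c], reference)
        agf, purity = agf_and_purity(blocks, [c], len(reference))
        assert agf == pytest.approx(100.0)
        assert purity == pytest.approx(1.0)

    def test_unalignable_insert_lowers_purity(self, reference, random_dna):
        insert = random_dna(10_000, seed=77)
        seq = reference.sequence[:45_000] + insert + reference.sequence[45_000:90_000]
        c = SequenceRecord(id="c", sequence=seq)
        blocks = align_to_reference([c], reference)
        agf, purity = agf_and_purity(blocks, [c], len(reference))
        assert purity == pytest.approx(0.9, abs=0.005)
        assert agf == pytest.approx(90.0, abs=0.5)

    def test_overlapping_blocks_count_reference_once(self):
        blocks = [
            AlignedBlock("a", 0, 5000, "r", 0, 5000, "+", 5000, 0, 0, 0),
            AlignedBlock("b", 0, 5000, "r", 0, 5000, "+", 5000, 0, 0, 0),
        ]
        contigs = [SequenceRecord(id=x, sequence="A" * 5000) for x in ("a", "b")]
        agf, _ = agf_and_purity(blocks, contigs, 10_000)
        assert agf == pytest.approx(50.0)

    def test_invariant_to_contig_order_and_strand(self, reference):
        c1 = SequenceRecord(id="c1", sequence=reference.sequence[:30_000])
        c2 = SequenceRecord(id="c2", sequence=reference.sequence[50_000:80_000])
        c2_rc = SequenceRecord(id="c2", sequence=K.revcomp(c2.sequence))
        for contigs in ([c1, c2], [c2, c1], [c1, c2_rc]):
            blocks = align_to_reference(contigs, reference)
            agf, purity = agf_and_purity(blocks, contigs, len(reference))
            assert agf == pytest.approx(60.0, abs=0.1)
            assert purity == pytest.approx(1.0, abs=1e-6)


class TestMisassemblies:
    def test_colinear_small_gap_is_clean(self, reference):
        seq = reference.sequence[0:20_000] + reference.sequence[20_200:40_000]
        blocks = align_to_reference([SequenceRecord(id="c", sequence=seq)], reference)
        assert count_misassemblies(blocks) == 0

    def test_fusion_of_two_references_is_one_event(self, reference, random_dna):
        other = SequenceRecord(id="ref2", sequence=random_dna(50_000, seed=8))
        fused = SequenceRecord(
            id="c", sequence=reference.sequence[:20_000] + other.sequence[:20_000]
        )
        blocks = align_to_reference([fused], [reference, other])
        assert count_misassemblies(blocks) == 1

    def test_inversion_is_two_events(self, reference):
        seq = (
            reference.sequence[:30_000]
            + K.revcomp(reference.sequence[30_000:40_000])
            + reference.sequence[40_000:60_000]
        )
        blocks = align_to_reference([SequenceRecord(id="c", sequence=seq)], reference)
        assert count_misassemblies(blocks) == 2

    def test_long_range_jump_is_one_event(self, reference):
        seq = reference.sequence[0:20_000] + reference.sequence[50_000:70_000]
        blocks = align_to_reference([SequenceRecord(id="c", sequence=seq)], reference)
        assert count_misassemblies(blocks) == 1


class TestGeneRecovery:
    def test_verbatim_mag_recovers_everything(self, lib):
        comm = build_community([GenomeSpec("g", 60_000)], lib, seed=60)
        g = comm.genomes[0]
        ref_proteins = [p for p in g.features.protein if p]
        assert len(ref_proteins) == 20
        assert gene_recovery(ref_proteins, [g.chromosome]) == 100.0

    def test_missing_genes_scale_linearly(self, lib):
        comm = build_community([GenomeSpec("g", 60_000)], lib, seed=60)
        g = comm.genomes[0]
        ref_proteins = [p for p in g.features.protein if p]
        # delete one marker gene's locus from the MAG
        feats = g.features[g.features.kind == "marker"].sort_values("start")
        row = feats.iloc[0]
        seq = g.chromosome.sequence[: row.start] + g.chromosome.sequence[row.end :]
        mag = SequenceRecord(id="mag", sequence=seq)
        assert gene_recovery(ref_proteins, [mag]) == pytest.approx(95.0)

    def test_single_aa_substitution_not_recovered(self, lib):
        comm = build_community([GenomeSpec("g", 60_000)], lib, seed=60)
        g = comm.genomes[0]
        ref_proteins = [p for p in g.features.protein if p]
        feats = g.features[g.features.kind == "marker"].sort_values("start")
        row = feats.iloc[0]
        # non-synonymous change in codon 5 of that gene (gene starts after TAA guard)
        gene_start = row.start + 3
        pos = gene_start + 3 * 5
        seq = g.chromosome.sequence
        codon = seq[pos : pos + 3]
        new_codon = "GAT" if codon != "GAT" else "CAT"
        mag = SequenceRecord(id="mag", sequence=seq[:pos] + new_codon + seq[pos + 3 :])
        assert gene_recovery(ref_proteins, [mag]) == pytest.approx(95.0)


class TestCoverageCorrelation:
    def test_expected_coverage_formula(self):
        exp = expected_coverage({"a": 0.9, "b": 0.1}, {"a": 1_000_000, "b": 500_000}, 1e9)
        assert exp["a"] == pytest.approx(900.0)
        assert exp["b"] == pytest.approx(200.0)

    def test_perfect_and_inverted_correlations(self):
        rho, ok = coverage_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert ok and rho == pytest.approx(1.0)
        rho, ok = coverage_correlation([4, 3, 2, 1], [10, 20, 30, 40])
        assert ok and rho == pytest.approx(-1.0)

    def test_degenerate_inputs_flagged(self):
        assert coverage_correlation([1, 2], [1, 2])[1] is False
        assert coverage_correlation([5, 5, 5], [1, 2, 3])[1] is False


def test_simulate_assemble_evaluate_is_clean(lib):
    """Zero-error reads from a repeat-free genome reassemble with no
    misassemblies, near-complete aligned fraction and purity."""
    from ihakit.assembly import toy_hybrid_assemble

    spec = GenomeSpec("g", 50_000, circular=True, marker_count=0,
                      rrna_operons=0, trna_count=0)
    comm = build_community([spec], lib, seed=61)
    pairs, _ = simulate_short_reads(comm, 50_000 * 30, seed=62)
    contigs = toy_hybrid_assemble(pairs, min_depth=3)
    ref = comm.genomes[0].chromosome
    records = []
    for c in contigs:
        seq = c.record.sequence
        if c.record.circular:
            # rotate a circular contig to the reference origin so the wrap
            # point does not read as a coordinate jump
            probe = ref.sequence[:31]
            if probe not in seq:
                seq = K.revcomp(seq)
            i = seq.find(probe)
            assert i >= 0
            seq = seq[i:] + seq[:i]
        records.append(SequenceRecord(id=c.record.id, sequence=seq))
    blocks = align_to_reference(records, ref)
    agf, purity = agf_and_purity(blocks, records, len(ref))
    assert count_misassemblies(blocks) == 0
    assert agf >= 99.9
    assert purity >= 0.999
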