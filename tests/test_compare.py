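import numpy as np
import pytest

from ihakit import _kmers as K
from ihakit.assembly import Bin, Contig
from ihakit.compare import (
    classify_genes,
    dereplicate,
    distance,
    find_pairs,
    sketch,
)
from ihakit.formats import SequenceRecord
from ihakit.quality import MagRecord, classify_tier
from ihakit.synthetic import GenomeSpec, build_community


def exact_mash_distance(a: str, b: str, k: int = 21) -> float:
    wa = set(K.canonical_words(K.kmer_words(a, k), k).tolist())
    wb = set(K.canonical_words(K.kmer_words(b, k), k).tolist())
    j = len(wa & wb) / len(wa | wb)
    if j == 0:
        return 1.0
    return -np.log(2 * j / (1 + j)) / k


class TestMinHash:
    def test_identical_sequences_distance_zero(self, random_dna):
        g = random_dna(50_000, seed=1)
        assert distance(sketch(g), sketch(g)) == 0.0

    def test_disjoint_sequences_distance_capped_at_one(self, random_dna):
        a, b = random_dna(30_000, seed=2), random_dna(30_000, seed=3)
        assert distance(sketch(a), sketch(b)) == 1.0

    def test_one_percent_divergence_matches_exact_jaccard(self, random_dna):
        rng = np.random.default_rng(5)
        a = random_dna(100_000, seed=4)
        bl = list(a)
        for i in rng.choice(len(a), size=1000, replace=False):
            bl[i] = "ACGT"[("ACGT".index(bl[i]) + 1) % 4]
        b = "".join(bl)
        d = distance(sketch(a), sketch(b))
        assert abs(d - exact_mash_distance(a, b)) <= 0.005

    def test_sketch_estimate_converges_to_exact_jaccard(self, random_dna):
        """Mean |j_hat - J| over 50 random pairs stays within 2/sqrt(s)."""
        rng = np.random.default_rng(6)
        s = 1000
        errs = []
        for rep in range(50):
            a = random_dna(20_000, seed=100 + rep)
            bl = list(a)
            n_sub = int(rng.integers(50, 400))
            for i in rng.choice(len(a), size=n_sub, replace=False):
                bl[i] = "ACGT"[("ACGT".index(bl[i]) + 1) % 4]
            b = "".join(bl)
            wa = set(K.canonical_words(K.kmer_words(a, 21), 21).tolist())
            wb = set(K.canonical_words(K.kmer_words(b, 21), 21).tolist())
            j_exact = len(wa & wb) / len(wa | wb)
            sa, sb = sketch(a, s=s), sketch(b, s=s)
            union = np.union1d(sa.hashes, sb.hashes)[:s]
            shared = np.intersect1d(sa.hashes, sb.hashes, assume_unique=True)
            j_hat = np.isin(union, shared, assume_unique=True).sum() / union.size
            errs.append(abs(j_hat - j_exact))
        assert np.mean(errs) <= 2 / np.sqrt(s)

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            sketch("ACGTACGT", k=21)

    def test_distance_symmetric(self, random_dna):
        a = sketch(random_dna(20_000, seed=7))
        b = sketch(random_dna(20_000, seed=8))
        assert distance(a, b) == distance(b, a)


class TestFindPairs:
    def test_same_genome_assembled_twice_pairs_at_zero(self, random_dna):
        g = random_dna(50_000, seed=9)
        pairs = find_pairs({"a": sketch(g)}, {"b": sketch(g)})
        assert len(pairs) == 1 and pairs[0][2] == pytest.approx(0.0)

    def test_unrelated_genomes_do_not_pair(self, random_dna):
        a = {"a": sketch(random_dna(30_000, seed=10))}
        b = {"b": sketch(random_dna(30_000, seed=11))}
        assert find_pairs(a, b) == []

    def test_three_vs_three_matches_truth(self, random_dna):
        genomes = {f"g{i}": random_dna(40_000, seed=20 + i) for i in range(3)}
        set_a = {f"hyb_{n}": sketch(s) for n, s in genomes.items()}
        # short-read versions: same genomes with a few substitutions
        rng = np.random.default_rng(12)
        set_b = {}
        for n, s in genomes.items():
            bl = list(s)
            for i in rng.choice(len(s), size=200, replace=False):
                bl[i] = "ACGT"[("ACGT".index(bl[i]) + 1) % 4]
            set_b[f"sr_{n}"] = sketch("".join(bl))
        matches = {(a, b) for a, b, _ in find_pairs(set_a, set_b)}
        assert matches == {(f"hyb_g{i}", f"sr_g{i}") for i in range(3)}


@pytest.fixture(scope="module")
def annotated_genome(lib):
    comm = build_community([GenomeSpec("g", 60_000)], lib, seed=70)
    return comm.genomes[0], comm.protein_annotator()


class TestClassifyGenes:
    def test_identical_mags_all_set_one(self, annotated_genome):
        g, annot = annotated_genome
        pc = classify_genes([g.chromosome], [g.chromosome], annot)
        assert pc.identical_ratio_vs_a == 100.0
        assert pc.identical_ratio_vs_b == 100.0
        assert pc.set_unweighted["I"] == 20
        assert pc.set_unweighted["II"] == pc.set_unweighted["III"] == pc.set_unweighted["IV"] == 0

    def test_extra_copy_in_hybrid_is_set_two(self, annotated_genome):
        g, annot = annotated_genome
        feats = g.features[g.features.kind == "marker"].sort_values("start")
        row = feats.iloc[0]
        dup_locus = g.chromosome.sequence[row.start : row.end]
        hybrid = SequenceRecord(
            id="h", sequence=g.chromosome.sequence + dup_locus + "TAA"
        )
        pc = classify_genes([hybrid], [g.chromosome], annot)
        assert pc.set_unweighted["II"] == 1
        assert pc.set_unweighted["I"] == 19

    def test_gene_only_in_sr_mag_is_set_four(self, annotated_genome):
        g, annot = annotated_genome
        feats = g.features[g.features.kind == "marker"].sort_values("start")
        row = feats.iloc[0]
        seq = g.chromosome.sequence
        hybrid = SequenceRecord(id="h", sequence=seq[: row.start] + seq[row.end :])
        pc = classify_genes([hybrid], [g.chromosome], annot)
        assert pc.set_unweighted["IV"] == 1
        assert pc.set_unweighted["I"] == 19

    def test_weighted_tallies_sum_to_union_gene_count(self, annotated_genome):
        g, annot = annotated_genome
        feats = g.features[g.features.kind == "marker"].sort_values("start")
        row = feats.iloc[0]
        seq = g.chromosome.sequence
        dup_locus = seq[row.start : row.end]
        hybrid = SequenceRecord(id="h", sequence=seq + dup_locus + "TAA")
        sr = SequenceRecord(id="s", sequence=seq[: row.start] + seq[row.end :])
        pc = classify_genes([hybrid], [sr], annot)
        # union over functions of max(copy_a, copy_b): 19 shared + 2-copy dup
        assert sum(pc.set_weighted.values()) == 21
        assert sum(pc.set_unweighted.values()) == 20


def _mag(mag_id, seq, completeness, contamination, n_contigs=1, n50=None):
    recs = [SequenceRecord(id=f"{mag_id}_c", sequence=seq)]
    qa = classify_tier(
        completeness, contamination, n_contigs, False,
        {"5S": 1, "16S": 1, "23S": 1}, 20,
        genome_size=len(seq), n50=n50 if n50 is not None else len(seq),
    )
    return MagRecord(mag_id=mag_id, bin=Bin(mag_id, [Contig(r) for r in recs]), qa=qa)


class TestDereplicate:
    def test_higher_scoring_version_kept(self, random_dna):
        g = random_dna(40_000, seed=30)
        a = _mag("good", g, 97.0, 0.0, n_contigs=1)
        b = _mag("worse", g, 94.0, 0.0, n_contigs=80)
        reps = dereplicate([a, b])
        assert [m.mag_id for m in reps] == ["good"]

    def test_singletons_unchanged(self, random_dna):
        mags = [
            _mag(f"m{i}", random_dna(30_000, seed=40 + i), 95.0, 1.0) for i in range(3)
        ]
        assert len(dereplicate(mags)) == 3

    def test_score_tie_broken_by_contigs_then_n50(self, random_dna):
        g = random_dna(40_000, seed=31)
        a = _mag("a", g, 95.0, 0.0, n_contigs=2, n50=10_000)
        b = _mag("b", g, 95.0, 0.0, n_contigs=2, n50=30_000)
        reps = dereplicate([a, b])
        assert [m.mag_id for m in reps] == ["b"]
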