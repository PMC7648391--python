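import numpy as np
import pytest

from ihakit.assembly import Bin, Contig
from ihakit.formats import SequenceRecord
from ihakit.synthetic import GenomeSpec, MarkerLibrary, build_community


@pytest.fixture(scope="session")
def lib():
    return MarkerLibrary.generate(seed=0)


@pytest.fixture(scope="session")
def random_dna():
    def make(length, seed=0, gc=0.5):
        rng = np.random.default_rng(seed)
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))

    return make


@pytest.fixture(scope="session")
def small_genome(lib):
    """One 120 kbp circular genome with all cassettes planted verbatim."""
    spec = GenomeSpec("sg", 120_000, gc_fraction=0.5, circular=True)
    comm = build_community([spec], lib, seed=11)
    return comm.genomes[0]


@pytest.fixture(scope="session")
def whole_genome_bin(small_genome):
    return Bin("wg", [Contig(small_genome.chromosome, mean_sr_depth=20.0)])


def as_contigs(records, depth=10.0):
    return [Contig(r, mean_sr_depth=depth) for r in records]


@pytest.fixture(scope="session")
def make_record():
    def make(rid, seq, circular=False):
        return SequenceRecord(id=rid, sequence=seq, circular=circular)

    return make
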