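import pytest

from genomekit.model import AssemblySegment, CoordSystem
from genomekit.store import Store


@pytest.fixture
def tiling_store():
    """chromosome "1" (len 100) tiled by contigs A(1..60) and B(61..100)."""
    store = Store()
    store.add_species("example_species")
    chrom_cs = store.add_coord_system(CoordSystem("chromosome",
                                                  version="ASM1", rank=1))
    contig_cs = store.add_coord_system(CoordSystem("contig", rank=2,
                                                   is_sequence_level=True))
    a_seq = ("ACGT" * 15)
    b_seq = ("TTGCA" * 8)
    chrom = store.add_seq_region("1", chrom_cs, 100)
    a = store.add_seq_region("A", contig_cs, 60, sequence=a_seq)
    b = store.add_seq_region("B", contig_cs, 40, sequence=b_seq)
    store.register_assembly([
        AssemblySegment(chrom, 1, 60, a, 1, 60, 1),
        AssemblySegment(chrom, 61, 100, b, 1, 40, 1),
    ])
    return store


@pytest.fixture(scope="session")
def release_pair():
    from genomekit.synthetic import FixtureSpec, make_release_pair
    return make_release_pair(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def exception_fixture():
    from genomekit.synthetic import make_exception_fixture
    return make_exception_fixture(seed=7)
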