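import numpy as np
import pytest

from scstrand import simulate as sim


@pytest.fixture(scope="session")
def small_truth():
    """1 x 100 kb genome with ~100 hetSNPs, no SVs or inversions."""
    return sim.simulate_diploid_genome(
        n_chroms=1, chrom_length=100_000, snp_rate=1e-3, sv_rate=0.0, seed=7
    )


@pytest.fixture(scope="session")
def barcode_tables():
    """Three well-separated (bc1, bc2) pairs keyed by cell id."""
    return sim.random_barcode_tables(3, seed=11)


def make_read(
    chrom="chr1",
    start=0,
    end=None,
    strand="C",
    cell="cellA",
    seq=None,
    cigar=None,
    mapq=60,
    name="",
):
    from scstrand.core import DirectionalRead

    if end is None:
        end = start + (len(seq) if seq and cigar is None else 100)
    return DirectionalRead(
        cell_id=cell,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        mapq=mapq,
        seq=seq,
        cigar=cigar,
        name=name,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
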