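import numpy as np
import pytest

from grmkit.binding import TFBSRecord
from grmkit.io_formats import GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_genes():
    return [
        GeneModel("gA", "chr1", "+", 1_000, 11_000),
        GeneModel("gB", "chr1", "-", 50_000, 60_000),
        GeneModel("gC", "chr1", "+", 100_000, 110_000),
        GeneModel("gD", "chr2", "+", 5_000, 15_000),
    ]


def make_tfbs(tf, gene, diff, start=100, chrom="chr1", idx=(0,), p_b=0.001, **kw):
    """Convenience TFBS with the requested differential binding."""
    make_tfbs._n = getattr(make_tfbs, "_n", 0) + 1
    return TFBSRecord(
        tfbs_id=f"t{make_tfbs._n:05d}",
        tf=tf,
        motif_id=f"M{tf}",
        chrom=chrom,
        start=start,
        end=start + 10,
        score_a=1.0,
        score_b=1.0 + diff,
        p_bound_a=0.5,
        p_bound_b=p_b,
        roc_id="roc_x",
        gene_id=gene,
        **kw,
    )


@pytest.fixture
def tfbs_factory():
    return make_tfbs


@pytest.fixture
def interval_factory():
    def make(chrom, start, end, iid):
        return GenomicInterval(chrom, start, end, iid)

    return make
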