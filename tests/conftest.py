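import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regumap import GeneModel, HaplotypePanel, Variant
from regumap.simulate import load_ss72

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ss72():
    """The packaged 72-variant worked example."""
    return load_ss72()


@pytest.fixture
def toy_gene():
    """Two-exon plus-strand gene with a poly-Gly coding sequence."""
    return GeneModel(
        gene_id="toy",
        chrom="chrT",
        strand="+",
        tx_start=1000,
        tx_end=1999,
        exons=[(1000, 1299), (1700, 1999)],
        cds=[(1000, 1299), (1700, 1999)],
        cds_seq="GGA" * 200,
    )


@pytest.fixture
def toy_gene_minus(toy_gene):
    """Same structure on the minus strand (coding sequence poly-Gly again)."""
    return GeneModel(
        gene_id="toym",
        chrom="chrT",
        strand="-",
        tx_start=toy_gene.tx_start,
        tx_end=toy_gene.tx_end,
        exons=list(toy_gene.exons),
        cds=list(toy_gene.cds),
        cds_seq="GGA" * 200,
    )


def make_panel(columns, positions=None, chrom="chrS"):
    """Panel from a list of 0/1 column tuples (all same haplotype count)."""
    matrix = np.array(columns, dtype=np.int8).T
    n_sites = matrix.shape[1]
    if positions is None:
        positions = [100 * (i + 1) for i in range(n_sites)]
    ids = [f"s{i}" for i in range(n_sites)]
    return HaplotypePanel(ids, positions, matrix, chrom=chrom)


@pytest.fixture
def hand_panel():
    """The hand-counted example: haplotype pairs 11 x3, 10 x1, 01 x1, 00 x3.

    D = 3/8 - 1/4 = 0.125 and r2 = 0.125**2 / 0.5**4 = 0.25 exactly.
    """
    col_a = (1, 1, 1, 1, 0, 0, 0, 0)
    col_b = (1, 1, 1, 0, 1, 0, 0, 0)
    return make_panel([col_a, col_b])


def variant_at(pos, vid=None, chrom="chrT", ref="A", alt="G", **kw):
    return Variant(vid or f"v{pos}", chrom, pos, ref, alt, **kw)
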