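import pytest

from genegraph.io import AlignmentHit
from genegraph.toys import chain, toy1, toy2, toy3, toy_parallel


@pytest.fixture
def t1():
    return toy1()


@pytest.fixture
def t2():
    return toy2()


@pytest.fixture
def t3():
    return toy3()


@pytest.fixture
def tpar():
    return toy_parallel()


@pytest.fixture
def tchain():
    return chain(5)


def make_hit(
    gene,
    genome,
    contig="c1",
    tstart=0,
    tend=None,
    score=500,
    strand="+",
    n_introns=1,
    protein=None,
):
    """Shorthand for synthetic alignment records in unit tests."""
    if tend is None:
        tend = tstart + 1000
    return AlignmentHit(
        protein=protein or gene,
        gene=gene,
        genome=genome,
        contig=contig,
        tstart=tstart,
        tend=tend,
        strand=strand,
        score=score,
        n_introns=n_introns,
        identity=0.98,
        qcov=1.0,
    )
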