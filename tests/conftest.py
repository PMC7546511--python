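import numpy as np
import pandas as pd
import pytest

from twosplice.data_io import GeneData, IsoformExpressionTable


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def make_gene(rng, L=3, J=2, K=(4, 4), shift=0.0, gene_id="g1"):
    """A gene with mild isoform structure; condition 2+ shifted by ``shift``."""
    base = rng.normal(2.0, 0.5, size=L)
    blocks = []
    for j in range(J):
        mu = base + (shift if j > 0 else 0.0)
        blocks.append(mu + rng.normal(0.0, 0.4, size=(K[j], L)) + rng.normal(0.0, 0.3, size=(K[j], 1)))
    return GeneData(
        gene_id,
        [f"t{l}" for l in range(L)],
        [f"c{j + 1}" for j in range(J)],
        blocks,
    )


@pytest.fixture
def small_gene(rng):
    return make_gene(rng)


def long_table(records):
    """Long-format raw table from (gene, transcript, sample, abundance) tuples."""
    df = pd.DataFrame(records, columns=["gene_id", "transcript_id", "sample_id", "abundance"])
    return IsoformExpressionTable(df, scale="raw")


@pytest.fixture
def toy_table():
    recs = []
    for g, n_iso in [("gA", 3), ("gB", 2), ("gC", 1)]:
        for t in range(n_iso):
            for s in range(4):
                recs.append((g, f"{g}.t{t}", f"s{s}", 2.0 + t + 0.1 * s))
    return long_table(recs)
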