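import numpy as np
import pandas as pd
import pytest

from methstage.io import CallTableMeta, CytosineCallTable


def make_table(rows, **meta):
    """Build a call table from (chrom, pos, strand, context, n_meth, n_total) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )
    return CytosineCallTable(df, CallTableMeta(**meta))


@pytest.fixture
def tiny_cg_table():
    """Four stranded CG records forming two dyads plus one lone CG and a CHH."""
    return make_table(
        [
            ("chr1", 1000, "+", "CG", 3, 5),
            ("chr1", 1001, "-", "CG", 2, 5),
            ("chr1", 2000, "+", "CG", 4, 6),
            ("chr1", 3000, "+", "CHH", 1, 8),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
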