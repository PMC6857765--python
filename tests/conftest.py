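import numpy as np
import pandas as pd
import pytest

from duomr.summary_io import InstrumentTable


def build_table(
    bzx,
    bzy,
    sezy,
    sezx=None,
    exposure="hdl",
    oriented_to=None,
    beta_fet=None,
    se_fet=None,
    pvals=None,
):
    """Hand-rolled single-exposure instrument table for estimator tests."""
    bzx = np.asarray(bzx, dtype=float)
    bzy = np.asarray(bzy, dtype=float)
    sezy = np.asarray(sezy, dtype=float)
    n = len(bzx)
    sezx = np.full(n, 0.01) if sezx is None else np.asarray(sezx, dtype=float)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            f"beta_{exposure}": bzx,
            f"se_{exposure}": sezx,
            f"p_{exposure}": np.full(n, 1e-10) if pvals is None else pvals,
            "beta_mat": bzy,
            "se_mat": sezy,
            "beta_fet": bzy if beta_fet is None else np.asarray(beta_fet, float),
            "se_fet": sezy if se_fet is None else np.asarray(se_fet, float),
        }
    )
    return InstrumentTable(df, exposures=[exposure], oriented_to=oriented_to)


@pytest.fixture
def make_table():
    return build_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
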