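import numpy as np
import pandas as pd
import pytest

from mrpath.instruments import HarmonizedSet
from mrpath.sumstats import SumStatTable


def make_table(rows, trait_name="trait", trait_type="continuous"):
    """Build a SumStatTable from a list of dicts with canonical keys."""
    return SumStatTable(trait_name, trait_type, pd.DataFrame(rows))


def make_hset(bx, sx, by, sy, **kw):
    bx = np.asarray(bx, float)
    ids = kw.pop("snp_ids", [f"rs{i+1}" for i in range(len(bx))])
    return HarmonizedSet(
        snp_ids=ids,
        beta_exp=bx,
        se_exp=np.asarray(sx, float),
        beta_out=np.asarray(by, float),
        se_out=np.asarray(sy, float),
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230829)


@pytest.fixture
def simple_hset():
    """Five well-behaved instruments on an exact line by = 0.2 * bx."""
    bx = np.array([0.10, 0.15, 0.08, 0.20, 0.12])
    return make_hset(bx, np.full(5, 0.01), 0.2 * bx, np.full(5, 0.02))
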