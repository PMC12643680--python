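import numpy as np
import pandas as pd
import pytest

from mrmediate.summary_io import AssociationTable, harmonized_from_arrays
from mrmediate.synthetic import SimConfig, simulate_summary_direct


def make_table(rows, trait_name="trait", trait_type="quantitative"):
    """AssociationTable from (snp, chrom, pos, ea, oa, eaf, beta, se, p, n) rows."""
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "effect_allele",
                                     "other_allele", "eaf", "beta", "se",
                                     "pval", "n"])
    return AssociationTable.from_frame(df, trait_name, trait_type)


@pytest.fixture
def two_instrument_set():
    """Two equal-weight instruments: IVW mean 0.6, fixed SE 1/sqrt(200)."""
    return harmonized_from_arrays(
        beta_exp=[1.0, 1.0], se_exp=[0.05, 0.05],
        beta_out=[0.5, 0.7], se_out=[0.1, 0.1])


@pytest.fixture
def collinear_egger_set():
    """Three points exactly on y = 0.1 + x."""
    return harmonized_from_arrays(
        beta_exp=[1.0, 2.0, 3.0], se_exp=[0.05, 0.05, 0.05],
        beta_out=[1.1, 2.1, 3.1], se_out=[0.1, 0.1, 0.1])


@pytest.fixture(scope="session")
def default_sim():
    """One summary-direct draw at the default study conditions."""
    return simulate_summary_direct(SimConfig(seed=20240101))


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
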