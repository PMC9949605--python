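import numpy as np
import pandas as pd
import pytest

from cismr.gwas_io import HarmonizedSet, LdMatrix
from cismr.pipeline import published_study_fixture


@pytest.fixture(scope="session")
def published_tables():
    """Published four-variant exposure/outcome tables plus placeholder LD."""
    return published_study_fixture()


@pytest.fixture
def make_hset():
    """Build a HarmonizedSet directly from effect vectors and an LD matrix."""

    def build(bx, sx, by, sy, r=None, rsids=None):
        k = len(bx)
        rsids = list(rsids) if rsids is not None else [f"rs{i}" for i in range(k)]
        r = np.eye(k) if r is None else np.asarray(r, dtype=float)
        log = pd.DataFrame({"rsid": rsids, "action": "kept", "reason": "alleles match"})
        return HarmonizedSet(rsids, bx, sx, by, sy, LdMatrix(rsids, r), log)

    return build


def random_correlation(rng, m):
    """Random full-rank correlation matrix (Wishart-based, then rescaled)."""
    a = rng.standard_normal((m, m + 2))
    s = a @ a.T
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)
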