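import numpy as np
import pytest
from scipy import stats

from targetmr import HarmonizedSet


def make_hset(
    b_X,
    b_Y,
    se_X=None,
    se_Y=None,
    rho=None,
    p_X=None,
    n_X=20_000,
    n_Y=300_000,
    pos=None,
    ids=None,
):
    """Build a HarmonizedSet from plain vectors with sensible defaults."""
    b_X = np.asarray(b_X, dtype=float)
    m = b_X.size
    b_Y = np.asarray(b_Y, dtype=float)
    se_X = np.full(m, 0.01) if se_X is None else np.asarray(se_X, dtype=float)
    se_Y = np.full(m, 0.01) if se_Y is None else np.asarray(se_Y, dtype=float)
    rho = np.eye(m) if rho is None else np.asarray(rho, dtype=float)
    if p_X is None:
        p_X = np.clip(2 * stats.norm.sf(np.abs(b_X / se_X)), 1e-300, 1.0)
    ids = tuple(f"v{i}" for i in range(m)) if ids is None else tuple(ids)
    pos = np.arange(m, dtype=float) * 1000 + 1 if pos is None else np.asarray(pos, dtype=float)
    return HarmonizedSet(
        variant_ids=ids,
        pos=pos,
        b_X=b_X,
        se_X=se_X,
        p_X=np.asarray(p_X, dtype=float),
        n_X=np.full(m, float(n_X)),
        b_Y=b_Y,
        se_Y=se_Y,
        n_Y=np.full(m, float(n_Y)),
        rho=rho,
    )


def ar1(m, c):
    idx = np.arange(m)
    return c ** np.abs(idx[:, None] - idx[None, :])


def random_psd_corr(rng, m, jitter=0.3):
    """Random well-conditioned correlation matrix."""
    a = rng.standard_normal((m, m + 5))
    s = a @ a.T + jitter * m * np.eye(m)
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240103)
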