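import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from xdevo.matrix import ExpressionMatrix

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_matrix(x, samples=None, species=None, scale="log", groups=None, ages=None):
    """Wrap a 2-d array as an ExpressionMatrix with minimal metadata."""
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if samples is None:
        samples = [f"s{i}" for i in range(m)]
    if species is None:
        species = ["sp"] * m
    if groups is None:
        groups = list(samples)
    if ages is None:
        ages = list(range(1, m + 1))
    meta = pd.DataFrame(
        {
            "species": species,
            "age_label": [f"t{a}" for a in ages],
            "age_order": ages,
            "platform": "count",
            "replicate_group": groups,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    values = pd.DataFrame(x, index=[f"G{i}" for i in range(n)], columns=samples)
    return ExpressionMatrix(values=values, meta=meta, scale=scale)


@pytest.fixture
def two_group_matrix():
    """2000 flat genes, 2 groups x 3 samples, Gaussian log-noise."""
    rng = np.random.default_rng(42)
    n = 2000
    x = rng.uniform(0, 10, n)[:, None] + rng.normal(0, 0.5, (n, 6))
    return make_matrix(x, groups=["g1"] * 3 + ["g2"] * 3, ages=[1, 1, 1, 2, 2, 2])


@pytest.fixture
def block_matrix():
    """Two well-separated sample blocks over 100 features."""
    rng = np.random.default_rng(5)
    n_feat = 100
    eff = rng.normal(0, 1, n_feat)
    cols = [5 * (1 if s < 5 else -1) * eff + rng.normal(0, 0.1, n_feat) for s in range(10)]
    return make_matrix(np.array(cols).T)
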