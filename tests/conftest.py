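import numpy as np
import pandas as pd
import pytest

from microgrs.simulate import SNPSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """A 8-family x 20-sample count matrix with some zeros."""
    counts = rng.integers(0, 400, size=(8, 20))
    counts[5:, ::3] = 0
    return pd.DataFrame(
        counts,
        index=[f"Fam{i}" for i in range(8)],
        columns=[f"S{j:02d}" for j in range(20)],
    )


@pytest.fixture
def trisnp():
    """A single SNP spec with all three genotype categories common."""
    return SNPSpec("snpX", ("A", "G"), 0.5, "none", 0.0)


def genotype_series(cats, counts, name="snpX"):
    """Genotype vector with the given category counts, fixed subject ids."""
    values = sum(([c] * k for c, k in zip(cats, counts)), [])
    idx = pd.Index([f"S{i:03d}" for i in range(len(values))], name="subject_id")
    return pd.Series(values, index=idx, name=name)
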