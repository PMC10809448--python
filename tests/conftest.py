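import numpy as np
import pandas as pd
import pytest

from quartetqc.profiles_io import (
    GROUPS,
    SAMPLE_COLUMNS,
    BatchProfile,
    MetaboliteKey,
)


def make_keys(n, start=1):
    return [MetaboliteKey(f"HMDB{k:07d}", f"met_{k:04d}")
            for k in range(start, start + n)]


def profile_from_log2(log2_values, batch_id="toy", keys=None):
    """Build a BatchProfile from a (metabolite x 12) log2 matrix."""
    arr = np.asarray(log2_values, dtype=float)
    if keys is None:
        keys = make_keys(arr.shape[0])
    df = pd.DataFrame(np.exp2(arr), index=keys, columns=list(SAMPLE_COLUMNS))
    return BatchProfile(batch_id, df)


def structured_log2(n_metabolites, rng, group_sd=1.0, noise_sd=0.1,
                    baseline=18.0):
    """Log2 matrix with distinct group means and replicate noise."""
    effects = rng.normal(0.0, group_sd, size=(n_metabolites, 4))
    base = rng.normal(baseline, 1.0, size=n_metabolites)
    out = np.empty((n_metabolites, 12))
    for ci, col in enumerate(SAMPLE_COLUMNS):
        gi = GROUPS.index(col.split("-")[0])
        out[:, ci] = base + effects[:, gi] + \
            rng.normal(0.0, noise_sd, size=n_metabolites)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def structured_profile(rng):
    """Complete 30-metabolite batch with clear group separation."""
    return profile_from_log2(structured_log2(30, rng), batch_id="lab1")
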