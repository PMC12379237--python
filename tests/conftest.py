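import numpy as np
import pandas as pd
import pytest

from khiblearn.encoders import DEFAULT_GROUPINGS, FeatureMatrix

#: the 20-residue worked-example peptide used throughout the CTD literature
EXAMPLE_SEQ = "AFDQFGHIKLMEPRQTSIWS"


@pytest.fixture(scope="session")
def hydrophobicity():
    return DEFAULT_GROUPINGS[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_window(rng, flank=21, n_pad_left=0, n_pad_right=0):
    """A random lysine-centred window string with optional terminal padding."""
    from khiblearn.simulate import AA20

    L = 2 * flank + 1
    chars = [AA20[i] for i in rng.integers(0, 20, size=L)]
    chars[flank] = "K"
    for i in range(n_pad_left):
        chars[i] = "X"
    for i in range(n_pad_right):
        chars[L - 1 - i] = "X"
    return "".join(chars)


def make_feature_matrix(X: np.ndarray, y, prefix="esm") -> FeatureMatrix:
    """Wrap a plain array as a category-tagged FeatureMatrix."""
    cols = [f"{prefix}_{i:04d}" for i in range(X.shape[1])]
    return FeatureMatrix(pd.DataFrame(X, columns=cols), np.asarray(y))
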