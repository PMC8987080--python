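import numpy as np
import pytest

from malosite.sequence_io import AMINO_ACIDS, PeptideWindow, SiteDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_window(rng, length=25, label="unknown", center_k=True):
    chars = list(rng.choice(list(AMINO_ACIDS), size=length))
    if center_k:
        chars[(length - 1) // 2] = "K"
    return PeptideWindow(residues="".join(chars), label=label)


@pytest.fixture
def random_windows(rng):
    return [random_window(rng) for _ in range(100)]


@pytest.fixture
def toy_dataset(rng):
    """Small balanced labeled dataset of 25-mers."""
    windows = [random_window(rng, label="positive") for _ in range(20)]
    windows += [random_window(rng, label="negative") for _ in range(20)]
    return SiteDataset(windows)
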