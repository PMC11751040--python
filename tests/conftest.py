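import numpy as np
import pytest

import cyspred as cp

#: Small architecture used by most tests to keep runtimes negligible.
TINY_MODEL = cp.ModelConfig(
    conv_channels=(4, 6), kernel_sizes=(3, 3), pool_size=2,
    lstm_hidden=6, attention_dim=5, fc_sizes=(8, 6), dropout=0.2,
)

#: Reduced architecture for the heavier synthetic-recovery runs: same layer
#: stack as the default, half the widths.
HALF_MODEL = cp.ModelConfig(
    conv_channels=(16, 32), kernel_sizes=(5, 5), pool_size=2,
    lstm_hidden=32, attention_dim=32, fc_sizes=(32, 16), dropout=0.5,
)


@pytest.fixture
def tiny_model_config():
    return TINY_MODEL


def make_separable_dataset(n: int = 20, L: int = 11, seed: int = 0):
    """Windows whose class is decided by a lysine adjacent to the center.

    Positives carry 'K' at center+1; negatives contain no 'K' at all, so the
    problem is linearly separable from the one-hot encoding.
    """
    rng = np.random.default_rng(seed)
    letters = [aa for aa in cp.ALPHABET if aa not in ("K", "C")]
    half = (L - 1) // 2
    windows = []
    for i in range(n):
        chars = list(rng.choice(letters, size=L))
        chars[half] = "C"
        label = i % 2
        if label == 1:
            chars[half + 1] = "K"
        windows.append(
            cp.PeptideWindow(
                sequence="".join(chars), label=label,
                protein_id=f"prot{i % 8}", center_position=half + 1,
            )
        )
    return cp.LabeledDataset(windows)


@pytest.fixture
def separable_dataset():
    return make_separable_dataset()


@pytest.fixture(scope="session")
def recovery_dataset():
    """The synthetic study dataset: strong center signal, 600 + 600 windows."""
    spec = cp.SignalSpec(L=41, signal_strength=0.8, signal_decay=0.05, seed=11)
    return cp.generate_dataset(spec, n_pos=600, n_neg=600)
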