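import numpy as np
import pytest

import quartetri as q


@pytest.fixture
def tiny_s1_file(tmp_path):
    """A minimal valid 4-row outcome file: one block, all four arms."""
    text = (
        "treatment,sel1,sel2,store1,store2,gen1,gen2,block,know_sel,know_store\n"
        "Ctrl,TRUE,FALSE,TRUE,TRUE,FALSE,TRUE,1,TRUE,FALSE\n"
        "Sel,FALSE,TRUE,TRUE,TRUE,TRUE,FALSE,1,FALSE,FALSE\n"
        "Store,TRUE,TRUE,FALSE,TRUE,TRUE,TRUE,1,TRUE,TRUE\n"
        "Sel+Store,TRUE,TRUE,TRUE,FALSE,FALSE,TRUE,1,FALSE,TRUE\n"
    )
    path = tmp_path / "tiny.csv"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def study_b5():
    """A small complete synthetic study: 5 blocks, 20 units."""
    return q.simulate_study(n_units=20, seed=101)


@pytest.fixture(scope="session")
def study_full():
    """A full-size synthetic study: 62 blocks, 248 units, default effects."""
    return q.simulate_study(n_units=248, seed=202)


def random_balanced_instance(rng, binary_outcome=True):
    """A random balanced-quartet instance: (y, indicator, block labels)."""
    B = int(rng.integers(2, 11))
    n = 4 * B
    y = (
        rng.integers(0, 2, n).astype(float)
        if binary_outcome
        else rng.normal(size=n)
    )
    patterns = np.asarray(q.BLOCK_PATTERNS)
    ind = np.empty(n)
    for b in range(B):
        ind[4 * b : 4 * b + 4] = patterns[rng.integers(6)] == "T"
    labels = np.repeat([f"b{b}" for b in rng.permutation(B)], 4)
    return y, ind, labels
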