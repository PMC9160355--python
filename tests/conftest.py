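import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220429)


@pytest.fixture(scope="session")
def random_sequences(rng):
    """60 random DNA sequences, lengths 100-3000 nt, for oracle comparisons."""
    seqs = []
    for _ in range(60):
        n = int(rng.integers(100, 3001))
        seqs.append("".join(rng.choice(list("ACGT"), size=n)))
    return seqs


@pytest.fixture(scope="session")
def fixture_study(tmp_path_factory):
    """A complete miniature synthetic study on disk."""
    from rhoterm.pipeline import make_fixture_study

    outdir = tmp_path_factory.mktemp("study")
    return make_fixture_study(outdir, seed=11)
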