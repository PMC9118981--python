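import numpy as np
import pytest

from cyaclear import motifs


@pytest.fixture(scope="session")
def cah_pattern():
    return motifs.parse_pattern(motifs.CAH_MOTIF)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_scan(residues: str, pattern) -> list[int]:
    """Brute-force sliding-window motif scan (1-based starts).

    Independent oracle: checks every window position against the pattern's
    allowed-residue sets directly.
    """
    m = len(pattern)
    starts = []
    for i in range(len(residues) - m + 1):
        if all(residues[i + j] in pattern.positions[j] for j in range(m)):
            starts.append(i + 1)
    return starts
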