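import numpy as np
import pytest

# The ten published non-square (L1, L2) ring conformations: wild type with
# ADP, both arginine-16 mutants with ADP, and the A80P/E125Q mutants with
# either nucleotide (two of the crystal forms hold two distinct rings).
PRINTED_NONSQUARE = [
    ("WT_ADP", 40.7, 30.7),
    ("R16K_ADP", 52.0, 21.9),
    ("R16A_ADP_1", 34.0, 30.0),
    ("R16A_ADP_2", 37.0, 28.0),
    ("A80P_ATP", 52.0, 23.0),
    ("A80P_ADP", 52.0, 22.0),
    ("E125Q_ATP_1", 34.0, 30.0),
    ("E125Q_ATP_2", 42.0, 27.0),
    ("E125Q_ADP_1", 34.0, 30.0),
    ("E125Q_ADP_2", 42.0, 27.0),
]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
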