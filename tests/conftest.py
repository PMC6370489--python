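import numpy as np
import pytest

import braindyn as bd


@pytest.fixture(scope="session")
def small_connectome():
    """10-ROI connectome used by fast simulation tests."""
    return bd.generate_synthetic_connectome(10, seed=7)


@pytest.fixture(scope="session")
def default_connectome():
    """The 66-ROI study connectome (fixed seed)."""
    return bd.generate_synthetic_connectome(66, seed=1)


def two_node_connectome(c12: float = 0.5, delay_s: float = 0.0) -> bd.Connectome:
    """Minimal symmetric 2-node network for closed-form checks."""
    W = np.array([[0.0, c12], [c12, 0.0]])
    L = np.full((2, 2), delay_s * 5.45 * 1e3)
    np.fill_diagonal(L, 0.0)
    L[W == 0] = 0.0
    return bd.Connectome(
        weights=W,
        lengths=L,
        delays=bd.delays_from_lengths(L, 5.45),
        hemisphere=np.array(["L", "R"]),
        roi_names=np.array(["L01", "R01"]),
    )
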