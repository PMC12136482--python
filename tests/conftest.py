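import numpy as np
import pytest

from hybridbrain import CellParams, Connectome


@pytest.fixture(scope="session")
def cell_params() -> CellParams:
    return CellParams()


@pytest.fixture()
def toy_connectome() -> Connectome:
    """3-region fully connected toy connectome with distinct delays."""
    w = np.array([[0.0, 0.5, 0.2],
                  [0.5, 0.0, 0.3],
                  [0.2, 0.3, 0.0]])
    L = np.array([[0.0, 6.0, 12.0],
                  [6.0, 0.0, 9.0],
                  [12.0, 9.0, 0.0]])
    return Connectome(labels=["A", "B", "C"], weights=w, tract_lengths=L,
                      speed=3.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
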