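import numpy as np
import pytest

from polcropsar.polsar import C3Field
from polcropsar.simulate import default_config, generate_scene


def random_psd_matrices(n: int, seed: int = 0) -> np.ndarray:
    """n random 3x3 Hermitian positive-semidefinite matrices, A A^H form."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, 3, 3)) + 1j * rng.normal(size=(n, 3, 3))
    return a @ a.conj().swapaxes(-1, -2)


@pytest.fixture(scope="session")
def psd_1000() -> np.ndarray:
    return random_psd_matrices(1000, seed=12345)


@pytest.fixture(scope="session")
def small_scene():
    """A small 4-class simulated scene shared across tests (seed 7)."""
    cfg = default_config(seed=7)
    cfg.shape = (64, 64)
    cfg.field_grid = (4, 4)
    cfg.train_fields_per_class = 1
    return generate_scene(cfg)


def coherent_c3(sinclair: np.ndarray) -> C3Field:
    """Single-pixel C3Field of a deterministic Sinclair matrix."""
    s = np.asarray(sinclair, dtype=complex)
    k = np.array([s[0, 0], np.sqrt(2.0) * s[0, 1], s[1, 1]])
    return C3Field(data=np.outer(k, k.conj())[None, None])
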