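import numpy as np
import pytest

from rollcall import DEFAULT_ADAPTER, LET7A, build_circular_template


@pytest.fixture(scope="session")
def adapter() -> str:
    return DEFAULT_ADAPTER


@pytest.fixture(scope="session")
def let7a() -> str:
    return LET7A


@pytest.fixture(scope="session")
def template(let7a, adapter) -> str:
    """42 nt circular template: control miRNA insert + adapter."""
    return build_circular_template(let7a, adapter)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220923)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(4, size=length))
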