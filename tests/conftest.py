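import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import build_nhoods, de_cfg, structured_cfg  # noqa: E402

from pseudodiff.simulate import simulate  # noqa: E402


@pytest.fixture(scope="session")
def structured_ct():
    """One structured toy dataset shared by read-only tests."""
    return simulate(structured_cfg(seed=11))


@pytest.fixture(scope="session")
def structured_nhoods(structured_ct):
    return build_nhoods(structured_ct, seed=1)


@pytest.fixture(scope="session")
def de_ct():
    return simulate(de_cfg(seed=7))


@pytest.fixture(scope="session")
def de_nhoods(de_ct):
    return build_nhoods(de_ct, seed=1)
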