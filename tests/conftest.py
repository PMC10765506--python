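import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from oenotype.assays import AssayPanel
from oenotype.data import reference


@pytest.fixture
def panel_neutral_dry():
    """Neutral, low H2S rising over time, acetic producer, fully SO2
    resistant, bglu negative: codes to (1,1,0,2,1) under the day-8 policy
    only because day 8 reads 1."""
    return AssayPanel(
        killer="neutral",
        h2s_scores={2: 0, 5: 1, 8: 1},
        acetic="producer",
        so2_growth={0: True, 100: True, 200: True, 300: True, 400: True, 500: True},
        bglu="negative",
    )


@pytest.fixture
def reference_outcomes():
    return reference.load_strain_outcomes()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_code_matrix(rng, n):
    """Random legal 5-digit codes (may contain duplicates)."""
    lows = np.array([1, 0, 0, 0, 0])
    highs = np.array([2, 3, 1, 2, 1])
    return rng.integers(lows, highs + 1, size=(n, 5))
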