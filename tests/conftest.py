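import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from materwell import apply_exclusions, default_config, generate_cohort, score_scales


@pytest.fixture(scope="session")
def default_cohort():
    """Scored, filtered cohort at the default 14-group / 712-dyad layout."""
    raw, truth = generate_cohort(default_config(seed=11))
    table, _ = apply_exclusions(score_scales(raw))
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
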