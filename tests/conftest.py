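import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from delphiset import RatingsPanel, SimConfig, simulate_round1

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(matrix, round_label="round1", rater_prefix="p", item_prefix="i"):
    """Build a panel from a raters x items integer array (no missing cells)."""
    matrix = np.asarray(matrix)
    n_raters, n_items = matrix.shape
    raters = [f"{rater_prefix}{r + 1:02d}" for r in range(n_raters)]
    items = [f"{item_prefix}{j + 1:02d}" for j in range(n_items)]
    long = pd.DataFrame(
        {
            "participant_id": np.repeat(raters, n_items),
            "item_id": np.tile(items, n_raters),
            "score": matrix.ravel(),
        }
    )
    return RatingsPanel(round_label=round_label, scores=long)


@pytest.fixture
def tiny_panel():
    # 5 raters x 4 items, handcrafted
    mat = np.array(
        [
            [9, 7, 2, 5],
            [8, 7, 3, 5],
            [9, 6, 1, 4],
            [7, 8, 2, 6],
            [9, 7, 2, 5],
        ]
    )
    return make_panel(mat)


@pytest.fixture
def small_sim():
    return simulate_round1(SimConfig(n_raters=12, n_items=10, seed=11))


@pytest.fixture
def default_sim():
    return simulate_round1(SimConfig(seed=5))
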