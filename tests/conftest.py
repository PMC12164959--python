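import logging

import numpy as np
import pandas as pd
import pytest

from selectmem import synthgen

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_cfg():
    """A small cohort config used across unit tests."""
    return synthgen.GenerativeConfig(
        n_participants=12, n_runs=3, trials_per_run=12, n_voxels_per_roi=32, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    participants, trials = synthgen.generate_cohort(small_cfg)
    return participants, trials


@pytest.fixture(scope="session")
def small_patterns(small_cfg, small_cohort):
    participants, trials = small_cohort
    return synthgen.generate_patterns(small_cfg, participants, trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_response_table(hits, n_old, fas, n_new, category="face"):
    """Build a single-participant response table with exact hit/FA counts."""
    other = "place" if category == "face" else "face"
    rows = []
    for i in range(n_old):
        rows.append(("p1", f"old_{category}", category if i < hits else other))
    for i in range(n_new):
        rows.append(("p1", "new", category if i < fas else "new"))
    return pd.DataFrame(rows, columns=["participant_id", "probe_type", "response"])
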