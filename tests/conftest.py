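"""Shared fixtures: small cohorts, geometries, deterministic RNGs."""

import numpy as np
import pandas as pd
import pytest

from turnvar import GroupSpec, MazeGeometry, SyntheticConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def geometry():
    return MazeGeometry()


@pytest.fixture
def two_group_config():
    """Small two-group cohort with a clear dispersion contrast."""
    return SyntheticConfig(
        groups=(
            GroupSpec("control", 40, 0.5, 18.0, 0.215, 0.787),
            GroupSpec("escitalopram", 40, 0.5, 60.0, 0.372, 1.012),
        ),
        session_minutes=60.0,
        seed=11,
    )


@pytest.fixture
def small_events(two_group_config):
    events, flies = simulate_cohort(two_group_config)
    return events, flies


def make_events(per_fly: dict[str, str], treatment: str = "g") -> pd.DataFrame:
    """Build a tiny events table from {fly_id: 'RRLR...'} strings."""
    rows = []
    for fly, seq in per_fly.items():
        for i, d in enumerate(seq):
            rows.append(
                {"fly_id": fly, "treatment": treatment, "time_s": float(i + 1), "direction": d}
            )
    return pd.DataFrame(rows, columns=["fly_id", "treatment", "time_s", "direction"])
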