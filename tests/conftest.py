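"""Shared fixtures: small, fast synthetic configurations and frame builders."""

import numpy as np
import pandas as pd
import pytest

from accelcal.synthetic_data import LognormalParams, Phase, SimulationConfig


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """Two short sessions, three children each: fast but fully featured."""
    return SimulationConfig(
        n_sessions=2,
        participants_per_session=3,
        phase_plan=[
            Phase(name="warm_up", duration_min=2, mix={1: 0.1, 2: 0.2, 3: 0.3, 4: 0.3, 5: 0.1}),
            Phase(name="games", duration_min=3, mix={2: 0.2, 3: 0.2, 4: 0.3, 5: 0.3}),
        ],
        seed=42,
    )


@pytest.fixture
def separated_config() -> SimulationConfig:
    """Disjoint class count distributions, no coding error, pure intervals.

    Tight lognormals with widely spaced medians make the per-category 20-s
    sums disjoint, and single-category phases (each a multiple of 20 s) keep
    behaviour constant within every interval, so calibration must separate
    the classes perfectly and place boundaries in the between-class gaps.
    """
    return SimulationConfig(
        n_sessions=2,
        participants_per_session=8,
        phase_plan=[
            Phase(name=f"only_{c}", duration_min=9, mix={c: 1.0}) for c in (1, 2, 3, 4, 5)
        ],
        category_count_params={
            1: LognormalParams(median=5, sigma=0.05),
            2: LognormalParams(median=30, sigma=0.05),
            3: LognormalParams(median=150, sigma=0.05),
            4: LognormalParams(median=400, sigma=0.05),
            5: LognormalParams(median=1200, sigma=0.05),
        },
        dwell_mean_s=90.0,
        participant_sd=0.0,
        mislabel_prob=0.0,
        out_of_hall_prob=0.0,
        seed=7,
    )


def make_aligned(counts_20s, categories, participant="P1", session=1, valid=True) -> pd.DataFrame:
    """Aligned-epoch frame from parallel count/category sequences."""
    counts_20s = np.asarray(counts_20s, dtype=np.int64)
    categories = np.asarray(categories, dtype=np.int64)
    n = len(counts_20s)
    return pd.DataFrame(
        {
            "participant": participant,
            "session": session,
            "interval": np.arange(n, dtype=np.int64),
            "vertical_counts_20s": counts_20s,
            "vm_counts_20s": counts_20s * 2,
            "category": categories,
            "valid": valid,
        }
    )
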