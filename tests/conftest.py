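"""Shared fixtures: canonical and reduced synthetic datasets.

Everything is generated in-process from seeds; no stored data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fmclass.metrics import build_covariate_matrix, compute_covariates
from fmclass.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def canonical_dataset():
    """The default-configuration dataset at the canonical seed (42)."""
    return generate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def canonical_covariates(canonical_dataset):
    """(covariate matrix, truth series) for the canonical dataset."""
    cov, excluded = compute_covariates(canonical_dataset.detections)
    matrix = build_covariate_matrix(cov)
    truth = (
        canonical_dataset.truth.set_index("tag_id").loc[cov.index, "archetype"]
    )
    return matrix, truth, excluded


@pytest.fixture(scope="session")
def small_config():
    """Reduced simulation: quick enough for repeated pipeline runs."""
    return SimulationConfig(
        n_installations=6,
        coast_length_km=800.0,
        counts={"RESIDENT": 10, "OCCASIONAL": 14, "IRRUPTOR": 5, "ROAMER": 7},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


def _make_track(
    times_min,
    lats,
    lons,
    tag="T1",
    receiver_ids=None,
    installation_ids=None,
) -> pd.DataFrame:
    """Hand-built detection table for covariate unit tests."""
    n = len(times_min)
    ts = pd.to_datetime("2015-01-01") + pd.to_timedelta(np.asarray(times_min), unit="m")
    return pd.DataFrame(
        {
            "tag_id": [tag] * n,
            "timestamp": ts.astype("datetime64[s]"),
            "receiver_id": receiver_ids or [f"R{i}" for i in range(n)],
            "installation_id": installation_ids or ["I0"] * n,
            "latitude": np.asarray(lats, dtype=float),
            "longitude": np.asarray(lons, dtype=float),
            "qc_flag": np.int64(1),
            "species": pd.NA,
        }
    )


@pytest.fixture(scope="session")
def make_track():
    """Factory for hand-built single-tag detection tables."""
    return _make_track
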