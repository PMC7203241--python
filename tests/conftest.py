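"""Shared fixtures: a small synthetic experiment generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cytofeat.fcs_io import ChannelMap, EventTable
from cytofeat.synthetic import default_channel_map, default_config, generate_experiment

SMALL_SEED = 11


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study conditions (same structure, fewer events/samples)."""
    return default_config(
        seed=SMALL_SEED, n_samples=4, n_events=8_000, n_fmo_events=5_000
    )


@pytest.fixture(scope="session")
def small_experiment(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("experiment")
    truth = generate_experiment(small_config, outdir)
    return small_config, outdir, truth


@pytest.fixture(scope="session")
def small_channel_map(small_config):
    return default_channel_map(small_config)


@pytest.fixture
def tiny_channel_map():
    """Minimal panel: scatter pair, viability, two markers."""
    return ChannelMap.from_entries(
        [
            ("FSC-A", "FSC-A", "scatter_area"),
            ("FSC-H", "FSC-H", "scatter_height"),
            ("Zombie-A", "Zombie", "viability"),
            ("CD3-A", "CD3", "marker"),
            ("CD4-A", "CD4", "marker"),
        ]
    )


def make_event_table(
    channel_map: ChannelMap, values: dict[str, np.ndarray], sample_id: str = "T01"
) -> EventTable:
    data = pd.DataFrame({d: values[d] for d in channel_map.detectors})
    return EventTable(sample_id=sample_id, data=data, channel_map=channel_map)
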