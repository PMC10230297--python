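"""Shared fixtures: small synthetic layers, panels and ping tables."""

import numpy as np
import pandas as pd
import pytest

from mobigrid import synth
from mobigrid.pipeline import RunConfig
from mobigrid.segreg import default_segments


@pytest.fixture(scope="session")
def segments():
    return default_segments()


@pytest.fixture(scope="session")
def calendar(segments):
    return synth.study_calendar(segments)


@pytest.fixture(scope="session")
def zones():
    return synth.generate_zones(8, ["A", "B", "C", "D"], area_km=10, seed=42)


@pytest.fixture(scope="session")
def panel(zones, calendar):
    return synth.generate_panel(60, zones, calendar, seed=7)


@pytest.fixture(scope="session")
def pings(panel, zones, calendar, segments):
    return synth.generate_pings(panel, zones, calendar, synth.null_schedule(),
                                segments, seed=3)


@pytest.fixture()
def small_config():
    """A fast pipeline config: fewer devices, relaxed cell threshold."""
    return RunConfig(seed=5, n_devices=60, n_zones=4, area_km=4,
                     categories=["A", "B"], min_devices=3)


def random_ping_table(rng: np.random.Generator, n_rows: int,
                      n_devices: int = 20, n_apps: int = 6,
                      span_days: int = 60) -> pd.DataFrame:
    """A structureless random ping table for oracle comparisons."""
    start = pd.Timestamp("2020-01-05", tz="UTC")
    ts = start + pd.to_timedelta(rng.integers(0, span_days * 86400, n_rows), unit="s")
    return pd.DataFrame({
        "device_id": rng.integers(0, n_devices, n_rows).astype(str),
        "app_id": np.char.add("app", rng.integers(0, n_apps, n_rows).astype(str)),
        "timestamp": ts,
        "x_m": rng.uniform(-2500, 7500, n_rows),
        "y_m": rng.uniform(-2500, 7500, n_rows),
        "accuracy_m": rng.exponential(120, n_rows),
    })
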