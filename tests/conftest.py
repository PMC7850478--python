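import io

import numpy as np
import pytest

from mmlineage.io import EventRecord, read_events


@pytest.fixture
def toy_events():
    """Two channels: one with three divisions then end-of-observation, one
    with two divisions then death."""
    return [
        EventRecord("A", 10.0, "division"),
        EventRecord("A", 20.0, "division"),
        EventRecord("A", 31.0, "division"),
        EventRecord("A", 100.0, "end_of_observation"),
        EventRecord("B", 5.0, "division"),
        EventRecord("B", 15.0, "division"),
        EventRecord("B", 20.0, "death"),
    ]


def make_random_event_table(rng: np.random.Generator, n_channels: int = 8):
    """Random but valid event table (for round-trip / oracle tests)."""
    records = []
    for i in range(n_channels):
        cid = f"c{i}"
        t = 0.0
        for _ in range(rng.integers(0, 8)):
            t += float(rng.uniform(0.5, 20.0))
            records.append(EventRecord(cid, round(t, 3), "division"))
        t += float(rng.uniform(0.5, 20.0))
        terminal = "death" if rng.random() < 0.3 else "end_of_observation"
        records.append(EventRecord(cid, round(t, 3), terminal))
    return records


@pytest.fixture
def random_table_factory():
    return make_random_event_table


def events_from_csv(text: str):
    return read_events(io.StringIO(text))
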