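import io

import pytest

from latebind import Warehouse
from latebind.fixtures import load_worked_example, worked_example


@pytest.fixture
def empty_warehouse():
    return Warehouse()


@pytest.fixture
def loaded_warehouse():
    """Warehouse with the worked example ingested and its pipelines defined
    (data at t=1000, maps at t=1000)."""
    wh = Warehouse()
    ex = load_worked_example(wh, data_ts=1000, map_ts=1000)
    return wh, ex


@pytest.fixture
def example():
    return worked_example()


def ingest_csv_text(wh: Warehouse, text: str, domain, key_spec, ts, dedup=True):
    return wh.ingestor.ingest_csv(io.StringIO(text), domain, key_spec, ts, dedup=dedup)
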