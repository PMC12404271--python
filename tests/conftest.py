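import numpy as np
import pandas as pd
import pytest

from iciqtl.config import StudyConfig
from iciqtl.io import GrowthSeries


@pytest.fixture
def config() -> StudyConfig:
    return StudyConfig(seed=0)


@pytest.fixture
def make_series():
    """Factory for GrowthSeries with sensible defaults."""

    def _make(days, volumes, mouse_id="m1", line_id="L1", arm="treated"):
        return GrowthSeries(
            mouse_id=mouse_id, line_id=line_id, arm=arm,
            days=np.asarray(days), volumes=np.asarray(volumes, dtype=float),
        )

    return _make


@pytest.fixture
def growth_tsv(tmp_path):
    """Write a growth table TSV from (mouse, line, arm, day, volume) rows."""

    def _write(rows, name="growth.tsv"):
        df = pd.DataFrame(
            rows, columns=["mouse_id", "line_id", "arm", "day", "volume_mm3"]
        )
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write
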