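import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ilkit.genetic_map import Marker, MarkerMap

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_map() -> MarkerMap:
    """Five markers on one 50 cM chromosome at 6, 10, 20, 26, 40 cM."""
    return MarkerMap(
        [Marker(f"m{i}", "1H", p) for i, p in enumerate([6.0, 10.0, 20.0, 26.0, 40.0])],
        chromosome_lengths={"1H": 50.0},
    )


@pytest.fixture
def two_chrom_map() -> MarkerMap:
    markers = [Marker(f"a{i}", "1H", p) for i, p in enumerate([0.0, 10.0, 20.0, 30.0])]
    markers += [Marker(f"b{i}", "2H", p) for i, p in enumerate([5.0, 15.0, 25.0])]
    return MarkerMap(markers, chromosome_lengths={"1H": 40.0, "2H": 30.0})


def line_series(marker_map: MarkerMap, calls: list[str]) -> pd.Series:
    return pd.Series(calls, index=[m.id for m in marker_map.markers])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
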