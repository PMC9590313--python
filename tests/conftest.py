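import math

import numpy as np
import pytest

from greenreach.city_model import Park
from greenreach.network_travel import RoadNetwork
from greenreach.synthcity import ScenarioSpec, generate_city


@pytest.fixture
def line_network():
    """Three nodes on a straight 2.5 km street (two 1250 m edges)."""
    return RoadNetwork(
        nodes={0: (0.0, 0.0), 1: (1250.0, 0.0), 2: (2500.0, 0.0)},
        edges=[(0, 1, 1250.0, "street"), (1, 2, 1250.0, "street")],
    )


@pytest.fixture
def detour_network():
    """5-node graph where the network path is much longer than the chord:
    straight-line 0→4 is 250 m but the only road path is 400 m."""
    return RoadNetwork(
        nodes={
            0: (0.0, 0.0),
            1: (0.0, 150.0),
            2: (125.0, 150.0),
            3: (250.0, 150.0),
            4: (250.0, 0.0),
        },
        edges=[
            (0, 1, 100.0, "street"),
            (1, 2, 100.0, "street"),
            (2, 3, 100.0, "street"),
            (3, 4, 100.0, "street"),
        ],
    )


@pytest.fixture
def small_spec():
    """A fast-to-generate 14x14 city used where many cities are needed."""
    return ScenarioSpec(
        nrows=14,
        ncols=14,
        total_population=8000,
        ring_radii_m=(300.0, 600.0),
        park_counts={"comprehensive": 1, "special": 1, "community": 2, "street": 2},
        n_pois=80,
        n_residential_pois=80,
        seed=0,
    )


@pytest.fixture
def small_city(small_spec):
    return generate_city(small_spec)


def park_at(x, y, area=10_000.0, category="community", park_id=0, radius=300.0):
    p = Park(park_id=park_id, category=category, area_m2=area,
             entrances=[(x, y)])
    p.service_radius_m = radius
    return p
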