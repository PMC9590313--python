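import itertools
import math

import networkx as nx
import numpy as np
import pytest

from greenreach.network_travel import (
    DEFAULT_MODES,
    RoadNetwork,
    SurveyBins,
    TravelMode,
    network_service_area,
    od_travel_times,
    threshold_from_survey,
)
from tests.conftest import park_at

WALK = DEFAULT_MODES["walking"]


class TestODTravelTimes:
    def test_length_over_speed(self, line_network):
        park = park_at(2500.0, 0.0)
        od = od_travel_times(line_network, [(0, (0.0, 0.0))], [park], WALK)
        # 2.5 km at 5 km/h = 30 min
        assert od.minutes[0, 0] == pytest.approx(30.0)

    def test_min_over_entrances(self, line_network):
        park = park_at(2500.0, 0.0)
        park.entrances = [(2500.0, 0.0), (1250.0, 0.0)]
        od = od_travel_times(line_network, [(0, (0.0, 0.0))], [park], WALK)
        assert od.minutes[0, 0] == pytest.approx(15.0)

    def test_disconnected_component_unreachable(self):
        net = RoadNetwork(
            nodes={0: (0, 0), 1: (100, 0), 2: (5000, 0), 3: (5100, 0)},
            edges=[(0, 1, 100.0, "street"), (2, 3, 100.0, "street")],
        )
        od = od_travel_times(net, [(0, (0.0, 0.0))], [park_at(5100.0, 0.0)], WALK)
        assert math.isinf(od.minutes[0, 0])

    def test_snap_distance_traversed_at_mode_speed(self, line_network):
        od = od_travel_times(
            line_network, [(0, (0.0, 250.0))], [park_at(2500.0, 0.0)], WALK
        )
        # 250 m snap + 2500 m path at 5 km/h
        assert od.minutes[0, 0] == pytest.approx((250 + 2500) / (5000 / 60))

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            od_travel_times(RoadNetwork(nodes={}, edges=[]),
                            [(0, (0.0, 0.0))], [park_at(0.0, 0.0)], WALK)

    def test_origin_entrance_symmetry(self, detour_network):
        # undirected graph: swapping origin and entrance leaves time unchanged
        fwd = od_travel_times(detour_network, [(0, (0.0, 0.0))],
                              [park_at(250.0, 0.0)], WALK)
        rev = od_travel_times(detour_network, [(0, (250.0, 0.0))],
                              [park_at(0.0, 0.0)], WALK)
        assert fwd.minutes[0, 0] == pytest.approx(rev.minutes[0, 0])

    def test_adding_edge_never_increases_times(self, small_city):
        origins = [(c.cell_id, c.centroid) for c in small_city.grid[::7]]
        before = od_travel_times(small_city.network, origins,
                                 small_city.parks, WALK).minutes
        net = small_city.network
        ids = sorted(net.nodes)
        u, v = ids[0], ids[-1]
        d = math.dist(net.nodes[u], net.nodes[v])
        augmented = RoadNetwork(nodes=dict(net.nodes),
                                edges=net.edges + [(u, v, d, "shortcut")])
        after = od_travel_times(augmented, origins, small_city.parks, WALK).minutes
        assert np.all(after <= before + 1e-9)

    def test_matches_exhaustive_path_enumeration(self):
        # oracle: on tiny graphs, Dijkstra equals brute-force enumeration of
        # all simple paths
        rng = np.random.default_rng(42)
        for trial in range(5):
            n = 8
            pts = rng.uniform(0, 1000, size=(n, 2))
            nodes = {i: tuple(pts[i]) for i in range(n)}
            edges = []
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.35:
                    edges.append((i, j, float(math.dist(pts[i], pts[j]) + 1.0), "s"))
            if not edges:
                continue
            net = RoadNetwork(nodes=nodes, edges=edges)
            g = nx.Graph()
            for u, v, w, _ in edges:
                g.add_edge(u, v, w=w)
            park = park_at(*pts[0])
            od = od_travel_times(net, [(i, tuple(pts[i])) for i in range(n)],
                                 [park], WALK)
            for i in range(n):
                if i == 0:
                    assert od.minutes[i, 0] == pytest.approx(0.0, abs=1e-12)
                    continue
                if i not in g or 0 not in g or not nx.has_path(g, i, 0):
                    assert math.isinf(od.minutes[i, 0])
                    continue
                best = min(
                    sum(g[a][b]["w"] for a, b in zip(path, path[1:]))
                    for path in nx.all_simple_paths(g, i, 0)
                )
                assert od.minutes[i, 0] == pytest.approx(
                    best / WALK.speed_m_per_min, abs=1e-9
                )


class TestServiceArea:
    def test_point_beside_covered_street_inside(self, line_network):
        park = park_at(0.0, 0.0, radius=300.0)
        sa = network_service_area(line_network, park)
        assert sa.contains((100.0, 10.0))

    def test_point_beyond_radius_outside(self, line_network):
        park = park_at(0.0, 0.0, radius=500.0)
        sa = network_service_area(line_network, park)
        assert not sa.contains((600.0, 0.0))

    def test_membership_uses_network_not_euclidean_distance(self, detour_network):
        # 250 m straight-line but 400 m by road, radius 300 → outside
        park = park_at(0.0, 0.0, radius=300.0)
        sa = network_service_area(detour_network, park)
        assert not sa.contains((250.0, 0.0))
        # brute-force check on the toy graph: shortest network path 0→4
        g = nx.Graph()
        for u, v, w, _ in detour_network.edges:
            g.add_edge(u, v, w=w)
        assert nx.shortest_path_length(g, 0, 4, weight="w") == 400.0

    def test_partial_edge_coverage(self, line_network):
        park = park_at(0.0, 0.0, radius=300.0)
        sa = network_service_area(line_network, park)
        assert sa.contains((290.0, 0.0))
        assert not sa.contains((400.0, 0.0))

    def test_unassigned_radius_rejected(self, line_network):
        park = park_at(0.0, 0.0)
        park.service_radius_m = None
        with pytest.raises(ValueError):
            network_service_area(line_network, park)


class TestSurveyThresholds:
    def test_degenerate_distribution(self):
        bins = SurveyBins(
            midpoints_min=[10, 30, 60],
            shares={(cat, "walking"): [0.0, 1.0, 0.0]
                    for cat in ("comprehensive", "special", "community", "street")},
        )
        assert threshold_from_survey(bins) == {"walking": 30.0}

    def test_max_over_categories_then_round(self):
        # category means 22.5, 18, 20, 24.4 → max 24.4 → rounds to 24
        shares = {
            ("comprehensive", "cycling"): [0.25, 0.75],
            ("special", "cycling"): [0.70, 0.30],
            ("community", "cycling"): [0.50, 0.50],
            ("street", "cycling"): [0.06, 0.94],
        }
        bins = SurveyBins(midpoints_min=[15, 25], shares=shares)
        means = [15 * a + 25 * b for a, b in shares.values()]
        assert means == pytest.approx([22.5, 18, 20, 24.4])
        assert threshold_from_survey(bins) == {"cycling": 24.0}

    def test_half_up_rounding(self):
        bins = SurveyBins(midpoints_min=[20, 25],
                          shares={("community", "walking"): [0.5, 0.5]})
        assert threshold_from_survey(bins) == {"walking": 23.0}  # 22.5 rounds up

    def test_default_mode_parameters(self):
        # stated defaults: 5/15/40 km/h and 30/25/30 min
        assert (DEFAULT_MODES["walking"].speed_kmh,
                DEFAULT_MODES["walking"].t0_min) == (5.0, 30.0)
        assert (DEFAULT_MODES["cycling"].speed_kmh,
                DEFAULT_MODES["cycling"].t0_min) == (15.0, 25.0)
        assert (DEFAULT_MODES["driving"].speed_kmh,
                DEFAULT_MODES["driving"].t0_min) == (40.0, 30.0)

    def test_invalid_shares_rejected(self):
        bins = SurveyBins(midpoints_min=[10, 30],
                          shares={("community", "walking"): [0.6, 0.5]})
        with pytest.raises(ValueError):
            threshold_from_survey(bins)

    def test_invalid_mode_parameters_rejected(self):
        with pytest.raises(ValueError):
            TravelMode("walking", 0.0, 30.0)
        with pytest.raises(ValueError):
            TravelMode("walking", 5.0, -1.0)
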