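import math

import numpy as np
import pytest
from scipy import sparse

from greenreach.equity_stats import (
    build_weights,
    classify_equality,
    classify_gini,
    equality_index,
    gini_pairwise,
    local_moran,
    local_moran_bruteforce,
    lorenz_gini,
)


class TestEqualityIndex:
    def test_cell_at_maximum_access_gets_max_ratio(self):
        E = equality_index([0.004, 0.002], [0.8, 0.1])
        assert E[0] == pytest.approx(0.8)

    def test_zero_access_gives_zero(self):
        E = equality_index([0.0, 0.002], [0.8])
        assert E[0] == 0.0

    def test_direct_evaluation(self):
        # max(R)=0.8, max(a)=0.004, a_i=0.002 → E_i = 0.4
        E = equality_index([0.004, 0.002], [0.8, 0.5])
        assert E[1] == pytest.approx(0.4)

    def test_all_zero_access_is_all_zero(self):
        assert equality_index([0.0, 0.0], [0.8]).tolist() == [0.0, 0.0]


class TestClassification:
    @pytest.mark.parametrize(
        "ei, cls, status, label",
        [
            (0.0, "I", "No supply", "Serious inequality"),
            (0.1, "II", "Very weak", "Serious inequality"),
            (0.25, "III", "Weak", "Relative inequality"),
            (0.3, "III", "Weak", "Relative inequality"),
            (0.6, "IV", "Good", "Equality"),
            (0.75, "V", "Very good", "Relative equality"),
            (0.9, "V", "Very good", "Relative equality"),
            (1.0, "V", "Very good", "Relative equality"),
            (1.2, "VI", "Oversupply", "Serious inequality"),
        ],
    )
    def test_six_class_scheme(self, ei, cls, status, label):
        assert classify_equality(ei) == (cls, status, label)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_equality(-0.1)

    @pytest.mark.parametrize(
        "g, band",
        [
            (0.15, "Absolute equality"),
            (0.25, "Equality"),
            (0.339, "Relatively equality"),
            (0.45, "Low inequality"),
            (0.55, "High inequality"),
        ],
    )
    def test_gini_bands(self, g, band):
        assert classify_gini(g) == band

    def test_gini_band_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_gini(1.2)


class TestLorenzGini:
    def test_uniform_per_capita_gives_zero(self):
        lg = lorenz_gini([10, 20, 30], [1.0, 2.0, 3.0])
        assert lg.gini == pytest.approx(0.0, abs=1e-12)

    def test_two_unit_total_concentration(self):
        lg = lorenz_gini([1, 1], [0.0, 1.0])
        assert lg.gini == pytest.approx(0.5)

    def test_two_unit_partial_concentration(self):
        lg = lorenz_gini([1, 1], [0.2, 0.8])
        assert lg.gini == pytest.approx(0.3)
        assert lg.gini == pytest.approx(gini_pairwise([1, 1], [0.2, 0.8]), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_oracle_on_equal_population_units(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 200))
        x = rng.gamma(1.5, 2.0, size=n)
        lg = lorenz_gini(np.ones(n), x)
        assert lg.gini == pytest.approx(gini_pairwise(np.ones(n), x), abs=1e-9)

    def test_lorenz_curve_monotone_convex_with_exact_endpoints(self):
        rng = np.random.default_rng(5)
        P = rng.uniform(1, 50, size=40)
        X = rng.gamma(1.0, 1.0, size=40) * P
        lg = lorenz_gini(P, X)
        assert lg.P[0] == 0.0 and lg.Q[0] == 0.0
        assert lg.P[-1] == pytest.approx(1.0) and lg.Q[-1] == pytest.approx(1.0)
        assert np.all(np.diff(lg.P) >= -1e-12)
        assert np.all(np.diff(lg.Q) >= -1e-12)
        # ascending per-capita sort puts the curve at or below the diagonal
        assert np.all(lg.Q <= lg.P + 1e-9)
        slopes = np.diff(lg.Q) / np.diff(lg.P)
        assert np.all(np.diff(slopes) >= -1e-9)

    def test_zero_resource_flagged(self):
        with pytest.raises(ValueError):
            lorenz_gini([1, 1], [0.0, 0.0])

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            lorenz_gini([0, 0], [1.0, 1.0])

    def test_literal_formula_differs_on_uniform_allocation(self):
        # the rectangle form yields 1 − 1/n on a uniform allocation, which is
        # why the trapezoid form is the default
        n = 10
        lg = lorenz_gini(np.ones(n), np.ones(n), literal_formula=True)
        assert lg.gini == pytest.approx(1 - 1 / n)


class TestWeights:
    def _grid(self, n):
        rows = [r for r in range(n) for _ in range(n)]
        cols = [c for _ in range(n) for c in range(n)]
        return rows, cols

    def test_queen_center_has_eight_neighbours(self):
        rows, cols = self._grid(3)
        W = build_weights(rows, cols, "queen")
        center = 4
        assert (W[center].toarray() > 0).sum() == 8

    def test_queen_corner_has_three_neighbours(self):
        rows, cols = self._grid(3)
        W = build_weights(rows, cols, "queen")
        assert (W[0].toarray() > 0).sum() == 3

    def test_rook_center_has_four_neighbours(self):
        rows, cols = self._grid(3)
        W = build_weights(rows, cols, "rook")
        assert (W[4].toarray() > 0).sum() == 4

    def test_rows_standardized(self):
        rows, cols = self._grid(4)
        W = build_weights(rows, cols, "queen")
        sums = np.asarray(W.sum(axis=1)).ravel()
        assert np.allclose(sums, 1.0)

    def test_distance_band(self):
        rows, cols = [0, 0, 5], [0, 1, 5]
        coords = [(0.0, 0.0), (100.0, 0.0), (500.0, 500.0)]
        W = build_weights(rows, cols, "distance_band", distance_band=150.0,
                          coords=coords)
        assert W[0, 1] == 1.0
        assert np.asarray(W[2].todense()).sum() == 0.0  # isolate: empty row

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            build_weights([0], [0], "hexagon")


def _lattice_weights(n, scheme="rook"):
    rows = [r for r in range(n) for _ in range(n)]
    cols = [c for _ in range(n) for c in range(n)]
    return build_weights(rows, cols, scheme)


class TestLocalMoran:
    def test_matches_bruteforce_on_random_fields(self):
        rng = np.random.default_rng(21)
        W = _lattice_weights(10, "queen")
        for _ in range(3):
            x = rng.normal(size=100)
            res = local_moran(x, W, permutations=9, seed=1)
            ref = local_moran_bruteforce(x, W)
            assert np.allclose(res.I, ref, atol=1e-10)

    def test_checkerboard_is_negatively_autocorrelated(self):
        n = 4
        x = np.array([(r + c) % 2 for r in range(n) for c in range(n)], float)
        res = local_moran(x, _lattice_weights(n, "rook"), permutations=99, seed=0)
        assert np.all(res.I < 0)

    def test_constant_field_rejected(self):
        with pytest.raises(ValueError):
            local_moran(np.ones(16), _lattice_weights(4), permutations=9)

    def test_homogeneous_blocks_label_hh_and_ll(self):
        # left half high, right half low: interior cells form HH / LL clusters
        n = 8
        rng = np.random.default_rng(2)
        x = np.array(
            [10.0 + rng.normal(0, 0.1) if c < n // 2 else rng.normal(0, 0.1)
             for r in range(n) for c in range(n)]
        )
        res = local_moran(x, _lattice_weights(n, "queen"),
                          permutations=999, seed=42)
        idx = lambda r, c: r * n + c
        hi_interior = [idx(r, c) for r in range(1, n - 1) for c in range(1, 2)]
        lo_interior = [idx(r, c) for r in range(1, n - 1) for c in range(n - 2, n - 1)]
        assert all(res.labels[i] == "HH" for i in hi_interior)
        assert all(res.labels[i] == "LL" for i in lo_interior)

    def test_labels_only_when_significant(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=36)
        res = local_moran(x, _lattice_weights(6), permutations=99, alpha=0.05,
                         seed=3)
        for lbl, p in zip(res.labels, res.p_sim):
            if lbl != "not-significant":
                assert p <= 0.05

    def test_labels_invariant_to_positive_affine_transform(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=49)
        W = _lattice_weights(7, "queen")
        a = local_moran(x, W, permutations=199, seed=5)
        b = local_moran(3.5 * x + 11.0, W, permutations=199, seed=5)
        assert a.labels == b.labels
        assert np.allclose(a.I, b.I, atol=1e-9)

    def test_sum_proportional_to_global_moran(self):
        # Anselin decomposition: Σ I_i = n · (global Moran's I) for
        # row-standardized weights
        rng = np.random.default_rng(33)
        W = _lattice_weights(9, "queen")
        for _ in range(3):
            x = rng.normal(size=81)
            res = local_moran(x, W, permutations=9, seed=0)
            z = x - x.mean()
            s0 = W.sum()
            global_I = (len(x) / s0) * float(z @ (W @ z)) / float(z @ z)
            assert res.I.sum() / len(x) == pytest.approx(global_I, rel=1e-9)
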