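import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spaceanova import (
    ConfigError,
    InsufficientCellsError,
    PointPattern,
    RadiusGrid,
    Window,
    average_curves,
    estimate_K,
    estimate_g,
    estimate_g_kernel,
    simulate_csri,
)
from spaceanova.summaries import SummaryCurve


def brute_force_K(pattern, type_m, type_m2, grid):
    """O(n^2) double-loop oracle for K with edge correction off."""
    A = np.flatnonzero(pattern.types == type_m)
    B = np.flatnonzero(pattern.types == type_m2)
    total = np.zeros(len(grid))
    for l in A:
        for l2 in B:
            if l == l2:
                continue
            d = np.hypot(pattern.x[l] - pattern.x[l2], pattern.y[l] - pattern.y[l2])
            total += d <= grid.r
    return pattern.window.area / (len(A) * len(B)) * total


class TestEstimateK:
    def test_hand_worked_three_cell_example(self):
        pat = PointPattern(
            np.array([0.0, 3.0, 4.0]),
            np.zeros(3),
            np.array(["A", "A", "B"]),
            Window(0, 10, 0, 10),
        )
        grid = RadiusGrid(np.array([0.0, 1.0, 2.0]))
        k = estimate_K(pat, "A", "B", grid, edge="none")
        # only the (3,0)-(4,0) pair lies within distance 2: 100/(2*1) * 1
        assert k.values[2] == pytest.approx(50.0)
        assert k.values[0] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("pair", [("A", "B"), ("A", "A")])
    def test_matches_brute_force_exactly(self, seed, pair):
        pat = simulate_csri(Window(0, 50, 0, 50), {"A": 25, "B": 20}, seed=seed)
        grid = RadiusGrid.from_step(20, 2.0)
        k = estimate_K(pat, *pair, grid, edge="none")
        np.testing.assert_allclose(k.values, brute_force_K(pat, *pair, grid), rtol=0, atol=1e-9)

    def test_K_at_zero_and_monotone(self, csri_pattern, grid100):
        k = estimate_K(csri_pattern, "A", "B", grid100)
        assert k.values[0] == 0.0
        assert np.all(np.diff(k.values) >= 0)

    @pytest.mark.parametrize("edge", ["translation", "isotropic"])
    def test_symmetry_in_pair_order(self, csri_pattern, grid100, edge):
        k1 = estimate_K(csri_pattern, "A", "B", grid100, edge=edge)
        k2 = estimate_K(csri_pattern, "B", "A", grid100, edge=edge)
        np.testing.assert_allclose(k1.values, k2.values, rtol=1e-9, atol=1e-9)

    def test_too_few_cells_raises_missing_signal(self, unit_window, grid100):
        pat = PointPattern(
            np.array([1.0]), np.array([1.0]), np.array(["A"]), unit_window, "im0"
        )
        with pytest.raises(InsufficientCellsError) as exc:
            estimate_K(pat, "A", "B", grid100)
        assert exc.value.pair == ("A", "B")
        assert exc.value.image_id == "im0"
        with pytest.raises(InsufficientCellsError):
            estimate_K(pat, "A", "A", grid100)  # same-type needs >= 2 cells

    def test_csri_K_near_theoretical(self, unit_window):
        grid = RadiusGrid.from_step(50, 1.0)
        vals = []
        for seed in range(10):
            pat = simulate_csri(unit_window, {"A": 2000, "B": 2000}, seed=seed)
            vals.append(estimate_K(pat, "A", "B", grid).values[-1])
        assert np.mean(vals) == pytest.approx(np.pi * 50**2, rel=0.05)


class TestEstimateG:
    def test_exact_quadratic_gives_unity(self, grid100):
        k = SummaryCurve(("A", "B"), "im", grid100, np.pi * grid100.r**2, "K")
        g = estimate_g(k, method="spline")
        assert np.isnan(g.values[0])
        np.testing.assert_allclose(g.values[1:], 1.0, atol=1e-6)
        g_fd = estimate_g(k, method="fd")
        np.testing.assert_allclose(g_fd.values[1:], 1.0, atol=1e-2)

    def test_closed_form_linear_perturbation(self, grid100):
        k = SummaryCurve(("A", "B"), "im", grid100, np.pi * grid100.r**2 + 10 * grid100.r, "K")
        g = estimate_g(k)
        r = grid100.r[1:]
        np.testing.assert_allclose(g.values[1:], 1 + 10 / (2 * np.pi * r), atol=1e-6)
        assert g.values[5] == pytest.approx(1 + 10 / (10 * np.pi), abs=1e-6)

    def test_non_K_input_rejected(self, grid100):
        g = SummaryCurve(("A", "B"), "im", grid100, np.ones(len(grid100)), "g")
        with pytest.raises(ConfigError):
            estimate_g(g)

    def test_csri_calibration_replicate_mean_near_one(self, unit_window, grid100):
        """Mean estimated g over CSRI images stays in [0.95, 1.05] on [10, 100]."""
        acc = np.zeros(len(grid100))
        n = 100
        for seed in range(n):
            pat = simulate_csri(unit_window, {"A": 500, "B": 500}, seed=1000 + seed)
            acc += estimate_g(estimate_K(pat, "A", "B", grid100)).values
        mean_g = acc / n
        sel = grid100.r >= 10
        assert np.all(mean_g[sel] > 0.95) and np.all(mean_g[sel] < 1.05)

    def test_kernel_estimator_agrees_with_differentiation(self, unit_window):
        grid = RadiusGrid.from_step(100, 1.0)
        acc_s = np.zeros(len(grid))
        acc_k = np.zeros(len(grid))
        n = 20
        for seed in range(n):
            pat = simulate_csri(unit_window, {"A": 1000, "B": 1000}, seed=seed)
            acc_s += estimate_g(estimate_K(pat, "A", "B", grid)).values
            acc_k += estimate_g_kernel(pat, "A", "B", grid).values
        sel = grid.r >= 10
        np.testing.assert_allclose(acc_s[sel] / n, acc_k[sel] / n, atol=0.05)


class TestAverageCurves:
    def _const(self, value, grid, weight=1.0):
        return SummaryCurve(("A", "B"), "im", grid, np.full(len(grid), float(value)), "g", weight)

    def test_simple_mean(self, grid100):
        avg = average_curves([self._const(1, grid100), self._const(3, grid100)], "simple")
        np.testing.assert_allclose(avg.values, 2.0)

    def test_weighted_mean(self, grid100):
        avg = average_curves(
            [self._const(1, grid100, 3.0), self._const(3, grid100, 1.0)], "weighted"
        )
        np.testing.assert_allclose(avg.values, 1.5)

    @pytest.mark.parametrize("mode", ["simple", "weighted"])
    def test_single_curve_identity(self, grid100, mode):
        c = self._const(2.5, grid100, 4.0)
        np.testing.assert_allclose(average_curves([c], mode).values, c.values)

    def test_missing_curves_excluded_then_all_missing_raises(self, grid100):
        avg = average_curves([None, self._const(4, grid100)], "simple")
        np.testing.assert_allclose(avg.values, 4.0)
        with pytest.raises(InsufficientCellsError):
            average_curves([None, None])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_property_K_monotone_and_symmetric(seed):
    pat = simulate_csri(Window(0, 200, 0, 200), {"A": 30, "B": 25}, seed=seed)
    grid = RadiusGrid.from_step(50, 5.0)
    kab = estimate_K(pat, "A", "B", grid)
    kba = estimate_K(pat, "B", "A", grid)
    assert np.all(np.diff(kab.values) >= 0)
    np.testing.assert_allclose(kab.values, kba.values, rtol=1e-9, atol=1e-9)
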