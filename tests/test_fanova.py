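import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import f_oneway

from spaceanova import (
    CurveSet,
    DegenerateVarianceError,
    DesignError,
    RadiusGrid,
    gpf_test_mult,
    gpf_test_univ,
    permutation_pvalue,
    pointwise_ss_oneway,
    pointwise_ss_twoway,
)
from spaceanova.fanova import _ss_oneway, _ss_twoway
from spaceanova.summaries import SummaryCurve

GRID = RadiusGrid.from_step(100, 1.0)


def const_curve(value, grid=GRID):
    v = np.full(len(grid), float(value))
    v[0] = np.nan  # g-kind curves are NaN at r = 0
    return SummaryCurve(("A", "B"), "im", grid, v, "g")


def curve_from(values, grid=GRID):
    v = np.concatenate([[np.nan], np.asarray(values, dtype=float)])
    return SummaryCurve(("A", "B"), "im", grid, v, "g")


def build_set(group_values, grid=GRID, avg_mode="simple"):
    """group_values: {group: {subject: [curve-values or scalar per image]}}"""
    entries = []
    for group, subs in group_values.items():
        for subject, images in subs.items():
            for val in images:
                curve = const_curve(val, grid) if np.isscalar(val) else curve_from(val, grid)
                entries.append((group, subject, curve))
    return CurveSet.build(("A", "B"), grid, entries, avg_mode)


class TestPointwiseSS:
    def test_identical_curves_zero_variability(self):
        cs = build_set({"g1": {"s1": [2.0], "s2": [2.0]}, "g2": {"s3": [2.0], "s4": [2.0]}})
        ssg, sse, sst = pointwise_ss_oneway(cs)
        assert np.all(ssg == 0) and np.all(sse == 0) and np.all(sst == 0)

    def test_scalar_anova_oracle(self):
        # constant curves {1, 3} vs {5, 7}: scalar one-way ANOVA gives SSG=16, SSE=4
        cs = build_set({"g1": {"s1": [1.0], "s2": [3.0]}, "g2": {"s3": [5.0], "s4": [7.0]}})
        ssg, sse, sst = pointwise_ss_oneway(cs)
        np.testing.assert_allclose(ssg, 16.0)
        np.testing.assert_allclose(sse, 4.0)
        np.testing.assert_allclose(sst, 20.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(np.float64, (6, 8), elements=st.floats(-50, 50)),
        st.integers(min_value=1, max_value=2),
    )
    def test_oneway_identity_property(self, Y, split):
        gidx = np.array([0] * (2 + split) + [1] * (4 - split))
        ssg, sse, sst = _ss_oneway(Y, gidx)
        np.testing.assert_allclose(sst, ssg + sse, rtol=1e-9, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(arrays(np.float64, (10, 6), elements=st.floats(-50, 50)))
    def test_twoway_identity_property(self, Y):
        # 4 subjects with unequal image counts 2,3,1,4 split across 2 groups
        sidx = np.array([0, 0, 1, 1, 1, 2, 3, 3, 3, 3])
        g_of_s = np.array([0, 0, 1, 1])
        sse, ssb, ssg, sst = _ss_twoway(Y, sidx, g_of_s)
        np.testing.assert_allclose(sst, sse + ssb + ssg, rtol=1e-9, atol=1e-9)
        assert np.all(sse >= -1e-12) and np.all(ssb >= -1e-12) and np.all(ssg >= -1e-12)


class TestUnivariateGPF:
    def test_identical_curves_statistic_zero_p_one(self):
        cs = build_set({"g1": {"s1": [5.0], "s2": [5.0]}, "g2": {"s3": [5.0], "s4": [5.0]}})
        res = gpf_test_univ(cs)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_constant_curves_reduce_to_scalar_anova(self):
        rng = np.random.default_rng(1)
        g1 = rng.normal(0, 1, 6)
        g2 = rng.normal(0.8, 1, 5)
        cs = build_set(
            {
                "g1": {f"s{i}": [v] for i, v in enumerate(g1)},
                "g2": {f"t{i}": [v] for i, v in enumerate(g2)},
            }
        )
        res = gpf_test_univ(cs)
        f_scalar = f_oneway(g1, g2).statistic
        L = GRID.interior[-1] - GRID.interior[0]
        np.testing.assert_allclose(res.statistic, L * f_scalar, rtol=1e-9)

    def test_scale_and_location_invariance(self):
        rng = np.random.default_rng(2)
        vals = {g: {f"{g}s{i}": [rng.normal(size=len(GRID) - 1)] for i in range(4)} for g in ("g1", "g2")}
        res = gpf_test_univ(build_set(vals))
        shift = np.sin(GRID.interior / 7.0)
        transformed = {
            g: {s: [3.5 * imgs[0] + shift] for s, imgs in subs.items()}
            for g, subs in vals.items()
        }
        res2 = gpf_test_univ(build_set(transformed))
        np.testing.assert_allclose(res2.statistic, res.statistic, rtol=1e-9)
        np.testing.assert_allclose(res2.p_value, res.p_value, rtol=1e-6)

    def test_single_group_raises(self):
        with pytest.raises(DesignError):
            gpf_test_univ(build_set({"g1": {"s1": [1.0], "s2": [2.0]}}))

    def test_one_subject_group_untestable(self):
        cs = build_set({"g1": {"s1": [1.0]}, "g2": {"s2": [2.0], "s3": [3.0]}})
        res = gpf_test_univ(cs)
        assert not res.testable and np.isnan(res.p_value)
        assert "fewer than 2 subjects" in res.reason

    def test_degenerate_variance_suggests_permutation(self):
        cs = build_set({"g1": {"s1": [1.0], "s2": [1.0]}, "g2": {"s3": [5.0], "s4": [5.0]}})
        with pytest.raises(DegenerateVarianceError, match="permutation"):
            gpf_test_univ(cs)


class TestMultivariateGPF:
    def _random_set(self, seed, n_imgs=(2, 3, 2, 3), delta=0.0):
        rng = np.random.default_rng(seed)
        vals = {}
        for s in range(4):
            g = "g1" if s < 2 else "g2"
            off = delta if g == "g2" else 0.0
            vals.setdefault(g, {})[f"s{s}"] = [
                rng.normal(off, 1, len(GRID) - 1) for _ in range(n_imgs[s])
            ]
        return build_set(vals)

    def test_identical_curves_statistic_zero(self):
        cs = build_set(
            {"g1": {"s1": [2.0, 2.0], "s2": [2.0]}, "g2": {"s3": [2.0, 2.0], "s4": [2.0]}}
        )
        assert gpf_test_mult(cs).statistic == 0.0

    def test_constant_curves_reduce_to_scalar_twoway(self):
        rng = np.random.default_rng(3)
        layout = {"g1": {"s1": 2, "s2": 3}, "g2": {"s3": 2, "s4": 4}}
        vals, flat, sidx, g_of_s = {}, [], [], []
        s = 0
        for g, subs in layout.items():
            vals[g] = {}
            for sub, n in subs.items():
                imgs = list(rng.normal(0, 1, n))
                vals[g][sub] = imgs
                flat.extend(imgs)
                sidx.extend([s] * n)
                g_of_s.append(0 if g == "g1" else 1)
                s += 1
        res = gpf_test_mult(build_set(vals))
        Y = np.array(flat)[:, None]
        sse, ssb, ssg, sst = _ss_twoway(Y, np.array(sidx), np.array(g_of_s))
        G, N, S = 2, len(flat), 4
        f_scalar = (ssg[0] / (G - 1)) / (sse[0] / (N - S))
        L = GRID.interior[-1] - GRID.interior[0]
        np.testing.assert_allclose(res.statistic, L * f_scalar, rtol=1e-9)
        np.testing.assert_allclose(sst, sse + ssb + ssg, rtol=1e-9)

    def test_all_single_image_subjects_redirects_to_univ(self):
        cs = build_set({"g1": {"s1": [1.0], "s2": [2.0]}, "g2": {"s3": [3.0], "s4": [4.0]}})
        with pytest.raises(DesignError, match="univ"):
            gpf_test_mult(cs)

    def test_ssb_reported_but_statistic_uses_sse_only(self):
        cs = self._random_set(4)
        res = gpf_test_mult(cs)
        assert res.ssb is not None and np.all(res.ssb >= 0)
        sse, ssb, ssg, _ = pointwise_ss_twoway(cs)
        d1, d2 = 1, res.n_images_used - res.n_subjects_used
        expect = np.trapezoid((ssg / d1) / (sse / d2), GRID.interior)
        np.testing.assert_allclose(res.statistic, expect, rtol=1e-9)


class TestPermutationPvalue:
    def test_zero_statistic_gives_p_one(self):
        cs = build_set({"g1": {"s1": [1.0], "s2": [1.0]}, "g2": {"s3": [1.0], "s4": [1.0]}})
        p, obs = permutation_pvalue(cs, "univ", B=99, seed=0)
        assert obs == 0.0
        assert p == 1.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        curves = {f"s{i}": rng.normal(i * 0.5, 1, len(GRID) - 1) for i in range(4)}
        cs = build_set(
            {"g1": {"s0": [curves["s0"]], "s1": [curves["s1"]]},
             "g2": {"s2": [curves["s2"]], "s3": [curves["s3"]]}}
        )
        Y, gidx = cs.univ_arrays()
        from spaceanova.fanova import _integrated_f

        obs = _integrated_f(Y, gidx, "univ", GRID.interior)
        # enumerate all 6 assignments of 4 subjects into two groups of 2
        stats = [
            _integrated_f(Y, np.array(assign), "univ", GRID.interior)
            for assign in set(itertools.permutations([0, 0, 1, 1]))
        ]
        exact = np.mean([s >= obs for s in stats])
        p, _ = permutation_pvalue(cs, "univ", B=4000, seed=1)
        # sampled p converges to the enumeration value (within +1/(B+1) smoothing)
        assert abs(p - exact) < 0.05


class TestCurveSetNaNPolicy:
    def test_isolated_nan_interpolated(self):
        v = np.linspace(1, 2, len(GRID) - 1)
        v[10] = np.nan
        cs = build_set({"g1": {"s1": [v], "s2": [v * 2]}, "g2": {"s3": [v * 3], "s4": [v * 4]}})
        assert cs.n_images == 4
        got = cs.subject_mean("g1", "s1")
        assert np.isfinite(got).all()
        assert got[10] == pytest.approx((got[9] + got[11]) / 2)

    def test_edge_nan_drops_curve_and_subject(self):
        v = np.ones(len(GRID) - 1)
        bad = v.copy()
        bad[0] = np.nan
        cs = build_set({"g1": {"s1": [bad], "s2": [v]}, "g2": {"s3": [v], "s4": [v]}})
        assert any(s == "s1" for _, s, _ in cs.dropped_subjects)
        assert cs.n_subjects == 3
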