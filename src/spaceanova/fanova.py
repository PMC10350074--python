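"""Functional ANOVA on pair-correlation curves across clinical groups.

For one ordered cell-type pair, let Y_gij(r) be the estimated (possibly
envelope-adjusted) g-function of image j of subject i in group g, on a
common radius grid.  Two tests are offered.

Univariate (subject-averaged, one-way).  Each subject is reduced to the
mean curve over its images, Ȳ_gi(r) — the images are treated as replicate
realisations of the subject's point process — and the one-way functional
model Ȳ_gi(r) = μ(r) + α_g(r) + ε_gi(r), ε ~ GP(0, γ), is tested for
H0: α_1 = ... = α_G = 0 with the global pointwise F statistic

    F_univ = ∫ [SSG(r)/(G−1)] / [SSE(r)/(n−G)] dr,

integrated by the trapezoidal rule over (0, R] (g is undefined at r = 0).

Multivariate (image-level, two-way nested).  Every image curve enters
individually under Y_gij(r) = μ(r) + α_g(r) + β_gi(r) + ε_gij(r), with the
pointwise decomposition SST = SSE + SSB + SSG (SSB = between subjects
within groups, weighted by the per-subject image counts n_gi) and

    F_mult = ∫ [SSG(r)/(G−1)] / [SSE(r)/(N−Σ s_g)] dr

over the N image curves.  SSB is reported but does not enter the statistic.

Null p-values come from a two-moment βχ²_d approximation of the integrated
pointwise-F process (moments matched via the estimated residual correlation
ρ̂(r, s); see docs/methods.md) and can be cross-checked with a
subject-level group-relabelling permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConfigError, DegenerateVarianceError, DesignError
from .geometry import RadiusGrid

__all__ = [
    "CurveSet",
    "FanovaResult",
    "pointwise_ss_oneway",
    "pointwise_ss_twoway",
    "gpf_test_univ",
    "gpf_test_mult",
    "permutation_pvalue",
    "results_to_frame",
]


def _clean_interior(values: np.ndarray) -> np.ndarray | None:
    """NaN policy for a curve's interior values: interpolate isolated gaps,
    drop the curve when NaN touches either end."""
    v = np.asarray(values, dtype=float)
    bad = ~np.isfinite(v)
    if not bad.any():
        return v
    if bad[0] or bad[-1] or bad.all():
        return None
    idx = np.arange(v.size)
    v = v.copy()
    v[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
    return v


@dataclass
class CurveSet:
    """Curves for one pair, organised group -> subject -> image curves.

    Holds the interior-grid (r > 0) values only.  Images whose curve is
    missing or un-repairable are dropped (recorded), subjects with no
    retained image are dropped (recorded); testability then requires G >= 2
    groups each retaining >= 2 subjects.
    """

    pair: tuple
    grid: RadiusGrid
    data: dict  # group -> {subject -> list[np.ndarray] interior values}
    weights: dict = field(default_factory=dict)  # group -> {subject -> list[float]}
    avg_mode: str = "simple"
    dropped_images: list = field(default_factory=list)
    dropped_subjects: list = field(default_factory=list)

    @classmethod
    def build(
        cls,
        pair: tuple,
        grid: RadiusGrid,
        entries: Sequence[tuple],
        avg_mode: str = "simple",
    ) -> "CurveSet":
        """Assemble from (group, subject, SummaryCurve-or-None) entries."""
        data: dict = {}
        weights: dict = {}
        dropped_images = []
        for group, subject, curve in entries:
            data.setdefault(group, {}).setdefault(subject, [])
            weights.setdefault(group, {}).setdefault(subject, [])
            if curve is None:
                dropped_images.append((group, subject, None, "missing curve"))
                continue
            if curve.grid != grid:
                raise ConfigError("all curves in a CurveSet must share the grid")
            v = _clean_interior(curve.interior_values)
            if v is None:
                dropped_images.append((group, subject, curve.image_id, "NaN at curve edge"))
                continue
            data[group][subject].append(v)
            weights[group][subject].append(float(curve.weight))
        dropped_subjects = []
        for group in list(data):
            for subject in list(data[group]):
                if not data[group][subject]:
                    dropped_subjects.append((group, subject, "no retained images"))
                    del data[group][subject]
                    del weights[group][subject]
            if not data[group]:
                del data[group]
                del weights[group]
        return cls(pair, grid, data, weights, avg_mode, dropped_images, dropped_subjects)

    @property
    def groups(self) -> list:
        return list(self.data)

    def subjects(self, group) -> list:
        return list(self.data[group])

    @property
    def n_subjects(self) -> int:
        return sum(len(s) for s in self.data.values())

    @property
    def n_images(self) -> int:
        return sum(len(v) for s in self.data.values() for v in s.values())

    def subject_mean(self, group, subject) -> np.ndarray:
        stack = np.vstack(self.data[group][subject])
        if self.avg_mode == "weighted":
            w = np.asarray(self.weights[group][subject], dtype=float)
            return (w[:, None] * stack).sum(axis=0) / w.sum()
        return stack.mean(axis=0)

    def untestable_reason(self) -> str | None:
        if len(self.data) < 2:
            return f"fewer than 2 groups retained ({len(self.data)})"
        small = [g for g, subs in self.data.items() if len(subs) < 2]
        if small:
            return f"group(s) {small} retain fewer than 2 subjects"
        return None

    # ---- matrix views -------------------------------------------------
    def univ_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Subject-mean curve matrix (n_subjects, n_r) and group index."""
        rows, gidx = [], []
        for k, group in enumerate(self.groups):
            for subject in self.data[group]:
                rows.append(self.subject_mean(group, subject))
                gidx.append(k)
        return np.vstack(rows), np.asarray(gidx)

    def mult_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Image curve matrix (N, n_r), subject index, group-of-subject index."""
        rows, sidx, g_of_s = [], [], []
        s = 0
        for k, group in enumerate(self.groups):
            for subject in self.data[group]:
                for v in self.data[group][subject]:
                    rows.append(v)
                    sidx.append(s)
                g_of_s.append(k)
                s += 1
        return np.vstack(rows), np.asarray(sidx), np.asarray(g_of_s)


@dataclass
class FanovaResult:
    """Outcome of one functional ANOVA test for one pair."""

    pair: tuple
    method: str  # "univ" or "mult"
    statistic: float
    beta_hat: float
    d_hat: float
    p_value: float
    r: np.ndarray
    ssg: np.ndarray
    sse: np.ndarray
    ssb: np.ndarray | None = None
    n_subjects_used: int = 0
    n_images_used: int = 0
    perm_p: float | None = None
    n_perm: int = 0
    reason: str | None = None  # set when untestable (p_value is NaN)

    @property
    def testable(self) -> bool:
        return self.reason is None


def _untestable(pair, method, reason, r) -> FanovaResult:
    nan = float("nan")
    z = np.full(r.shape, nan)
    return FanovaResult(pair, method, nan, nan, nan, nan, r, z, z, reason=reason)


# ---------------------------------------------------------------------------
# pointwise sums of squares


def _ss_oneway(Y: np.ndarray, gidx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    grand = Y.mean(axis=0)
    ssg = np.zeros(Y.shape[1])
    sse = np.zeros(Y.shape[1])
    for k in np.unique(gidx):
        Yg = Y[gidx == k]
        mg = Yg.mean(axis=0)
        ssg += Yg.shape[0] * (mg - grand) ** 2
        sse += ((Yg - mg) ** 2).sum(axis=0)
    return ssg, sse, ((Y - grand) ** 2).sum(axis=0)


def _ss_twoway(
    Y: np.ndarray, sidx: np.ndarray, g_of_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise SSE / SSB / SSG / SST of the nested two-way decomposition,
    subject means weighted by their image counts n_gi."""
    n_r = Y.shape[1]
    n_sub = g_of_s.size
    counts = np.bincount(sidx, minlength=n_sub).astype(float)
    sub_sum = np.zeros((n_sub, n_r))
    np.add.at(sub_sum, sidx, Y)
    sub_mean = sub_sum / counts[:, None]
    sse = ((Y - sub_mean[sidx]) ** 2).sum(axis=0)
    grand = Y.mean(axis=0)
    ssb = np.zeros(n_r)
    ssg = np.zeros(n_r)
    for k in np.unique(g_of_s):
        subs = np.flatnonzero(g_of_s == k)
        n_g = counts[subs].sum()
        mg = (counts[subs, None] * sub_mean[subs]).sum(axis=0) / n_g
        ssb += (counts[subs, None] * (sub_mean[subs] - mg) ** 2).sum(axis=0)
        ssg += n_g * (mg - grand) ** 2
    sst = ((Y - grand) ** 2).sum(axis=0)
    return sse, ssb, ssg, sst


def pointwise_ss_oneway(curves: CurveSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(SSG(r), SSE(r), SST(r)) of the one-way model on subject-mean curves.

    The identity SST = SSG + SSE holds pointwise to float precision.
    """
    if any(len(subs) < 1 for subs in curves.data.values()) or not curves.data:
        raise DesignError("every group needs at least one subject")
    Y, gidx = curves.univ_arrays()
    ssg, sse, sst = _ss_oneway(Y, gidx)
    return ssg, sse, sst


def pointwise_ss_twoway(curves: CurveSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(SSE, SSB, SSG, SST) of the nested two-way model on image curves."""
    Y, sidx, g_of_s = curves.mult_arrays()
    return _ss_twoway(Y, sidx, g_of_s)


# ---------------------------------------------------------------------------
# integrated F statistics and the beta * chi^2 null approximation


def _pointwise_f(ssg: np.ndarray, sse: np.ndarray, d1: int, d2: int) -> np.ndarray:
    num = ssg / d1
    den = sse / d2
    f = np.zeros_like(num)
    ok = den > 0
    f[ok] = num[ok] / den[ok]
    bad = (~ok) & (num > 0)
    if bad.any():
        raise DegenerateVarianceError(
            "pointwise error variance is zero where group variation is not; "
            "use the permutation p-value instead"
        )
    return f


def _integrated_f(Y, design, method: str, r: np.ndarray) -> float:
    if method == "univ":
        gidx = design
        G = np.unique(gidx).size
        ssg, sse, _ = _ss_oneway(Y, gidx)
        d1, d2 = G - 1, Y.shape[0] - G
    else:
        sidx, g_of_s = design
        G = np.unique(g_of_s).size
        sse, _, ssg, _ = _ss_twoway(Y, sidx, g_of_s)
        d1, d2 = G - 1, Y.shape[0] - g_of_s.size
    return float(np.trapezoid(_pointwise_f(ssg, sse, d1, d2), r))


def _beta_chi2_pvalue(
    f_stat: float, resid: np.ndarray, d1: int, d2: int, r: np.ndarray
) -> tuple[float, float, float]:
    """Two-moment βχ²_d approximation of the integrated pointwise-F null.

    Pointwise, F(r) ~ F_{d1, d2} under H0; the integral's mean and variance
    follow from the F moments and the residual correlation ρ̂(r, s):
    E = L·d2/(d2−2), V = 2·c·∬ρ²(r,s) dr ds with
    c = (d2/(d2−2))²(d1+d2−2)/(d1(d2−4)).  Then d = 2E²/V, β = V/(2E) and
    p = P(χ²_d > F/β).  For d2 <= 4 (F variance undefined) the χ² form of
    the standardized between-group integral is matched instead.

    ρ̂² carries an upward sampling bias of order (1−ρ²)²/d2 per entry which,
    summed over the grid², badly inflates V when curves decorrelate fast in
    r; the approximately unbiased estimator ρ̂² − (1−ρ̂²)²/d2 is integrated
    instead (unclipped — clipping entries at zero would restore the bias),
    and the double integral is floored at its exact diagonal contribution.
    """
    L = r[-1] - r[0]
    gamma = resid.T @ resid / d2
    var = np.diag(gamma).copy()
    if np.any(var <= 0):
        raise DegenerateVarianceError(
            "residual variance vanishes at some radii; use the permutation p-value"
        )
    sd = np.sqrt(var)
    rho = gamma / np.outer(sd, sd)
    rho2 = rho**2 - (1 - rho**2) ** 2 / d2
    # trapezoid weights for the double integral over [r0, R]^2
    wts = np.full(r.size, r[1] - r[0])
    wts[0] = wts[-1] = 0.5 * (r[1] - r[0])
    I2 = float(wts @ rho2 @ wts)
    I2 = max(I2, float((wts**2).sum()))  # diagonal (rho = 1) lower bound
    if d2 > 4:
        E = L * d2 / (d2 - 2)
        c = (d2 / (d2 - 2)) ** 2 * (d1 + d2 - 2) / (d1 * (d2 - 4))
        V = 2 * c * I2
        S = f_stat
    else:  # chi-square moment matching on T = d1 * F
        E = d1 * L
        V = 2 * d1 * I2
        S = d1 * f_stat
    beta = V / (2 * E)
    d = 2 * E**2 / V
    p = float(chi2.sf(S / beta, d))
    return beta, d, p


def gpf_test_univ(curves: CurveSet) -> FanovaResult:
    """Global pointwise F test on subject-averaged curves (one-way FANOVA)."""
    r = curves.grid.interior
    if len(curves.data) < 2:
        raise DesignError("univariate FANOVA needs G >= 2 groups")
    reason = curves.untestable_reason()
    if reason is not None:
        return _untestable(curves.pair, "univ", reason, r)
    Y, gidx = curves.univ_arrays()
    G = len(curves.groups)
    n = Y.shape[0]
    if n - G < 1:
        return _untestable(curves.pair, "univ", "no within-group degrees of freedom", r)
    ssg, sse, _ = _ss_oneway(Y, gidx)
    d1, d2 = G - 1, n - G
    if not np.any(ssg > 0):  # identical group means everywhere
        return FanovaResult(
            curves.pair, "univ", 0.0, float("nan"), float("nan"), 1.0, r, ssg, sse,
            n_subjects_used=n, n_images_used=curves.n_images,
        )
    f_stat = float(np.trapezoid(_pointwise_f(ssg, sse, d1, d2), r))
    means = np.vstack([Y[gidx == k].mean(axis=0) for k in range(G)])
    resid = Y - means[gidx]
    beta, d, p = _beta_chi2_pvalue(f_stat, resid, d1, d2, r)
    return FanovaResult(
        curves.pair, "univ", f_stat, beta, d, p, r, ssg, sse,
        n_subjects_used=n, n_images_used=curves.n_images,
    )


def gpf_test_mult(curves: CurveSet) -> FanovaResult:
    """Global pointwise F test on image-level curves (nested two-way FANOVA)."""
    r = curves.grid.interior
    if len(curves.data) < 2:
        raise DesignError("multivariate FANOVA needs G >= 2 groups")
    reason = curves.untestable_reason()
    if reason is not None:
        return _untestable(curves.pair, "mult", reason, r)
    Y, sidx, g_of_s = curves.mult_arrays()
    N = Y.shape[0]
    S = g_of_s.size
    G = len(curves.groups)
    if N == S:
        raise DesignError(
            "every subject has exactly one image: SSE is identically zero; "
            "use gpf_test_univ"
        )
    sse, ssb, ssg, _ = _ss_twoway(Y, sidx, g_of_s)
    d1, d2 = G - 1, N - S
    if not np.any(ssg > 0):
        return FanovaResult(
            curves.pair, "mult", 0.0, float("nan"), float("nan"), 1.0, r, ssg, sse, ssb,
            n_subjects_used=S, n_images_used=N,
        )
    f_stat = float(np.trapezoid(_pointwise_f(ssg, sse, d1, d2), r))
    counts = np.bincount(sidx, minlength=S).astype(float)
    sub_sum = np.zeros((S, Y.shape[1]))
    np.add.at(sub_sum, sidx, Y)
    resid = Y - (sub_sum / counts[:, None])[sidx]
    beta, d, p = _beta_chi2_pvalue(f_stat, resid, d1, d2, r)
    return FanovaResult(
        curves.pair, "mult", f_stat, beta, d, p, r, ssg, sse, ssb,
        n_subjects_used=S, n_images_used=N,
    )


def permutation_pvalue(
    curves: CurveSet, method: str = "univ", B: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Group-relabelling permutation p-value for either statistic.

    Whole subjects (with all their image curves) are reassigned to groups
    uniformly at random with group sizes fixed; p = (1 + #{F_perm >= F_obs})
    / (B + 1).  Returns (p, observed statistic).
    """
    if B < 1:
        raise ConfigError("permutation count B must be >= 1")
    if method not in ("univ", "mult"):
        raise ConfigError(f"unknown method {method!r}")
    r = curves.grid.interior
    rng = np.random.default_rng(seed)
    if method == "univ":
        Y, gidx = curves.univ_arrays()
        obs = _integrated_f(Y, gidx, "univ", r)
        count = 0
        for _ in range(B):
            count += _integrated_f(Y, rng.permutation(gidx), "univ", r) >= obs
    else:
        Y, sidx, g_of_s = curves.mult_arrays()
        obs = _integrated_f(Y, (sidx, g_of_s), "mult", r)
        count = 0
        for _ in range(B):
            perm = rng.permutation(g_of_s)
            count += _integrated_f(Y, (sidx, perm), "mult", r) >= obs
    return (1 + count) / (B + 1), obs


def results_to_frame(results: Sequence[FanovaResult]) -> pd.DataFrame:
    """Long-format export of test outcomes."""
    rows = []
    for res in results:
        rows.append(
            {
                "type_m": res.pair[0],
                "type_m2": res.pair[1],
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "beta_hat": res.beta_hat,
                "d_hat": res.d_hat,
                "n_subjects_used": res.n_subjects_used,
                "n_images_used": res.n_images_used,
                "perm_p": res.perm_p,
                "reason": res.reason,
            }
        )
    return pd.DataFrame(rows)
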