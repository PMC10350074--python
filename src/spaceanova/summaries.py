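"""Bivariate spatial summary functions: Ripley's cross-type K and the pair
correlation function g.

For an ordered cell-type pair (m, m') in an image with window W,

    K̂_mm'(r) = |W| / (l_m l_m') · Σ_l Σ_l' 1{d_ll' <= r} · e(l, l'),

with l_m, l_m' the per-type cell counts, d_ll' the inter-cell distance and
e an edge-correction weight (translation correction by default; exact for
rectangles).  Self-pairs are excluded when m = m'.  Under complete spatial
randomness and independence (CSRI) K_mm'(r) = πr² for every pair.

The pair correlation function g_mm'(r) = K'_mm'(r) / (2πr) equals 1 under
CSRI and, unlike K, is not cumulative: it isolates structure at distance
exactly r, which is what the downstream functional ANOVA compares across
clinical groups.  ĝ is obtained by numerical differentiation of K̂ — a
cubic-spline fit differentiated analytically (default), centred finite
differences, or a direct kernel estimator as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .errors import ConfigError, InsufficientCellsError
from .geometry import PairData, PointPattern, RadiusGrid

__all__ = [
    "SummaryCurve",
    "estimate_K",
    "estimate_g",
    "estimate_g_kernel",
    "average_curves",
    "curves_to_frame",
]

G_METHODS = ("spline", "fd")


@dataclass
class SummaryCurve:
    """One summary function of radius for one image and ordered type pair."""

    pair: tuple
    image_id: str
    grid: RadiusGrid
    values: np.ndarray
    kind: str  # "K", "g" or "g-adjusted"
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.r.shape:
            raise ConfigError("curve values must align with the radius grid")
        if self.weight < 0:
            raise ConfigError("curve weight must be nonnegative")

    @property
    def interior_values(self) -> np.ndarray:
        """Values on (0, R] — the FANOVA integration domain."""
        return self.values[1:]


def estimate_K(
    pattern: PointPattern,
    type_m,
    type_m2,
    grid: RadiusGrid,
    edge: str = "translation",
    pair_data: PairData | None = None,
    min_count: int = 1,
) -> SummaryCurve:
    """Estimate the bivariate K function for the ordered pair (m, m').

    Raises :class:`InsufficientCellsError` when the image has fewer than
    ``min_count`` cells of either type (and always when m = m' with fewer
    than two cells): the curve is missing, not zero.

    ``pair_data`` lets callers reuse one KD-tree pair enumeration across
    many pairs and label permutations of the same image.
    """
    lm = pattern.count(type_m)
    lm2 = pattern.count(type_m2)
    needed = max(min_count, 2 if type_m == type_m2 else 1)
    if lm < needed or lm2 < needed:
        raise InsufficientCellsError((type_m, type_m2), pattern.image_id)
    if pair_data is None:
        pair_data = PairData(pattern, grid.rmax, edge)
    values = pair_data.k_values(pattern.types, type_m, type_m2, grid)
    return SummaryCurve((type_m, type_m2), pattern.image_id, grid, values, "K", weight=lm * lm2)


def _g_from_k(r: np.ndarray, k: np.ndarray, method: str, lam: float | None) -> np.ndarray:
    if method == "spline":
        if lam is None:
            dk = CubicSpline(r, k)(r, 1)
        else:
            dk = make_smoothing_spline(r, k, lam=lam).derivative()(r)
    elif method == "fd":
        dk = np.gradient(k, r)
    else:
        raise ConfigError(f"unknown g method {method!r}; choose from {G_METHODS}")
    with np.errstate(divide="ignore", invalid="ignore"):
        g = dk / (2 * np.pi * r)
    g[r == 0] = np.nan
    return g


def estimate_g(
    Kcurve: SummaryCurve, method: str = "spline", lam: float | None = None
) -> SummaryCurve:
    """Derive ĝ = K̂'(r) / (2πr) by numerical differentiation of a K curve.

    ``method="spline"`` fits a cubic spline to K̂ and differentiates it
    analytically (interpolating by default; pass ``lam`` for a smoothing
    penalty); ``method="fd"`` uses centred finite differences.  The value at
    r = 0 is undefined and stored as NaN.
    """
    if Kcurve.kind != "K":
        raise ConfigError(f"estimate_g needs a K curve, got kind {Kcurve.kind!r}")
    g = _g_from_k(Kcurve.grid.r, Kcurve.values, method, lam)
    return replace(Kcurve, values=g, kind="g")


def estimate_g_kernel(
    pattern: PointPattern,
    type_m,
    type_m2,
    grid: RadiusGrid,
    edge: str = "translation",
    bandwidth: float | None = None,
    pair_data: PairData | None = None,
) -> SummaryCurve:
    """Direct kernel estimator of g (Epanechnikov kernel) — a cross-check for
    the differentiation route, not the default.

    ĝ(r) = |W| / (l_m l_m' 2πr) Σ pairs e(l,l') k_h(d − r), with the Stoyan
    rule bandwidth h = 0.15/sqrt(λ̂_m') when none is given.
    """
    lm = pattern.count(type_m)
    lm2 = pattern.count(type_m2)
    needed = 2 if type_m == type_m2 else 1
    if lm < needed or lm2 < needed:
        raise InsufficientCellsError((type_m, type_m2), pattern.image_id)
    if bandwidth is None:
        lam2 = lm2 / pattern.window.area
        bandwidth = 0.15 / np.sqrt(lam2)
    if pair_data is None:
        pair_data = PairData(pattern, grid.rmax + 2 * bandwidth, edge)
    li = pattern.types[pair_data.i]
    lj = pattern.types[pair_data.j]
    if type_m == type_m2:
        mask = (li == type_m) & (lj == type_m)
        mult = 2.0
    else:
        mask = ((li == type_m) & (lj == type_m2)) | ((li == type_m2) & (lj == type_m))
        mult = 1.0
    d = pair_data.d[mask]
    w = pair_data.w[mask]
    r = grid.r[:, None]
    u = (d[None, :] - r) / bandwidth
    kern = np.where(np.abs(u) < 1, 0.75 * (1 - u**2) / bandwidth, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = pattern.window.area / (lm * lm2) * mult * (kern * w[None, :]).sum(axis=1) / (
            2 * np.pi * grid.r
        )
    g[grid.r == 0] = np.nan
    return SummaryCurve((type_m, type_m2), pattern.image_id, grid, g, "g", weight=lm * lm2)


def average_curves(curves: Sequence[SummaryCurve], mode: str = "simple") -> SummaryCurve:
    """Pointwise average of an image set's curves for one subject and pair.

    ``mode="simple"`` is the arithmetic mean; ``mode="weighted"`` weights
    each curve by its stored weight (the number of contributing ordered cell
    pairs l_m·l_m' by construction), normalised to sum to one.  Curves that
    are missing (None) are excluded before averaging.
    """
    kept = [c for c in curves if c is not None]
    if not kept:
        raise InsufficientCellsError(("?", "?"), "?", "all curves missing for this subject")
    grid = kept[0].grid
    if any(c.grid != grid for c in kept):
        raise ConfigError("curves must share one radius grid")
    if any(c.kind != kept[0].kind for c in kept):
        raise ConfigError("cannot average curves of different kinds")
    stack = np.vstack([c.values for c in kept])
    if mode == "simple":
        values = stack.mean(axis=0)
    elif mode == "weighted":
        w = np.array([c.weight for c in kept], dtype=float)
        if w.sum() <= 0:
            raise ConfigError("weighted averaging needs a positive total weight")
        values = (w[:, None] * stack).sum(axis=0) / w.sum()
    else:
        raise ConfigError(f"unknown averaging mode {mode!r}")
    return SummaryCurve(
        kept[0].pair, "+".join(str(c.image_id) for c in kept), grid, values, kept[0].kind,
        weight=float(sum(c.weight for c in kept)),
    )


def curves_to_frame(curves: Sequence[SummaryCurve]) -> pd.DataFrame:
    """Long-format export: pair, image_id, r, value, kind."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "type_m": c.pair[0],
                    "type_m2": c.pair[1],
                    "image_id": c.image_id,
                    "r": c.grid.r,
                    "value": c.values,
                    "kind": c.kind,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
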