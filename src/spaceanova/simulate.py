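"""Study-structured synthetic data generators.

Three generators produce data with the full study hierarchy (two groups of
subjects, three equal-area images per subject cut from a 1000 x 1000
super-image), mirroring how a large tissue section is profiled as several
non-overlapping fields of view:

* ``simulate_csri`` — the null model itself: each type's cells i.i.d.
  uniform, types independent (homogeneous multitype Poisson conditioned on
  counts).
* ``simulate_mixed_poisson`` — type A homogeneous Poisson; type B an
  inhomogeneous Poisson whose intensity is the disc-kernel density of the
  type-A cells (disc size Sigma, group 2 uses Sigma + Sigma_difference).
  Smaller Sigma means tighter B-around-A co-localisation.
* ``simulate_neyman_scott`` — a multitype Neyman-Scott cluster process:
  Poisson parents, Poisson(3) offspring per parent uniform in a disc of
  radius Radius (group 2: Radius + Radius_difference), parents deleted,
  offspring labelled A/B with probability 1/2.  Larger Radius means looser
  clusters.

``punch_holes`` deletes every cell inside randomly placed discs, emulating
missing tissue regions; the hole geometry is recorded on the window for
diagnostics but estimation still assumes the full rectangle — precisely
the stressor the permutation-envelope adjustment addresses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import fftconvolve

from .data import CellTable
from .errors import ConfigError
from .geometry import PointPattern, Window

__all__ = [
    "SimulationConfig",
    "simulate_csri",
    "simulate_mixed_poisson",
    "simulate_neyman_scott",
    "punch_holes",
    "write_manifest",
]

SUPER_SIZE = 1000.0


@dataclass(frozen=True)
class SimulationConfig:
    """Shared configuration of the subject-level simulation frameworks.

    Defaults are the study conditions used throughout: N = 50 subjects in
    two equal groups, three images per subject from a 1000 x 1000
    super-image, per-type (or parent) counts uniform on [200, 400].
    """

    n_subjects: int = 50
    images_per_subject: int = 3
    super_size: float = SUPER_SIZE
    count_range: tuple[int, int] = (200, 400)
    # mixed-Poisson parameters
    sigma: float = 40.0
    sigma_difference: float = 0.0
    # Neyman-Scott parameters
    radius: float = 30.0
    radius_difference: float = 0.0
    offspring_mean: float = 3.0
    # hole scenario
    n_holes: int = 5
    hole_radius_range: tuple[float, float] = (50.0, 150.0)
    holes_group: str | None = None  # e.g. "g1": punch that group's super-images
    kde_resolution: int = 256
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_subjects % 2:
            raise ConfigError("n_subjects must be an even integer >= 2 (two equal groups)")
        if self.images_per_subject < 1:
            raise ConfigError("images_per_subject must be >= 1")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.radius <= 0:
            raise ConfigError("radius must be positive")
        if self.count_range[0] > self.count_range[1] or self.count_range[0] < 0:
            raise ConfigError("count_range must be a nondecreasing nonnegative pair")
        if self.n_holes < 0:
            raise ConfigError("n_holes must be >= 0")

    def group_of(self, subject_index: int) -> str:
        """First half of subjects -> g1, second half -> g2."""
        return "g1" if subject_index < self.n_subjects // 2 else "g2"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_csri(
    window: Window, counts: dict, seed=None
) -> PointPattern:
    """Complete spatial randomness and independence: per-type i.i.d. uniform
    points, types independent.  ``counts`` maps type label -> cell count."""
    rng = _rng(seed)
    xs, ys, labels = [], [], []
    for label, n in counts.items():
        if n < 0:
            raise ConfigError("counts must be nonnegative")
        xs.append(rng.uniform(window.xmin, window.xmax, size=n))
        ys.append(rng.uniform(window.ymin, window.ymax, size=n))
        labels.append(np.repeat(label, n))
    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        t = np.concatenate(labels)
    else:
        x = y = np.empty(0)
        t = np.empty(0, dtype=object)
    return PointPattern(x, y, t, window)


def punch_holes(
    pattern: PointPattern, n_holes: int, radius_range: tuple[float, float], seed=None
) -> PointPattern:
    """Delete every cell lying inside ``n_holes`` random discs.

    Disc centres are uniform in the pattern's window, radii uniform in
    ``radius_range``; the discs are recorded on the returned pattern's
    window (diagnostics only — estimators keep assuming the full rectangle).
    """
    if n_holes < 0:
        raise ConfigError("n_holes must be >= 0")
    if n_holes == 0:
        return pattern
    rng = _rng(seed)
    w = pattern.window
    cx = rng.uniform(w.xmin, w.xmax, size=n_holes)
    cy = rng.uniform(w.ymin, w.ymax, size=n_holes)
    rad = rng.uniform(radius_range[0], radius_range[1], size=n_holes)
    keep = np.ones(pattern.n, dtype=bool)
    for k in range(n_holes):
        keep &= np.hypot(pattern.x - cx[k], pattern.y - cy[k]) >= rad[k]
    holes = w.holes + tuple((float(cx[k]), float(cy[k]), float(rad[k])) for k in range(n_holes))
    new_window = Window(w.xmin, w.xmax, w.ymin, w.ymax, holes)
    return PointPattern(
        pattern.x[keep], pattern.y[keep], pattern.types[keep], new_window, pattern.image_id
    )


def _split_bands(
    pattern: PointPattern, n_bands: int, subject_id: str, group: str
) -> tuple[list[dict], dict]:
    """Cut a super-image into horizontal equal-area bands; band coordinates
    are re-expressed relative to the band origin."""
    w = pattern.window
    band_h = w.height / n_bands
    rows: list[dict] = []
    windows: dict = {}
    for k in range(n_bands):
        lo = w.ymin + k * band_h
        hi = w.ymin + (k + 1) * band_h
        if k == n_bands - 1:
            mask = (pattern.y >= lo) & (pattern.y <= hi)
        else:
            mask = (pattern.y >= lo) & (pattern.y < hi)
        image_id = f"{subject_id}_im{k}"
        windows[image_id] = Window(0.0, w.width, 0.0, band_h)
        for x, y, t in zip(pattern.x[mask], pattern.y[mask] - lo, pattern.types[mask]):
            rows.append(
                {
                    "x": float(x),
                    "y": float(y),
                    "cell_type": t,
                    "image_id": image_id,
                    "subject_id": subject_id,
                    "group": group,
                }
            )
    return rows, windows


def _assemble_table(all_rows: list[dict], all_windows: dict) -> CellTable:
    df = pd.DataFrame(
        all_rows, columns=["x", "y", "cell_type", "image_id", "subject_id", "group"]
    )
    return CellTable.from_dataframe(
        df, allow_duplicates=True, cell_types=["A", "B"], groups=["g1", "g2"],
        windows=all_windows,
    )


def _maybe_punch(pattern: PointPattern, group: str, config: SimulationConfig, rng):
    if config.holes_group is not None and group == config.holes_group:
        return punch_holes(pattern, config.n_holes, config.hole_radius_range, rng)
    return pattern


def _disc_kernel_density(
    x: np.ndarray, y: np.ndarray, window: Window, disc_radius: float, resolution: int
):
    """Disc-kernel density of a point set on a lattice, as an interpolator.

    The density at z is the number of points within ``disc_radius`` of z
    divided by the disc area, evaluated on a resolution² lattice by
    convolving the binned counts with a disc indicator.
    """
    edges_x = np.linspace(window.xmin, window.xmax, resolution + 1)
    edges_y = np.linspace(window.ymin, window.ymax, resolution + 1)
    hist, _, _ = np.histogram2d(x, y, bins=[edges_x, edges_y])
    dx = (window.xmax - window.xmin) / resolution
    dy = (window.ymax - window.ymin) / resolution
    nk = max(1, int(np.ceil(disc_radius / min(dx, dy))))
    kx = (np.arange(-nk, nk + 1) * dx)[:, None]
    ky = (np.arange(-nk, nk + 1) * dy)[None, :]
    disc = (kx**2 + ky**2 <= disc_radius**2).astype(float) / (np.pi * disc_radius**2)
    dens = fftconvolve(hist, disc, mode="same")
    dens = np.clip(dens, 0.0, None)
    cx = 0.5 * (edges_x[:-1] + edges_x[1:])
    cy = 0.5 * (edges_y[:-1] + edges_y[1:])
    interp = RegularGridInterpolator(
        (cx, cy), dens, method="linear", bounds_error=False, fill_value=None
    )
    return interp, float(dens.max())


def _thin_inhomogeneous(
    n: int, window: Window, interp, fmax: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw exactly n points from the normalized lattice density by
    rejection sampling against its maximum."""
    if n == 0 or fmax <= 0:
        return np.empty(0), np.empty(0)
    xs, ys = [], []
    got = 0
    while got < n:
        m = max(4 * (n - got), 256)
        cand_x = rng.uniform(window.xmin, window.xmax, size=m)
        cand_y = rng.uniform(window.ymin, window.ymax, size=m)
        f = np.clip(interp(np.column_stack([cand_x, cand_y])), 0.0, None)
        accept = rng.uniform(0.0, fmax, size=m) < f
        xs.append(cand_x[accept])
        ys.append(cand_y[accept])
        got += int(accept.sum())
    x = np.concatenate(xs)[:n]
    y = np.concatenate(ys)[:n]
    return x, y


def simulate_mixed_poisson(config: SimulationConfig, seed=None) -> CellTable:
    """Mixed-Poisson framework: B cells track the local density of A cells.

    Per subject: J_A, J_B uniform integers in ``count_range``; type A a
    homogeneous Poisson process with expected count J_A on the super-image;
    type B an inhomogeneous Poisson process with expected count J_B and
    intensity proportional to the disc-kernel density of A (disc size Sigma
    for group 1, Sigma + Sigma_difference for group 2).  The super-image is
    split into ``images_per_subject`` equal-area bands.
    """
    rng = _rng(seed if seed is not None else config.seed)
    w = Window(0.0, config.super_size, 0.0, config.super_size)
    lo, hi = config.count_range
    all_rows: list[dict] = []
    all_windows: dict = {}
    for s in range(config.n_subjects):
        subject_id = f"s{s:03d}"
        group = config.group_of(s)
        disc = config.sigma if group == "g1" else config.sigma + config.sigma_difference
        if disc <= 0:
            raise ConfigError("sigma + sigma_difference must be positive")
        JA = int(rng.integers(lo, hi + 1))
        JB = int(rng.integers(lo, hi + 1))
        nA = rng.poisson(JA)
        ax = rng.uniform(w.xmin, w.xmax, size=nA)
        ay = rng.uniform(w.ymin, w.ymax, size=nA)
        interp, fmax = _disc_kernel_density(ax, ay, w, disc, config.kde_resolution)
        nB = rng.poisson(JB)
        bx, by = _thin_inhomogeneous(nB, w, interp, fmax, rng)
        x = np.concatenate([ax, bx])
        y = np.concatenate([ay, by])
        t = np.concatenate([np.repeat("A", nA), np.repeat("B", bx.size)])
        pattern = _maybe_punch(PointPattern(x, y, t, w), group, config, rng)
        rows, windows = _split_bands(pattern, config.images_per_subject, subject_id, group)
        all_rows.extend(rows)
        all_windows.update(windows)
    return _assemble_table(all_rows, all_windows)


def simulate_neyman_scott(
    config: SimulationConfig, seed=None, return_debug: bool = False
):
    """Multitype Neyman-Scott cluster process per super-image.

    Parents: homogeneous Poisson with expected count J ~ U{count_range}.
    Each parent spawns Poisson(offspring_mean) offspring uniform in a disc
    of radius Radius (group 1) or Radius + Radius_difference (group 2);
    parents are deleted, offspring falling outside the super-image are
    discarded, and each offspring is labelled A or B with probability 1/2.

    With ``return_debug`` the per-subject parent coordinates and each
    offspring's parent index and displacement are also returned.
    """
    rng = _rng(seed if seed is not None else config.seed)
    w = Window(0.0, config.super_size, 0.0, config.super_size)
    lo, hi = config.count_range
    all_rows: list[dict] = []
    all_windows: dict = {}
    debug: dict = {}
    for s in range(config.n_subjects):
        subject_id = f"s{s:03d}"
        group = config.group_of(s)
        disc = config.radius if group == "g1" else config.radius + config.radius_difference
        if disc <= 0:
            raise ConfigError("radius + radius_difference must be positive")
        J = int(rng.integers(lo, hi + 1))
        n_par = rng.poisson(J)
        px = rng.uniform(w.xmin, w.xmax, size=n_par)
        py = rng.uniform(w.ymin, w.ymax, size=n_par)
        n_off = rng.poisson(config.offspring_mean, size=n_par)
        parent_idx = np.repeat(np.arange(n_par), n_off)
        total = parent_idx.size
        rr = disc * np.sqrt(rng.uniform(size=total))
        th = rng.uniform(0.0, 2 * np.pi, size=total)
        ox = px[parent_idx] + rr * np.cos(th)
        oy = py[parent_idx] + rr * np.sin(th)
        inside = w.contains(ox, oy)
        labels = np.where(rng.uniform(size=total) < 0.5, "A", "B")
        pattern = PointPattern(ox[inside], oy[inside], labels[inside], w)
        if return_debug:
            debug[subject_id] = {
                "parents": np.column_stack([px, py]),
                "parent_index": parent_idx[inside],
                "offspring": np.column_stack([ox[inside], oy[inside]]),
                "cluster_radius": disc,
            }
        pattern = _maybe_punch(pattern, group, config, rng)
        rows, windows = _split_bands(pattern, config.images_per_subject, subject_id, group)
        all_rows.extend(rows)
        all_windows.update(windows)
    table = _assemble_table(all_rows, all_windows)
    return (table, debug) if return_debug else table


def write_manifest(config: SimulationConfig, path: str | Path, extra: dict | None = None) -> None:
    """Record the generating configuration and seed next to exported data."""
    payload = dataclasses.asdict(config)
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
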