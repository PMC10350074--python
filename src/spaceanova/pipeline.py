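"""All-pairs orchestration: cell table in, p-value matrices out.

For every ordered cell-type pair (m, m') the pipeline estimates a per-image
g curve (permutation-envelope adjusted by default), averages curves within
subject for the univariate test, and runs both functional ANOVA variants.
Pairs that cannot be tested (too few cells in too many images) are flagged
with a reason, never silently numbered.

One seed governs every stochastic step; per-image permutation streams are
spawned from it independently of iteration order, so two runs with the same
seed produce identical result tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CellTable, summarize_design
from .errors import DesignError, InsufficientCellsError
from .fanova import CurveSet, FanovaResult, gpf_test_mult, gpf_test_univ, permutation_pvalue
from .geometry import PairData, RadiusGrid
from .permutation import EnvelopeSpec, adjust_g
from .summaries import SummaryCurve, _g_from_k, estimate_K, estimate_g

__all__ = ["PipelineConfig", "PairwiseResults", "run_pairwise", "bh_adjust"]


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; defaults follow the real-data conventions
    (radius 0..100 step 1, translation correction, P = 50 permutations)."""

    radius_max: float = 100.0
    radius_step: float = 1.0
    edge: str = "translation"
    adjust: bool = True
    permutations: int = 50
    shared_permutations: bool = True  # one permutation set per image, shared by pairs
    g_method: str = "spline"
    lam: float | None = None
    avg_mode: str = "simple"
    min_count: int = 1
    seed: int | None = None
    upper_triangle_only: bool = False
    pairs: tuple | None = None  # restrict to these ordered pairs (default: all)
    perm_pvalue_B: int = 0  # >0 adds subject-permutation p-values
    methods: tuple[str, ...] = ("univ", "mult")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        payload.update(overrides)
        return cls(**payload)


@dataclass
class PairwiseResults:
    """All-pairs test outcomes plus the per-pair curve sets for plotting."""

    cell_types: list
    results: dict  # (m, m') -> {method -> FanovaResult}
    curve_sets: dict  # (m, m') -> CurveSet
    config: PipelineConfig
    kind: str  # "g" or "g-adjusted"

    def p_matrix(self, method: str = "univ") -> pd.DataFrame:
        M = len(self.cell_types)
        mat = np.full((M, M), np.nan)
        for (m, m2), bym in self.results.items():
            if method in bym:
                mat[self.cell_types.index(m), self.cell_types.index(m2)] = bym[method].p_value
        return pd.DataFrame(mat, index=self.cell_types, columns=self.cell_types)

    def neglog10_matrix(self, method: str = "univ") -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            return -np.log10(self.p_matrix(method))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (m, m2), bym in self.results.items():
            for method, res in bym.items():
                rows.append(
                    {
                        "type_m": m,
                        "type_m2": m2,
                        "method": method,
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
        df = pd.DataFrame(rows)
        if len(df):
            df["p_bh"] = np.nan
            for method in df["method"].unique():
                mask = (df["method"] == method) & df["p_value"].notna()
                df.loc[mask, "p_bh"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
        return df

    def save(self, outdir: str | Path) -> dict:
        """Write results.csv, curves.csv and a manifest; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"results": outdir / "results.csv", "curves": outdir / "curves.csv",
                 "manifest": outdir / "manifest.json"}
        self.to_frame().to_csv(paths["results"], index=False)
        frames = []
        for (m, m2), cs in self.curve_sets.items():
            for group in cs.groups:
                for subject in cs.subjects(group):
                    frames.append(
                        pd.DataFrame(
                            {
                                "type_m": m, "type_m2": m2, "group": group,
                                "subject_id": subject, "r": cs.grid.interior,
                                "value": cs.subject_mean(group, subject),
                                "kind": self.kind,
                            }
                        )
                    )
        pd.concat(frames, ignore_index=True).to_csv(paths["curves"], index=False)
        manifest = dataclasses.asdict(self.config)
        manifest["cell_types"] = self.cell_types
        manifest["curve_kind"] = self.kind
        paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        return paths


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported as an extra column;
    raw p-values remain the primary output)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _ordered_pairs(cell_types, upper_only: bool):
    if upper_only:
        return [(m, m2) for i, m in enumerate(cell_types) for m2 in cell_types[i:]]
    return list(product(cell_types, repeat=2))


def run_pairwise(table: CellTable, config: PipelineConfig = PipelineConfig()) -> PairwiseResults:
    """Run the full analysis for every ordered pair of cell types."""
    design = summarize_design(table)
    if design.n_groups < 2:
        raise DesignError("pairwise testing needs G >= 2 groups")
    grid = RadiusGrid.from_step(config.radius_max, config.radius_step)
    if config.pairs is not None:
        pairs = [tuple(p) for p in config.pairs]
    else:
        pairs = _ordered_pairs(table.cell_types, config.upper_triangle_only)
    meta = table.image_meta()
    image_ids = meta["image_id"].tolist()
    seed_seq = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    image_seeds = seed_seq.spawn(len(image_ids))

    curves: dict = {pair: [] for pair in pairs}
    for img_pos, row in meta.iterrows():
        image_id = row["image_id"]
        pattern = table.pattern(image_id)
        pair_data = PairData(pattern, grid.rmax, config.edge)
        perms = None
        if config.adjust:
            rng = np.random.default_rng(image_seeds[img_pos])
            if config.shared_permutations:
                perms = [rng.permutation(pattern.types) for _ in range(config.permutations)]
        for pair in pairs:
            try:
                if config.adjust:
                    if perms is not None:
                        kcurve = estimate_K(
                            pattern, *pair, grid, config.edge, pair_data, config.min_count
                        )
                        g_obs = _g_from_k(grid.r, kcurve.values, config.g_method, config.lam)
                        acc = np.zeros_like(g_obs)
                        for labels in perms:
                            kp = pair_data.k_values(labels, *pair, grid)
                            acc += _g_from_k(grid.r, kp, config.g_method, config.lam) - g_obs
                        curve = SummaryCurve(
                            pair, pattern.image_id, grid, -acc / len(perms),
                            "g-adjusted", weight=kcurve.weight,
                        )
                    else:
                        curve = adjust_g(
                            pattern, pair, grid,
                            EnvelopeSpec(config.permutations), config.edge,
                            config.g_method, config.lam, pair_data, rng=rng,
                            min_count=config.min_count,
                        )
                else:
                    kcurve = estimate_K(
                        pattern, *pair, grid, config.edge, pair_data, config.min_count
                    )
                    curve = estimate_g(kcurve, config.g_method, config.lam)
            except InsufficientCellsError:
                curve = None
            curves[pair].append((row["group"], row["subject_id"], curve))

    results: dict = {}
    curve_sets: dict = {}
    perm_seeds = seed_seq.spawn(len(pairs) + len(image_ids))[len(image_ids):]
    for pair_pos, pair in enumerate(pairs):
        cs = CurveSet.build(pair, grid, curves[pair], config.avg_mode)
        curve_sets[pair] = cs
        bym: dict = {}
        for method in config.methods:
            test = gpf_test_univ if method == "univ" else gpf_test_mult
            try:
                res = test(cs)
            except DesignError as exc:
                res = FanovaResult(
                    pair, method, float("nan"), float("nan"), float("nan"),
                    float("nan"), grid.interior,
                    np.full(grid.interior.shape, np.nan),
                    np.full(grid.interior.shape, np.nan), reason=str(exc),
                )
            if config.perm_pvalue_B > 0 and res.testable:
                child = np.random.default_rng(perm_seeds[pair_pos])
                res.perm_p, _ = permutation_pvalue(
                    cs, method, config.perm_pvalue_B, child
                )
                res.n_perm = config.perm_pvalue_B
            bym[method] = res
        results[pair] = bym
    return PairwiseResults(
        list(table.cell_types), results, curve_sets, config,
        "g-adjusted" if config.adjust else "g",
    )
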