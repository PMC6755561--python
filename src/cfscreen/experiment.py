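"""Experimental protocol: repeated stratified splits, grid search, binning.

The evaluation protocol runs four independent 70:30 per-target stratified
shuffle splits; on each, the chosen collaborative-filtering method is fit on
the training matrix and its predictions for every target's validation
ligands are scored with AUC, BEDROC (alpha=20) and EF (1%). Per-target
results carry the iteration index and the target's training-assay-count bin,
so performance can be summarized as a function of how much training data a
target has — the regime below 100 training assays is where implicit
(assay-only) methods earn their keep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import factorization, neighborhood
from .data import ASSAY_COUNT_BIN_LABELS, BioactivityMatrix, assay_count_bins, stratified_split
from .metrics import MetricConfig, evaluate_target

__all__ = [
    "ExperimentConfig",
    "run_iterations",
    "grid_search",
    "bin_summary",
    "compare_methods",
    "DEFAULT_FACTOR_GRID",
    "DEFAULT_REG_GRID",
    "DEFAULT_STEP_GRID",
    "DEFAULT_THRESHOLD_GRID",
]

# Grid ranges mirrored from the published hyperparameter search.
DEFAULT_FACTOR_GRID = tuple(range(5, 61, 5))
DEFAULT_REG_GRID = tuple(float(x) for x in np.logspace(-7, -1, 7))
DEFAULT_STEP_GRID = tuple(float(x) for x in np.logspace(-3, -1, 3))
DEFAULT_THRESHOLD_GRID = tuple(float(x) for x in np.logspace(-7, -1, 7))


@dataclass
class ExperimentConfig:
    """One protocol run: method, hyperparameters, split and metric settings."""

    method: str = "mf"  # "mf" | "neighborhood"
    hyper: dict = field(default_factory=dict)
    n_iterations: int = 4
    validation_fraction: float = 0.3
    metric_config: MetricConfig = field(default_factory=MetricConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("mf", "neighborhood"):
            raise ValueError(f"unknown method {self.method!r}")


def _fit_and_score(
    matrix: BioactivityMatrix, config: ExperimentConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, "BioactivityMatrix", dict[str, str]]:
    split = stratified_split(matrix, config.validation_fraction, seed=seed)
    val = split.validation
    if config.method == "mf":
        hyper = dict(config.hyper)
        hyper.setdefault("seed", seed)
        model, _ = factorization.fit(split.train, **hyper)
        scores = factorization.predict_pairs(model, val.rows, val.cols)
        if model.mode == "multilevel":
            scores = -scores
    else:
        model = neighborhood.NeighborhoodModel(split.train, **config.hyper)
        scores, _ = neighborhood.predict_pairs(model, val.rows, val.cols)
    return scores, val.labels, split, assay_count_bins(split.train)


def run_iterations(matrix: BioactivityMatrix, config: ExperimentConfig) -> pd.DataFrame:
    """Run the repeated-split protocol; one row per (iteration, target).

    Iteration i uses seed ``master_seed + i`` for its split and model fit, so
    the whole table is reproducible from the config alone. Undefined metrics
    are NaN with ``*_defined`` flags.
    """
    frames = []
    for i in range(1, config.n_iterations + 1):
        seed_i = config.master_seed + i
        scores, labels, split, bins = _fit_and_score(matrix, config, seed_i)
        val = split.validation
        train_counts = np.zeros(split.train.n_targets, dtype=np.int64)
        np.add.at(train_counts, split.train.rows, 1)
        rows = []
        for t, (cols, truth) in val.entries_by_target.items():
            mask = val.rows == t
            rec = evaluate_target(cols, scores[mask], labels[mask] == 1.0, config.metric_config)
            rec.update(
                iteration=i,
                target_id=str(val.targets[t]),
                n_train_assays=int(train_counts[t]),
                bin=bins[str(val.targets[t])],
            )
            rows.append(rec)
        frames.append(pd.DataFrame(rows))
    table = pd.concat(frames, ignore_index=True)
    front = ["iteration", "target_id", "n_train_assays", "bin", "N", "n_actives"]
    return table[front + [c for c in table.columns if c not in front]]


def grid_search(
    matrix: BioactivityMatrix,
    config: ExperimentConfig,
    grids: dict[str, list],
    criterion: str = "ef",
    n_iterations: int = 1,
    max_combinations: int | None = None,
) -> pd.DataFrame:
    """Evaluate hyperparameter combinations; mean metrics per combo, sorted.

    The Cartesian product of ``grids`` is evaluated (optionally a seeded
    random subset of ``max_combinations``) with ``n_iterations`` splits each,
    and combinations are ranked by the mean of ``criterion`` over targets
    with defined values.
    """
    if not grids:
        raise ValueError("grids must be non-empty")
    names = sorted(grids)
    combos: list[dict] = [{}]
    for name in names:
        if not grids[name]:
            raise ValueError(f"grid for {name!r} is empty")
        combos = [{**c, name: v} for c in combos for v in grids[name]]
    if max_combinations is not None and len(combos) > max_combinations:
        rng = np.random.default_rng(config.master_seed)
        combos = [combos[k] for k in rng.choice(len(combos), max_combinations, replace=False)]
    records = []
    for combo in combos:
        cfg = replace(config, hyper={**config.hyper, **combo}, n_iterations=n_iterations)
        table = run_iterations(matrix, cfg)
        rec = dict(combo)
        for metric in ("auc", "bedroc", "ef"):
            rec[f"mean_{metric}"] = float(table[metric].mean())
        records.append(rec)
    out = pd.DataFrame(records).sort_values(f"mean_{criterion}", ascending=False)
    return out.reset_index(drop=True)


def bin_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per assay-count bin: mean, standard error and target count per metric.

    Undefined (NaN) metric values are excluded; empty bins are omitted.
    """
    if table.empty:
        raise ValueError("empty metric table")
    rows = []
    for bin_label in ASSAY_COUNT_BIN_LABELS:
        sub = table[table["bin"] == bin_label]
        if sub.empty:
            continue
        rec: dict = {"bin": bin_label, "n_rows": len(sub)}
        for metric in ("auc", "bedroc", "ef"):
            vals = sub[metric].dropna()
            rec[f"{metric}_mean"] = float(vals.mean()) if len(vals) else np.nan
            rec[f"{metric}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
            rec[f"{metric}_n"] = int(len(vals))
        rows.append(rec)
    return pd.DataFrame(rows)


def compare_methods(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric: str = "bedroc",
    bin_label: str | None = None,
) -> dict:
    """Two-tailed t-test between two methods' per-target metric values."""
    a = table_a if bin_label is None else table_a[table_a["bin"] == bin_label]
    b = table_b if bin_label is None else table_b[table_b["bin"] == bin_label]
    va = a[metric].dropna().to_numpy()
    vb = b[metric].dropna().to_numpy()
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("not enough defined values for a t-test")
    t, p = stats.ttest_ind(va, vb)
    return {
        "mean_a": float(va.mean()),
        "mean_b": float(vb.mean()),
        "n_a": len(va),
        "n_b": len(vb),
        "t": float(t),
        "p": float(p),
    }
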