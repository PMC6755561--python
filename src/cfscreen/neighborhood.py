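"""Memory-based (neighborhood) collaborative filtering over targets.

A target's unknown affinity for a ligand is predicted as the unweighted mean
of the labels given to that ligand by *similar* targets, where similarity is
computed between matrix rows over their co-rated support (the ligands both
targets have labelled) and a target counts as a neighbor when its similarity
reaches a threshold tau. Pairs whose similarity is undefined (fewer than two
co-rated ligands, or a constant row under Pearson) yield NaN sentinels that
can never pass the threshold. When no neighbor exists the prediction falls
back to the global training active rate, flagged as a cold start.

Defaults (Pearson, tau = 1e-2) are the best-performing configuration from
the hyperparameter search on the real screening data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .data import BioactivityMatrix

__all__ = [
    "NeighborhoodModel",
    "NO_OVERLAP",
    "DEGENERATE",
    "row_similarity",
    "neighbors",
    "predict",
    "predict_pairs",
]


class _Sentinel(float):
    """A NaN carrying a reason; NaN comparisons guarantee it never passes tau."""

    def __new__(cls, reason: str):
        obj = super().__new__(cls, float("nan"))
        obj.reason = reason
        return obj

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<similarity undefined: {self.reason}>"


NO_OVERLAP = _Sentinel("no overlap")
DEGENERATE = _Sentinel("degenerate")

_MIN_SUPPORT = 2  # Pearson is undefined below this; applied to all metrics


@dataclass
class NeighborhoodModel:
    train: BioactivityMatrix
    metric: str = "pearson"
    threshold: float = 1e-2
    weighted: bool = False  # similarity-weighted mean instead of plain mean

    def __post_init__(self) -> None:
        if self.metric not in ("pearson", "cosine", "jaccard"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @cached_property
    def dense(self) -> np.ndarray:
        """Row labels with NaN at unobserved entries."""
        return self.train.to_dense(fill=np.nan)

    @cached_property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.dense)

    @cached_property
    def global_active_rate(self) -> float:
        return float(self.train.labels.mean()) if self.train.n_observed else 0.0

    @cached_property
    def raters_by_ligand(self) -> dict[int, np.ndarray]:
        out: dict[int, np.ndarray] = {}
        order = np.argsort(self.train.cols, kind="stable")
        cols = self.train.cols[order]
        rows = self.train.rows[order]
        bounds = np.searchsorted(cols, np.arange(self.train.n_ligands + 1))
        for l in range(self.train.n_ligands):
            lo, hi = bounds[l], bounds[l + 1]
            if lo < hi:
                out[l] = np.sort(rows[lo:hi])
        return out


def row_similarity(model: NeighborhoodModel, u: int, v: int) -> float:
    """Similarity between two target rows over their co-rated ligands.

    Returns NO_OVERLAP when fewer than two ligands are co-rated and
    DEGENERATE when the metric is undefined on the support (zero variance
    under Pearson, a zero vector under cosine, empty union under jaccard).
    """
    if u == v:
        raise ValueError("row_similarity requires distinct targets")
    common = model.observed[u] & model.observed[v]
    if common.sum() < _MIN_SUPPORT:
        return NO_OVERLAP
    a = model.dense[u, common]
    b = model.dense[v, common]
    if model.metric == "pearson":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return DEGENERATE
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))
    if model.metric == "cosine":
        na = np.sqrt(a @ a)
        nb = np.sqrt(b @ b)
        if na == 0 or nb == 0:
            return DEGENERATE
        return float(a @ b / (na * nb))
    # jaccard on binarized labels (active sets)
    xa = a > 0
    xb = b > 0
    union = int((xa | xb).sum())
    if union == 0:
        return DEGENERATE
    return float((xa & xb).sum() / union)


def neighbors(model: NeighborhoodModel, u0: int, i: int) -> list[int]:
    """Targets other than u0 that labelled ligand i and are similar enough."""
    out = []
    for u in model.raters_by_ligand.get(i, ()):
        if u == u0:
            continue
        if row_similarity(model, u0, u) >= model.threshold:  # NaN sentinels fail
            out.append(int(u))
    return out


def predict(
    model: NeighborhoodModel, u0: int, i: int, return_flag: bool = False
) -> float | tuple[float, bool]:
    """Mean neighbor label for (u0, i); global active rate on cold start."""
    U = neighbors(model, u0, i)
    if not U:
        score, fallback = model.global_active_rate, True
    elif model.weighted:
        sims = np.array([row_similarity(model, u0, u) for u in U])
        w = np.abs(sims)
        labels = model.dense[U, i]
        score = float((sims / w.sum()) @ labels) if w.sum() > 0 else float(labels.mean())
        fallback = False
    else:
        score, fallback = float(model.dense[U, i].mean()), False
    return (score, fallback) if return_flag else score


def predict_pairs(
    model: NeighborhoodModel, rows: np.ndarray, cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized prediction for many (target, ligand) pairs.

    Precomputes each queried target's similarity row once; returns scores
    and a cold-start fallback flag per pair.
    """
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    scores = np.empty(len(rows), dtype=np.float64)
    flags = np.zeros(len(rows), dtype=bool)
    sim_cache: dict[int, np.ndarray] = {}
    for k, (u0, i) in enumerate(zip(rows, cols)):
        sims = sim_cache.get(u0)
        if sims is None:
            sims = np.full(model.train.n_targets, np.nan)
            for v in range(model.train.n_targets):
                if v != u0:
                    sims[v] = row_similarity(model, u0, v)
            sim_cache[int(u0)] = sims
        raters = model.raters_by_ligand.get(int(i))
        if raters is None:
            U = np.empty(0, dtype=np.int64)
        else:
            raters = raters[raters != u0]
            with np.errstate(invalid="ignore"):
                U = raters[sims[raters] >= model.threshold]
        if len(U) == 0:
            scores[k] = model.global_active_rate
            flags[k] = True
        elif model.weighted:
            w = sims[U]
            scores[k] = float((w / np.abs(w).sum()) @ model.dense[U, i])
        else:
            scores[k] = float(model.dense[U, i].mean())
    return scores, flags
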