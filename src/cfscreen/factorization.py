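"""Latent-factor collaborative filtering by regularized SGD matrix factorization.

Known affinities a_{t,l} between target t and ligand l are modelled as the
dot product p_t . q_l of f-dimensional latent factor vectors, learned by
minimizing the regularized squared error

    sum_{(t,l) in observed} (a_{t,l} - p_t . q_l)^2
        + lambda * (||p_t||^2 + ||q_l||^2)

with stochastic gradient descent over the observed pairs, in a seeded
shuffled order each epoch. Because only a tiny fraction of the matrix is
observed, training is complemented by *adaptive negative sampling*: for each
target, after its positives in an epoch, unobserved ligands are pooled at
random, scored with the current model, and the highest-scoring candidate is
trained as inactive. This pushes down the most confidently wrong
predictions and speeds convergence.

Ranking a target's candidates by p_t . q_l is the screening output; the
learned rows of P and columns of Q double as *implicit fingerprints* —
descriptors of targets and ligands derived purely from assay outcomes, with
no molecular structure involved.

Defaults (f=50, lambda=1e-3, step size 1e-3) are the best configuration
from the hyperparameter grid search on the real screening data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .data import BioactivityMatrix
from .metrics import RankedList

__all__ = [
    "FactorModel",
    "DivergenceError",
    "init_factors",
    "predict",
    "predict_pairs",
    "sgd_step",
    "sample_adaptive_negative",
    "fit",
    "rank_ligands",
    "extract_implicit_fingerprints",
    "save_model",
    "load_model",
]

INIT_SCALE = 0.1


class DivergenceError(RuntimeError):
    """SGD produced non-finite factors; retry with a smaller step size."""


@dataclass
class FactorModel:
    """Latent factors P (targets x f) and Q (f x ligands) plus hyperparameters."""

    P: np.ndarray  # (T, f)
    Q: np.ndarray  # (f, L)
    n_factors: int
    regularization: float = 1e-3
    step_size: float = 1e-3
    n_epochs: int = 50
    negatives_per_positive: int = 1
    candidate_pool_size: int = 100
    seed: int = 0
    mode: str = "binary"
    target_ids: np.ndarray | None = None
    ligand_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.P.shape[1] != self.n_factors or self.Q.shape[0] != self.n_factors:
            raise ValueError("factor matrices inconsistent with n_factors")

    @property
    def n_targets(self) -> int:
        return self.P.shape[0]

    @property
    def n_ligands(self) -> int:
        return self.Q.shape[1]


def init_factors(T: int, L: int, f: int, seed: int = 0) -> FactorModel:
    """Zero-mean Gaussian initialization with scale 0.1/sqrt(f)."""
    if T < 1 or L < 1 or f < 1:
        raise ValueError("T, L and f must be positive")
    rng = np.random.default_rng(seed)
    scale = INIT_SCALE / np.sqrt(f)
    return FactorModel(
        P=rng.normal(0.0, scale, size=(T, f)),
        Q=rng.normal(0.0, scale, size=(f, L)),
        n_factors=f,
        seed=seed,
    )


def predict(model: FactorModel, t: int, l: int) -> float:
    """Predicted affinity p_t . q_l."""
    if not (0 <= t < model.n_targets and 0 <= l < model.n_ligands):
        raise IndexError(f"pair ({t}, {l}) out of range")
    return float(model.P[t] @ model.Q[:, l])


def predict_pairs(model: FactorModel, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    return np.einsum("ij,ji->i", model.P[rows], model.Q[:, cols])


def sgd_step(model: FactorModel, t: int, l: int, a: float) -> None:
    """One in-place gradient step on the pair (t, l) with observed label a.

    Both vectors are updated simultaneously from their pre-update values:
    with e = a - p_t.q_l,  p_t += eta*(e*q_l - lambda*p_t) and
    q_l += eta*(e*p_t - lambda*q_l).
    """
    eta, lam = model.step_size, model.regularization
    p = model.P[t]
    q = model.Q[:, l]
    with np.errstate(over="ignore", invalid="ignore"):
        e = a - p @ q
        p_new = p + eta * (e * q - lam * p)
        q_new = q + eta * (e * p - lam * q)
    if not (np.isfinite(p_new).all() and np.isfinite(q_new).all()):
        raise DivergenceError(
            f"non-finite factors at pair ({t}, {l}); reduce step_size (eta={eta})"
        )
    model.P[t] = p_new
    model.Q[:, l] = q_new


def sample_adaptive_negative(
    model: FactorModel, t: int, candidates: np.ndarray
) -> int:
    """Pick the unobserved ligand the current model scores highest for t.

    Ties break toward the lowest ligand index. The caller trains the chosen
    pair as inactive in the following step.
    """
    candidates = np.sort(np.asarray(candidates, dtype=np.int64))
    if len(candidates) == 0:
        raise ValueError("no negatives available")
    scores = model.P[t] @ model.Q[:, candidates]
    return int(candidates[int(np.argmax(scores))])  # argmax -> first max = lowest index


def _positive_label_mask(labels: np.ndarray, mode: str) -> np.ndarray:
    # Binary: active = 1. Multilevel: labels 1-2 are sub-100 nM binders.
    return labels == 1.0 if mode == "binary" else labels <= 2.0


@njit(cache=True)
def _sweep_observed(P, Q, rows, cols, labels, order, eta, lam):
    """One SGD pass over the observed pairs in the given order (in place)."""
    f = P.shape[1]
    for idx in order:
        t = rows[idx]
        l = cols[idx]
        e = labels[idx]
        for j in range(f):
            e -= P[t, j] * Q[j, l]
        for j in range(f):
            pj = P[t, j]
            qj = Q[j, l]
            P[t, j] = pj + eta * (e * qj - lam * pj)
            Q[j, l] = qj + eta * (e * pj - lam * qj)


@njit(cache=True)
def _sweep_negatives(P, Q, t, pools, neg_label, eta, lam):
    """Adaptive negatives for one target: argmax over each (sorted) pool row,
    lowest ligand index on ties, then an SGD step at the inactive label."""
    f = P.shape[1]
    for i in range(pools.shape[0]):
        best = pools[i, 0]
        best_score = -1.0e300
        for k in range(pools.shape[1]):
            l = pools[i, k]
            s = 0.0
            for j in range(f):
                s += P[t, j] * Q[j, l]
            if s > best_score:  # strict: first (lowest-index) max wins
                best_score = s
                best = l
        e = neg_label - best_score
        for j in range(f):
            pj = P[t, j]
            qj = Q[j, best]
            P[t, j] = pj + eta * (e * qj - lam * pj)
            Q[j, best] = qj + eta * (e * pj - lam * qj)


def fit(
    train: BioactivityMatrix,
    n_factors: int = 50,
    regularization: float = 1e-3,
    step_size: float = 1e-3,
    n_epochs: int = 50,
    negatives_per_positive: int = 1,
    candidate_pool_size: int = 100,
    seed: int = 0,
    early_stop_tol: float | None = None,
    early_stop_window: int = 3,
) -> tuple[FactorModel, pd.DataFrame]:
    """Fit latent factors to a training matrix by SGD with adaptive negatives.

    Each epoch visits every observed pair once in a seeded shuffled order,
    then, per target, draws ``negatives_per_positive`` adaptive negatives for
    each of its positive labels from a fresh random pool of at most
    ``candidate_pool_size`` unobserved ligands, training each at the inactive
    label (0 in binary mode, 4 in multilevel mode). Returns the model and a
    per-epoch trace of the regularized objective over observed pairs and the
    number of negatives used. With ``early_stop_tol`` set, training stops
    once the relative objective change stays below it for
    ``early_stop_window`` consecutive epochs.
    """
    if train.n_observed == 0:
        raise ValueError("training matrix has no observed entries")
    rng = np.random.default_rng(seed)
    model = init_factors(train.n_targets, train.n_ligands, n_factors, seed=seed)
    model.regularization = regularization
    model.step_size = step_size
    model.n_epochs = n_epochs
    model.negatives_per_positive = negatives_per_positive
    model.candidate_pool_size = candidate_pool_size
    model.mode = train.mode
    model.target_ids = train.targets
    model.ligand_ids = train.ligands

    rows, cols, labels = train.rows, train.cols, train.labels
    negative_label = 0.0 if train.mode == "binary" else 4.0
    pos_mask = _positive_label_mask(labels, train.mode)
    n_pos_by_target = np.zeros(train.n_targets, dtype=np.int64)
    np.add.at(n_pos_by_target, rows[pos_mask], 1)
    unobserved = {
        t: np.setdiff1d(
            np.arange(train.n_ligands),
            train.entries_by_target[t][0] if t in train.entries_by_target else (),
        )
        for t in range(train.n_targets)
    }

    trace: list[dict] = []
    P, Q = model.P, model.Q
    eta, lam = step_size, regularization
    rows_c = np.ascontiguousarray(rows, dtype=np.int64)
    cols_c = np.ascontiguousarray(cols, dtype=np.int64)
    labels_c = np.ascontiguousarray(labels, dtype=np.float64)
    neg_targets = [
        t
        for t in range(train.n_targets)
        if n_pos_by_target[t] > 0 and len(unobserved[t]) > 0
    ]
    for epoch in range(n_epochs):
        order = rng.permutation(train.n_observed)
        _sweep_observed(P, Q, rows_c, cols_c, labels_c, order, eta, lam)
        n_negatives = 0
        if negatives_per_positive > 0:
            for t in neg_targets:
                pool_all = unobserved[t]
                m = negatives_per_positive * int(n_pos_by_target[t])
                if len(pool_all) > candidate_pool_size:
                    picks = rng.integers(0, len(pool_all), size=(m, candidate_pool_size))
                    pools = np.sort(pool_all[picks], axis=1)
                else:
                    pools = np.tile(np.sort(pool_all), (m, 1))
                _sweep_negatives(P, Q, t, pools, negative_label, eta, lam)
                n_negatives += m
        if not (np.isfinite(P).all() and np.isfinite(Q).all()):
            raise DivergenceError(f"non-finite factors after epoch {epoch}; reduce step_size")
        preds = np.einsum("ij,ji->i", P[rows], Q[:, cols])
        sq = float(np.mean((labels - preds) ** 2))
        reg = lam * float(
            np.mean(np.sum(P[rows] ** 2, axis=1) + np.sum(Q[:, cols] ** 2, axis=0))
        )
        trace.append(
            {"epoch": epoch + 1, "objective": sq + reg, "mse": sq, "n_negatives": n_negatives}
        )
        if early_stop_tol is not None and len(trace) > early_stop_window:
            recent = [r["objective"] for r in trace[-(early_stop_window + 1):]]
            rel = [
                abs(recent[i + 1] - recent[i]) / max(abs(recent[i]), 1e-12)
                for i in range(early_stop_window)
            ]
            if max(rel) < early_stop_tol:
                break
    return model, pd.DataFrame(trace)


def rank_ligands(
    model: FactorModel, t: int, candidates: np.ndarray, truths: np.ndarray | None = None
) -> RankedList:
    """Rank candidate ligands for target t by predicted affinity.

    Descending score in binary mode; ascending in multilevel mode, where a
    lower predicted label means stronger binding. Ties break toward the
    lowest ligand index.
    """
    candidates = np.asarray(candidates, dtype=np.int64)
    if len(candidates) == 0:
        raise ValueError("no candidates")
    scores = model.P[t] @ model.Q[:, candidates]
    if model.mode == "multilevel":
        scores = -scores
    if truths is None:
        truths = np.zeros(len(candidates), dtype=bool)
    return RankedList.from_scores(candidates, scores, truths)


def extract_implicit_fingerprints(
    model: FactorModel,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Latent factors as f-dimensional descriptors of targets and ligands."""
    t_ids = (
        model.target_ids
        if model.target_ids is not None
        else np.array([str(i) for i in range(model.n_targets)], dtype=object)
    )
    l_ids = (
        model.ligand_ids
        if model.ligand_ids is not None
        else np.array([str(i) for i in range(model.n_ligands)], dtype=object)
    )
    targets = {str(t_ids[t]): model.P[t].copy() for t in range(model.n_targets)}
    ligands = {str(l_ids[l]): model.Q[:, l].copy() for l in range(model.n_ligands)}
    return targets, ligands


def save_model(model: FactorModel, path: str | Path) -> None:
    """Serialize to an .npz archive (factors, id maps, hyperparameters)."""
    meta = {
        "n_factors": model.n_factors,
        "regularization": model.regularization,
        "step_size": model.step_size,
        "n_epochs": model.n_epochs,
        "negatives_per_positive": model.negatives_per_positive,
        "candidate_pool_size": model.candidate_pool_size,
        "seed": model.seed,
        "mode": model.mode,
    }
    np.savez(
        path,
        P=model.P,
        Q=model.Q,
        target_ids=np.asarray(
            model.target_ids if model.target_ids is not None else [], dtype=str
        ),
        ligand_ids=np.asarray(
            model.ligand_ids if model.ligand_ids is not None else [], dtype=str
        ),
        meta=np.array(json.dumps(meta)),
    )


def load_model(path: str | Path) -> FactorModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        t_ids = npz["target_ids"].astype(object)
        l_ids = npz["ligand_ids"].astype(object)
        return FactorModel(
            P=npz["P"],
            Q=npz["Q"],
            target_ids=t_ids if len(t_ids) else None,
            ligand_ids=l_ids if len(l_ids) else None,
            **meta,
        )


def export_fingerprints_csv(fingerprints: dict[str, np.ndarray], path: str | Path) -> None:
    """Write id, v1..vf rows; round-trips bit-exactly via repr precision."""
    with open(path, "w") as fh:
        for key, vec in fingerprints.items():
            fh.write(key + "," + ",".join(repr(float(x)) for x in vec) + "\n")


def read_fingerprints_csv(path: str | Path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split(",")
            out[parts[0]] = np.array([float(x) for x in parts[1:]], dtype=np.float64)
    return out
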