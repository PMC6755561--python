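"""Asymmetric Validation Embedding (AVE) bias from binary ligand fingerprints.

Benchmark scores in ligand-based screening are inflated when validation
ligands sit unusually close (in fingerprint space) to training ligands of
the same class — the split is then partly testing memorization. The AVE
bias quantifies this per target as

    B = [H(Va, Ta) - H(Va, Ti)] + [H(Vi, Ti) - H(Vi, Ta)]

where Va/Vi are the validation actives/inactives, Ta/Ti the training
actives/inactives, and H(V, S) measures how *clumped* the ligands of V are
among those of S: for each v in V take its nearest-neighbor Tanimoto
distance to S, threshold it over a uniform grid in (0, 1], and average the
indicators over ligands and thresholds. B near 0 means no redundancy bias;
strongly positive B means validation ligands clump with same-class training
ligands, making the benchmark too easy; negative B marks splits that are
harder than a random draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SplitPair

__all__ = [
    "BiasInput",
    "UndefinedBias",
    "DEFAULT_THRESHOLDS",
    "tanimoto_similarity",
    "pairwise_tanimoto",
    "clumping_H",
    "ave_bias",
    "bias_per_target",
    "bias_performance_correlation",
]

#: Default threshold grid: t = 0.01, 0.02, ..., 1.00.
DEFAULT_THRESHOLDS = np.arange(1, 101) * 0.01


class UndefinedBias(ValueError):
    """B is undefined (no validation ligands at all)."""


def tanimoto_similarity(x: np.ndarray, y: np.ndarray, zero_zero: float = 1.0) -> float:
    """|x AND y| / |x OR y| on binary vectors; two all-zero vectors -> ``zero_zero``."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"bit-length mismatch: {x.shape} vs {y.shape}")
    union = int((x | y).sum())
    if union == 0:
        return zero_zero
    return float((x & y).sum() / union)


def pairwise_tanimoto(V: np.ndarray, S: np.ndarray, zero_zero: float = 1.0) -> np.ndarray:
    """(|V|, |S|) Tanimoto similarity matrix between two fingerprint sets."""
    V = np.asarray(V, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if V.shape[1] != S.shape[1]:
        raise ValueError("bit-length mismatch")
    inter = V @ S.T
    union = V.sum(axis=1)[:, None] + S.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), zero_zero)
    return sim


def clumping_H(
    V: np.ndarray, S: np.ndarray, thresholds: np.ndarray | None = None
) -> float:
    """Fraction of (ligand, threshold) pairs whose nearest-neighbor distance beats t.

    For each v in V, d(v) = 1 - max_{s in S} tanimoto(v, s); H is the mean
    over v and over the threshold grid of the indicator d(v) < t. H = 1 when
    every v has an exact duplicate in S; H = 0 when every v is maximally
    distant from S.
    """
    V = np.atleast_2d(np.asarray(V))
    S = np.atleast_2d(np.asarray(S))
    if V.size == 0 or S.size == 0:
        raise ValueError("empty fingerprint set")
    t = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds, dtype=np.float64)
    nearest_dist = 1.0 - pairwise_tanimoto(V, S).max(axis=1)  # (|V|,)
    hits = nearest_dist[:, None] < t[None, :]
    return float(hits.mean())


@dataclass
class BiasInput:
    """The four fingerprint sets entering B; training sets must be non-empty."""

    validation_actives: np.ndarray  # (na, bits) or empty
    validation_inactives: np.ndarray
    training_actives: np.ndarray
    training_inactives: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            np.atleast_2d(np.asarray(a))
            for a in (
                self.validation_actives,
                self.validation_inactives,
                self.training_actives,
                self.training_inactives,
            )
        ]
        widths = {a.shape[1] for a in arrays if a.size}
        if len(widths) > 1:
            raise ValueError(f"fingerprint bit-lengths differ: {sorted(widths)}")
        if arrays[2].size == 0 or arrays[3].size == 0:
            raise ValueError("training actives and inactives must be non-empty")
        (
            self.validation_actives,
            self.validation_inactives,
            self.training_actives,
            self.training_inactives,
        ) = arrays


def ave_bias(
    inp: BiasInput, thresholds: np.ndarray | None = None, return_terms: bool = False
):
    """AVE bias B in [-2, 2]; positive = redundant split, ~0 = unbiased.

    A missing validation class contributes 0 to its term (flagged via
    ``return_terms``); with no validation ligands at all B is undefined.
    """
    has_va = inp.validation_actives.size > 0
    has_vi = inp.validation_inactives.size > 0
    if not has_va and not has_vi:
        raise UndefinedBias("no validation ligands")
    term_active = (
        clumping_H(inp.validation_actives, inp.training_actives, thresholds)
        - clumping_H(inp.validation_actives, inp.training_inactives, thresholds)
        if has_va
        else 0.0
    )
    term_inactive = (
        clumping_H(inp.validation_inactives, inp.training_inactives, thresholds)
        - clumping_H(inp.validation_inactives, inp.training_actives, thresholds)
        if has_vi
        else 0.0
    )
    b = term_active + term_inactive
    if return_terms:
        return b, {
            "term_active": term_active,
            "term_inactive": term_inactive,
            "validation_actives_present": has_va,
            "validation_inactives_present": has_vi,
        }
    return b


def bias_per_target(
    split: SplitPair,
    fingerprints: dict[str, np.ndarray],
    thresholds: np.ndarray | None = None,
) -> pd.Series:
    """AVE bias B for every target of a train/validation split.

    Targets whose training set lacks actives or inactives, or with no
    validation ligands, are reported as NaN (flagged, excluded from
    aggregates). Raises KeyError listing any ligand without a fingerprint.
    """
    train, val = split.train, split.validation
    missing = [
        str(l)
        for l in set(train.ligands[train.cols]) | set(val.ligands[val.cols])
        if str(l) not in fingerprints
    ]
    if missing:
        raise KeyError(f"no fingerprint for ligands: {sorted(missing)[:10]}")

    def fps(matrix, t, active: bool) -> np.ndarray:
        entry = matrix.entries_by_target.get(t)
        if entry is None:
            return np.empty((0, 0))
        cols, labels = entry
        sel = cols[(labels == 1.0) if active else (labels == 0.0)]
        if len(sel) == 0:
            return np.empty((0, 0))
        return np.stack([fingerprints[str(matrix.ligands[c])] for c in sel])

    out = {}
    for t in range(train.n_targets):
        ta = fps(train, t, True)
        ti = fps(train, t, False)
        va = fps(val, t, True)
        vi = fps(val, t, False)
        if ta.size == 0 or ti.size == 0 or (va.size == 0 and vi.size == 0):
            out[str(train.targets[t])] = np.nan
            continue
        out[str(train.targets[t])] = ave_bias(
            BiasInput(va, vi, ta, ti), thresholds=thresholds
        )
    return pd.Series(out, name="ave_bias")


def bias_performance_correlation(bias: pd.Series, metric_table: pd.DataFrame, metric: str = "auc") -> float:
    """Pearson correlation between per-target AVE bias and a performance metric.

    Computed over targets with defined values of both quantities; this is the
    audit of whether a method's apparent performance is explained by split
    redundancy rather than generalization.
    """
    per_target = metric_table.groupby("target_id")[metric].mean()
    joined = pd.concat([bias.rename("bias"), per_target.rename("metric")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("too few targets with defined bias and metric")
    return float(np.corrcoef(joined["bias"], joined["metric"])[0, 1])
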