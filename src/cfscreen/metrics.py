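"""Early-recognition evaluation of ranked ligand lists.

Virtual screening is judged on whether true actives appear at the very top
of a target's ranked candidate list, not just on overall separability. This
module provides the four standard measures:

* AUC — probability that a random active outranks a random inactive
  (Mann-Whitney, ties counted 1/2);
* EF_X% — enrichment factor: the active rate in the top X% of the list,
  normalized by the overall active rate;
* RIE — robust initial enhancement: exponentially rank-weighted analogue of
  EF, equal to 1 in expectation for a random ordering;
* BEDROC — min-max-normalized RIE, bounded in [0, 1], with pre-exponent
  alpha (default 20, weighting roughly the top 8% of the list).

Rank-based metrics (EF/RIE/BEDROC) need a total order, so lists are sorted
by descending score with ties broken by ascending ligand index; AUC instead
uses the standard tie-aware convention. Metrics that are undefined for a
list (a single-class validation set) raise :class:`UndefinedMetric` and are
flagged, never zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RankedList",
    "MetricConfig",
    "UndefinedMetric",
    "auc",
    "enrichment_factor",
    "rie",
    "bedroc",
    "bedroc_extremes",
    "evaluate_target",
]


class UndefinedMetric(ValueError):
    """The metric is not defined for this list (e.g. a single-class list)."""


@dataclass(frozen=True)
class MetricConfig:
    alpha: float = 20.0
    ef_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.ef_fraction <= 1):
            raise ValueError("ef_fraction must be in (0, 1]")
        if not (self.alpha > 0):
            raise ValueError("alpha must be positive")


@dataclass
class RankedList:
    """A target's candidates ordered by descending predicted score.

    Construct with :meth:`from_scores`, which applies the deterministic
    ordering (descending score, ties by ascending ligand index).
    """

    ligand_ids: np.ndarray
    scores: np.ndarray
    truths: np.ndarray  # bool, True = active

    def __post_init__(self) -> None:
        self.ligand_ids = np.asarray(self.ligand_ids)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.truths = np.asarray(self.truths, dtype=bool)
        if not (len(self.ligand_ids) == len(self.scores) == len(self.truths)):
            raise ValueError("ligand_ids, scores and truths must have equal length")
        if len(self.scores) == 0:
            raise ValueError("empty ranked list")

    @classmethod
    def from_scores(cls, ligand_ids, scores, truths) -> "RankedList":
        ids = list(ligand_ids)
        scores = np.asarray(scores, dtype=np.float64)
        order = sorted(range(len(scores)), key=lambda i: (-scores[i], ids[i]))
        return cls(
            np.asarray(ids, dtype=object)[order],
            scores[order],
            np.asarray(truths, dtype=bool)[order],
        )

    @property
    def N(self) -> int:
        return len(self.scores)

    @property
    def n(self) -> int:
        return int(self.truths.sum())

    @property
    def active_ranks(self) -> np.ndarray:
        """1-based positions of the actives in the sorted list."""
        return np.flatnonzero(self.truths) + 1


def auc(ranked: RankedList) -> float:
    """Tie-aware ROC AUC: P(random active outranks random inactive)."""
    n, N = ranked.n, ranked.N
    if n == 0 or n == N:
        raise UndefinedMetric("AUC needs both actives and inactives")
    ranks = rankdata(-ranked.scores)  # average ranks, 1 = best score
    active_rank_sum = ranks[ranked.truths].sum()
    # Mann-Whitney U of the actives over the inactives, ties counted 1/2.
    u = n * (N - n) + n * (n + 1) / 2.0 - active_rank_sum
    return float(u / (n * (N - n)))


def enrichment_factor(ranked: RankedList, x: float | None = None, config: MetricConfig | None = None) -> float:
    """EF_X%: active rate in the top ceil(X*N) candidates over the base rate."""
    if x is None:
        x = (config or MetricConfig()).ef_fraction
    if not (0 < x <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n, N = ranked.n, ranked.N
    if n == 0:
        raise UndefinedMetric("EF needs at least one active")
    top = math.ceil(x * N)
    hits = int(ranked.truths[:top].sum())
    return (hits / top) / (n / N)


def _rie_denominator(alpha: float, N: int) -> float:
    # Expected value of exp(-alpha * r / N) under a uniform random rank r.
    return (1.0 / N) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0)


def rie(ranked: RankedList, alpha: float = 20.0) -> float:
    """Robust initial enhancement with exponential rank weights."""
    n, N = ranked.n, ranked.N
    if n == 0 or n == N:
        raise UndefinedMetric("RIE needs both actives and inactives")
    num = float(np.exp(-alpha * ranked.active_ranks / N).sum()) / n
    return num / _rie_denominator(alpha, N)


def _bedroc_from_rie(rie_value: float, ra: float, alpha: float) -> float:
    scale = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    )
    value = rie_value * scale + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    # exact value lies in [0, 1]; cancellation can stray by ~1 ulp at the ends
    return min(max(value, 0.0), 1.0)


def bedroc(ranked: RankedList, alpha: float = 20.0) -> float:
    """Min-max-normalized RIE, bounded in [0, 1]; depends only on ranks."""
    n, N = ranked.n, ranked.N
    if n == 0 or n == N:
        raise UndefinedMetric("BEDROC needs both actives and inactives")
    return _bedroc_from_rie(rie(ranked, alpha), n / N, alpha)


def bedroc_extremes(N: int, n: int, alpha: float = 20.0) -> tuple[float, float]:
    """Closed-form best/worst BEDROC: actives at ranks 1..n vs N-n+1..N."""
    ranks_best = np.arange(1, n + 1)
    ranks_worst = np.arange(N - n + 1, N + 1)
    denom = _rie_denominator(alpha, N)
    rie_best = float(np.exp(-alpha * ranks_best / N).sum()) / n / denom
    rie_worst = float(np.exp(-alpha * ranks_worst / N).sum()) / n / denom
    ra = n / N
    return _bedroc_from_rie(rie_best, ra, alpha), _bedroc_from_rie(rie_worst, ra, alpha)


def evaluate_target(ligand_ids, scores, truths, config: MetricConfig | None = None) -> dict:
    """Score one target's validation list with AUC, EF and BEDROC.

    Undefined metrics (single-class lists) are reported as NaN with a flag
    so aggregation can exclude rather than impute them.
    """
    config = config or MetricConfig()
    ranked = RankedList.from_scores(ligand_ids, scores, truths)
    out: dict = {"N": ranked.N, "n_actives": ranked.n}
    for name, fn in (
        ("auc", lambda r: auc(r)),
        ("bedroc", lambda r: bedroc(r, config.alpha)),
        ("ef", lambda r: enrichment_factor(r, config.ef_fraction)),
    ):
        try:
            out[name] = fn(ranked)
            out[f"{name}_defined"] = True
        except UndefinedMetric:
            out[name] = float("nan")
            out[f"{name}_defined"] = False
    return out
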