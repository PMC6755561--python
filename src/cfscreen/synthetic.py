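"""Synthetic bioactivity data from a known low-rank latent-factor model.

The generator mirrors the statistical shape of curated ChEMBL-style binding
data — a very sparse target x ligand matrix (default 0.15% observed) with a
roughly 7:3 inactive:active balance — while keeping the generating factors
available as ground truth, so factor-recovery and split-auditing behaviour
can be measured exactly. Binary labels come from thresholding the dot product
of latent target and ligand factors; label noise models assay
irreproducibility. Binary "fingerprints" are random sign projections of the
ligand factors, so ligands with nearby factors receive similar bit patterns,
which is what the AVE bias audit needs from real chemical fingerprints.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .data import BioactivityMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_ground_truth",
    "simulate_assays",
    "simulate_fingerprints",
    "fingerprint_map",
    "skewed_assay_quotas",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated screening dataset.

    Defaults emulate the curated real data: 0.15% matrix density and a 30%
    active fraction (7:3 inactive:active); 5% label noise reflects the
    irreproducibility of experimental binding measures.
    """

    n_targets: int = 300
    n_ligands: int = 3000
    true_rank: int = 10
    density: float = 0.0015
    active_fraction: float = 0.3
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.n_ligands < 1 or self.true_rank < 1:
            raise ValueError("dimensions must be positive")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if not (0 < self.active_fraction < 1):
            raise ValueError("active_fraction must be in (0, 1)")


@dataclass
class GroundTruth:
    """True generating factors and the activity threshold on their products."""

    target_factors: np.ndarray  # (T, rank)
    ligand_factors: np.ndarray  # (rank, L)
    score_threshold: float

    def scores(self) -> np.ndarray:
        return self.target_factors @ self.ligand_factors


def simulate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw latent factors and calibrate the activity threshold.

    Factor entries are i.i.d. Gaussian with scale 1/sqrt(rank), so the
    dot-product variance is rank-independent; the threshold is the empirical
    (1 - active_fraction) quantile of all T*L pair scores, which makes the
    population active rate equal to ``active_fraction`` by construction.
    """
    rng = substream(config.seed, "ground_truth")
    scale = 1.0 / np.sqrt(config.true_rank)
    P = rng.normal(0.0, scale, size=(config.n_targets, config.true_rank))
    Q = rng.normal(0.0, scale, size=(config.true_rank, config.n_ligands))
    scores = P @ Q
    threshold = float(np.quantile(scores, 1.0 - config.active_fraction))
    return GroundTruth(P, Q, threshold)


def simulate_assays(
    truth: GroundTruth,
    config: SimulationConfig,
    per_target_quotas: np.ndarray | None = None,
) -> BioactivityMatrix:
    """Sample observed pairs and emit a binary bioactivity matrix.

    By default ``round(density * T * L)`` pairs are drawn uniformly without
    replacement. ``per_target_quotas`` instead fixes the number of observed
    ligands per target, emulating the heavily skewed per-target assay counts
    of real screening data. A pair is labelled active (1) iff its true score
    exceeds the threshold, then each label is flipped independently with
    probability ``label_noise``.
    """
    T, rank = truth.target_factors.shape
    L = truth.ligand_factors.shape[1]
    rng = substream(config.seed, "assays")
    if per_target_quotas is None:
        n_obs = int(round(config.density * T * L))
        flat = rng.choice(T * L, size=n_obs, replace=False)
        rows = flat // L
        cols = flat % L
    else:
        quotas = np.asarray(per_target_quotas, dtype=np.int64)
        if quotas.shape != (T,):
            raise ValueError(f"per_target_quotas must have shape ({T},)")
        if quotas.max(initial=0) > L:
            raise ValueError("quota exceeds number of ligands")
        rows = np.repeat(np.arange(T), quotas)
        cols = np.concatenate(
            [rng.choice(L, size=q, replace=False) for q in quotas]
        ) if quotas.sum() else np.empty(0, dtype=np.int64)
    scores = np.einsum(
        "ij,ji->i", truth.target_factors[rows], truth.ligand_factors[:, cols]
    )
    labels = (scores > truth.score_threshold).astype(np.float64)
    if config.label_noise > 0:
        flips = rng.random(len(labels)) < config.label_noise
        labels[flips] = 1.0 - labels[flips]
    t_width = max(4, len(str(T)))
    l_width = max(5, len(str(L)))
    targets = np.array([f"T{t:0{t_width}d}" for t in range(T)], dtype=object)
    ligands = np.array([f"L{l:0{l_width}d}" for l in range(L)], dtype=object)
    order = np.lexsort((cols, rows))
    return BioactivityMatrix(targets, ligands, rows[order], cols[order], labels[order], "binary")


def skewed_assay_quotas(
    n_targets: int,
    seed: int = 0,
    groups: tuple[tuple[float, int, int], ...] = (
        (0.55, 20, 90),
        (0.25, 100, 200),
        (0.20, 250, 450),
    ),
) -> np.ndarray:
    """Per-target assay counts with the skew of real screening panels.

    Real panels are dominated by sparsely assayed targets (more than half
    below ~200 recorded assays) with a long tail of heavily assayed ones.
    ``groups`` gives (proportion, low, high) blocks; counts are drawn
    uniformly within each block. Use with ``simulate_assays``'s
    ``per_target_quotas``.
    """
    rng = substream(seed, "quotas")
    fractions = [g[0] for g in groups]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("group proportions must sum to 1")
    sizes = [int(round(f * n_targets)) for f in fractions]
    sizes[-1] = n_targets - sum(sizes[:-1])
    quotas = np.concatenate(
        [rng.integers(lo, hi + 1, size=s) for (_, lo, hi), s in zip(groups, sizes)]
    )
    return rng.permutation(quotas)


def simulate_fingerprints(
    truth: GroundTruth, n_bits: int = 128, flip_prob: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Binary ligand fingerprints correlated with the true ligand factors.

    Each bit is the sign indicator of a random Gaussian projection of the
    ligand's factor vector, flipped independently with ``flip_prob``. At
    flip_prob near 0.5 the bits carry no structural signal (the uninformative
    control for bias audits). Returns an (L, n_bits) uint8 array indexed like
    the matrix columns.
    """
    if not (0 <= flip_prob < 0.5):
        raise ValueError("flip_prob must be in [0, 0.5)")
    if n_bits < 1:
        raise ValueError("n_bits must be positive")
    rng = substream(seed, "fingerprints")
    rank, L = truth.ligand_factors.shape
    W = rng.normal(size=(n_bits, rank))
    bits = (W @ truth.ligand_factors > 0).astype(np.uint8).T  # (L, n_bits)
    if flip_prob > 0:
        flips = rng.random(bits.shape) < flip_prob
        bits = np.where(flips, 1 - bits, bits).astype(np.uint8)
    return bits


def fingerprint_map(matrix: BioactivityMatrix, bits: np.ndarray) -> dict[str, np.ndarray]:
    """Attach simulated fingerprints to the matrix's ligand identifiers."""
    if len(bits) != matrix.n_ligands:
        raise ValueError("fingerprint array does not match matrix ligand count")
    return {str(lig): bits[i] for i, lig in enumerate(matrix.ligands)}
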