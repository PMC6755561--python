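"""Bioactivity curation: assay records, activity labels, sparse matrices, splits.

Assay outcomes arrive as (ligand, target, measure, concentration) records with
measure type Ki, IC50 or EC50 in nM. Curation resolves duplicate measures per
pair (Ki preferred over IC50 over EC50), applies concentration thresholds to
assign activity labels, and assembles a sparse target x ligand label matrix
whose rows are protein targets and columns are ligands. Splitting stratifies
on targets: each target's observed assays are partitioned 70:30 between
training and validation independently of the other targets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AssayRecord",
    "BioactivityMatrix",
    "SplitPair",
    "ACTIVE_THRESHOLD_NM",
    "INACTIVE_THRESHOLD_NM",
    "MEASURE_PRIORITY",
    "ASSAY_COUNT_BIN_LABELS",
    "label_binary",
    "label_multilevel",
    "resolve_measure",
    "build_matrix",
    "stratified_split",
    "assay_count_bins",
    "read_assay_table",
    "write_assay_table",
    "read_matrix",
    "write_matrix",
]

#: Activity thresholds in nM: strictly below -> active, strictly above -> inactive.
ACTIVE_THRESHOLD_NM = 100.0
INACTIVE_THRESHOLD_NM = 1000.0

#: Lower value = higher priority when one pair has several measure types.
MEASURE_PRIORITY = {"Ki": 0, "IC50": 1, "EC50": 2}

_MEASURE_CANON = {"KI": "Ki", "IC50": "IC50", "EC50": "EC50"}


@dataclass(frozen=True)
class AssayRecord:
    """A single measured ligand-target binding concentration."""

    ligand_id: str
    target_id: str
    measure: str  # "Ki" | "IC50" | "EC50"
    value: float  # concentration in nM, > 0

    def __post_init__(self) -> None:
        if self.measure not in MEASURE_PRIORITY:
            raise ValueError(f"unknown measure type {self.measure!r}")
        if not (self.value > 0):
            raise ValueError(f"concentration must be positive, got {self.value}")


def label_binary(value_nm: float) -> str:
    """Binary activity label from a concentration in nM.

    Strictly below 100 nM is ``"active"``, strictly above 1000 nM is
    ``"inactive"``; anything in between (including exactly 100 or 1000 nM)
    is ``"indeterminate"`` and is discarded when building binary matrices.
    """
    if not (value_nm > 0):
        raise ValueError(f"concentration must be positive, got {value_nm}")
    if value_nm < ACTIVE_THRESHOLD_NM:
        return "active"
    if value_nm > INACTIVE_THRESHOLD_NM:
        return "inactive"
    return "indeterminate"


def label_multilevel(value_nm: float) -> int:
    """Four-level affinity label: 1 strongest (<1 nM) ... 4 weakest (>=1000 nM).

    Half-open intervals [1, 100) and [100, 1000) avoid double assignment at
    the cut points.
    """
    if not (value_nm > 0):
        raise ValueError(f"concentration must be positive, got {value_nm}")
    if value_nm < 1:
        return 1
    if value_nm < 100:
        return 2
    if value_nm < 1000:
        return 3
    return 4


def resolve_measure(records: list[AssayRecord], merge: str = "geometric") -> AssayRecord:
    """Collapse multiple measures for one (ligand, target) pair to one record.

    The measure type with the highest priority (Ki > IC50 > EC50) wins; if
    several records share that measure type their concentrations are merged
    (geometric mean by default, appropriate for log-scaled concentrations;
    ``merge`` may also be ``"median"`` or ``"min"``).
    """
    if not records:
        raise ValueError("no records")
    pairs = {(r.ligand_id, r.target_id) for r in records}
    if len(pairs) != 1:
        raise ValueError(f"records span multiple (ligand, target) pairs: {sorted(pairs)}")
    best = min(MEASURE_PRIORITY[r.measure] for r in records)
    kept = [r for r in records if MEASURE_PRIORITY[r.measure] == best]
    values = [r.value for r in kept]
    if merge == "geometric":
        value = math.exp(sum(math.log(v) for v in values) / len(values))
    elif merge == "median":
        value = float(np.median(values))
    elif merge == "min":
        value = min(values)
    else:
        raise ValueError(f"unknown merge rule {merge!r}")
    return AssayRecord(kept[0].ligand_id, kept[0].target_id, kept[0].measure, value)


@dataclass
class BioactivityMatrix:
    """Sparse target x ligand activity label matrix.

    ``targets`` and ``ligands`` fix the row/column order (lexicographic when
    built from records). Observed entries are stored as parallel triplet
    arrays ``rows``/``cols``/``labels``; in binary mode labels are 1 (active)
    and 0 (inactive), in multilevel mode 1..4.
    """

    targets: np.ndarray  # (T,) str
    ligands: np.ndarray  # (L,) str
    rows: np.ndarray  # (n_obs,) int
    cols: np.ndarray  # (n_obs,) int
    labels: np.ndarray  # (n_obs,) float
    mode: str = "binary"

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=object)
        self.ligands = np.asarray(self.ligands, dtype=object)
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if not (len(self.rows) == len(self.cols) == len(self.labels)):
            raise ValueError("triplet arrays must have equal length")
        if self.mode not in ("binary", "multilevel"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    @property
    def n_observed(self) -> int:
        return len(self.rows)

    @property
    def density(self) -> float:
        total = self.n_targets * self.n_ligands
        return self.n_observed / total if total else 0.0

    @cached_property
    def observed_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    @cached_property
    def target_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.targets)}

    @cached_property
    def ligand_index(self) -> dict[str, int]:
        return {l: i for i, l in enumerate(self.ligands)}

    @cached_property
    def entries_by_target(self) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Map row index -> (column indices, labels), in insertion order."""
        out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        order = np.argsort(self.rows, kind="stable")
        rows, cols, labels = self.rows[order], self.cols[order], self.labels[order]
        bounds = np.searchsorted(rows, np.arange(self.n_targets + 1))
        for t in range(self.n_targets):
            lo, hi = bounds[t], bounds[t + 1]
            if lo < hi:
                out[t] = (cols[lo:hi], labels[lo:hi])
        return out

    def to_dense(self, fill: float = np.nan) -> np.ndarray:
        dense = np.full((self.n_targets, self.n_ligands), fill, dtype=np.float64)
        dense[self.rows, self.cols] = self.labels
        return dense

    def subset(self, entry_indices: np.ndarray) -> "BioactivityMatrix":
        """Matrix over the same target/ligand universe restricted to some entries."""
        idx = np.asarray(entry_indices, dtype=np.int64)
        return BioactivityMatrix(
            self.targets, self.ligands, self.rows[idx], self.cols[idx], self.labels[idx], self.mode
        )


@dataclass
class SplitPair:
    """A disjoint train/validation partition of one matrix's observed entries."""

    train: BioactivityMatrix
    validation: BioactivityMatrix
    seed: int
    iteration: int = 1


def build_matrix(
    records: list[AssayRecord], mode: str = "binary", merge: str = "geometric"
) -> BioactivityMatrix:
    """Curate assay records into a sparse label matrix.

    Duplicates per (ligand, target) pair are resolved by measure priority,
    then labels are assigned; in binary mode indeterminate records (100 nM to
    1000 nM inclusive) are dropped. Row/column order is lexicographic by id
    over the surviving records, so serialized matrices are reproducible.
    """
    if mode not in ("binary", "multilevel"):
        raise ValueError(f"unknown mode {mode!r}")
    if not records:
        raise ValueError("no records")
    grouped: dict[tuple[str, str], list[AssayRecord]] = {}
    for r in records:
        grouped.setdefault((r.target_id, r.ligand_id), []).append(r)

    entries: list[tuple[str, str, float]] = []
    for (target_id, ligand_id), group in grouped.items():
        rec = resolve_measure(group, merge=merge)
        if mode == "binary":
            lab = label_binary(rec.value)
            if lab == "indeterminate":
                continue
            entries.append((target_id, ligand_id, 1.0 if lab == "active" else 0.0))
        else:
            entries.append((target_id, ligand_id, float(label_multilevel(rec.value))))
    if not entries:
        raise ValueError("empty matrix: all records indeterminate")

    targets = np.array(sorted({e[0] for e in entries}), dtype=object)
    ligands = np.array(sorted({e[1] for e in entries}), dtype=object)
    t_index = {t: i for i, t in enumerate(targets)}
    l_index = {l: i for i, l in enumerate(ligands)}
    entries.sort(key=lambda e: (e[0], e[1]))
    rows = np.array([t_index[e[0]] for e in entries], dtype=np.int64)
    cols = np.array([l_index[e[1]] for e in entries], dtype=np.int64)
    labels = np.array([e[2] for e in entries], dtype=np.float64)
    return BioactivityMatrix(targets, ligands, rows, cols, labels, mode)


def stratified_split(
    matrix: BioactivityMatrix,
    validation_fraction: float = 0.3,
    seed: int = 0,
    iteration: int = 1,
) -> SplitPair:
    """Per-target random train/validation partition of the observed entries.

    For each target, ``round(fraction * n)`` of its ``n`` observed entries go
    to validation (never more than ``n - 1``, so every target keeps at least
    one training assay; a single-assay target contributes nothing to
    validation). Deterministic for a given seed.
    """
    if not (0 < validation_fraction < 1):
        raise ValueError("validation_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    val_mask = np.zeros(matrix.n_observed, dtype=bool)
    order = np.argsort(matrix.rows, kind="stable")
    rows_sorted = matrix.rows[order]
    bounds = np.searchsorted(rows_sorted, np.arange(matrix.n_targets + 1))
    for t in range(matrix.n_targets):
        idx = order[bounds[t] : bounds[t + 1]]
        n = len(idx)
        if n < 2:
            continue
        n_val = min(int(round(validation_fraction * n)), n - 1)
        chosen = rng.permutation(idx)[:n_val]
        val_mask[chosen] = True
    all_idx = np.arange(matrix.n_observed)
    return SplitPair(
        train=matrix.subset(all_idx[~val_mask]),
        validation=matrix.subset(all_idx[val_mask]),
        seed=seed,
        iteration=iteration,
    )


ASSAY_COUNT_BIN_LABELS = ("<100", "100-200", "200-300", "300-400", "400-500", ">500")
_BIN_EDGES = np.array([100, 200, 300, 400, 500])


def assay_count_bins(train: BioactivityMatrix) -> dict[str, str]:
    """Bin each target by its number of training assays.

    Bins are half-open: <100, [100,200), ..., [400,500), and >=500 labelled
    ">500". Targets absent from the training matrix count as 0 assays.
    """
    counts = np.zeros(train.n_targets, dtype=np.int64)
    np.add.at(counts, train.rows, 1)
    bins = np.searchsorted(_BIN_EDGES, counts, side="right")
    return {
        str(train.targets[t]): ASSAY_COUNT_BIN_LABELS[bins[t]] for t in range(train.n_targets)
    }


# ---------------------------------------------------------------------------
# I/O: delimited assay tables and triplet matrix serialization


def read_assay_table(path: str | Path) -> list[AssayRecord]:
    """Read assay records from a .csv or .tsv file.

    Requires columns ligand_id, target_id, measure_type, value_nm (extra
    columns ignored; measure_type matched case-insensitively).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    required = {"ligand_id", "target_id", "measure_type", "value_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        measure = _MEASURE_CANON.get(str(row.measure_type).upper())
        if measure is None:
            raise ValueError(f"unknown measure_type {row.measure_type!r}")
        records.append(
            AssayRecord(str(row.ligand_id), str(row.target_id), measure, float(row.value_nm))
        )
    return records


def write_assay_table(records: list[AssayRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.DataFrame(
        {
            "ligand_id": [r.ligand_id for r in records],
            "target_id": [r.target_id for r in records],
            "measure_type": [r.measure for r in records],
            "value_nm": [r.value for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def write_matrix(matrix: BioactivityMatrix, outdir: str | Path) -> None:
    """Serialize as a triplet TSV plus a JSON sidecar with index order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "triplets.tsv", "w") as fh:
        fh.write("target_id\tligand_id\tlabel\n")
        for t, l, a in zip(matrix.rows, matrix.cols, matrix.labels):
            fh.write(f"{matrix.targets[t]}\t{matrix.ligands[l]}\t{a:g}\n")
    meta = {
        "targets": matrix.targets.tolist(),
        "ligands": matrix.ligands.tolist(),
        "mode": matrix.mode,
        "density": matrix.density,
    }
    with open(outdir / "matrix.json", "w") as fh:
        json.dump(meta, fh)


def read_matrix(indir: str | Path) -> BioactivityMatrix:
    indir = Path(indir)
    with open(indir / "matrix.json") as fh:
        meta = json.load(fh)
    df = pd.read_csv(indir / "triplets.tsv", sep="\t", dtype={"target_id": str, "ligand_id": str})
    t_index = {t: i for i, t in enumerate(meta["targets"])}
    l_index = {l: i for i, l in enumerate(meta["ligands"])}
    return BioactivityMatrix(
        np.array(meta["targets"], dtype=object),
        np.array(meta["ligands"], dtype=object),
        df["target_id"].map(t_index).to_numpy(),
        df["ligand_id"].map(l_index).to_numpy(),
        df["label"].to_numpy(dtype=np.float64),
        meta["mode"],
    )
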