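"""Expression matrices: loading, replicate-based QC, scaling, discretization.

The central objects are :class:`ExpressionMatrix` (continuous log-ratio scale
values, genes x experiments, with explicit missing entries) and
:class:`DiscretizedMatrix` (the same shape with each present entry mapped to
one of three expression states: 0 = under-expressed, 1 = normal,
2 = over-expressed, relative to the gene's own average across experiments).

Missing data are represented explicitly throughout (NaN for continuous
values, -1 for states) and are never imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigError, DataError

MISSING_STATE = -1

__all__ = [
    "ExpressionMatrix",
    "DiscretizedMatrix",
    "ReplicateMap",
    "QCReport",
    "read_expression",
    "write_expression",
    "read_discretized",
    "write_discretized",
    "read_replicate_map",
    "quality_filter",
    "quality_filter_detailed",
    "median_scale",
    "discretize",
    "shuffle",
]


def _check_ids(ids: Iterable[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x experiments matrix of continuous expression values.

    ``values`` is float64 with NaN marking missing entries; ``mask`` is the
    derived boolean presence matrix (True = value present).
    """

    gene_ids: tuple[str, ...]
    experiment_ids: tuple[str, ...]
    values: np.ndarray
    _row_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.experiment_ids = _check_ids(self.experiment_ids, "experiment")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.experiment_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.experiment_ids)} experiments"
            )
        self._row_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._row_index[gene_id]]
        except KeyError:
            raise DataError(f"gene {gene_id!r} not in matrix") from None

    def row_number(self, gene_id: str) -> int:
        try:
            return self._row_index[gene_id]
        except KeyError:
            raise DataError(f"gene {gene_id!r} not in matrix") from None

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        rows = [self.row_number(g) for g in gene_ids]
        return ExpressionMatrix(tuple(gene_ids), self.experiment_ids, self.values[rows].copy())


@dataclass
class DiscretizedMatrix:
    """Genes x experiments matrix of 3-state expression levels.

    ``states`` is int8 with entries in {0, 1, 2} where present and
    ``MISSING_STATE`` (-1) where missing.
    """

    gene_ids: tuple[str, ...]
    experiment_ids: tuple[str, ...]
    states: np.ndarray
    _row_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.experiment_ids = _check_ids(self.experiment_ids, "experiment")
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.gene_ids), len(self.experiment_ids)):
            raise DataError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.experiment_ids)} experiments"
            )
        bad = (self.states != MISSING_STATE) & ((self.states < 0) | (self.states > 2))
        if bad.any():
            raise DataError("states must be in {0,1,2} or -1 for missing")
        self._row_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def mask(self) -> np.ndarray:
        return self.states != MISSING_STATE

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.states[self._row_index[gene_id]]
        except KeyError:
            raise DataError(f"gene {gene_id!r} not in matrix") from None

    def row_number(self, gene_id: str) -> int:
        try:
            return self._row_index[gene_id]
        except KeyError:
            raise DataError(f"gene {gene_id!r} not in matrix") from None

    def as_float(self) -> np.ndarray:
        """States as float64 with NaN at missing entries."""
        out = self.states.astype(np.float64)
        out[self.states == MISSING_STATE] = np.nan
        return out

    def subset(self, gene_ids: Iterable[str]) -> "DiscretizedMatrix":
        gene_ids = list(gene_ids)
        rows = [self.row_number(g) for g in gene_ids]
        return DiscretizedMatrix(tuple(gene_ids), self.experiment_ids, self.states[rows].copy())


@dataclass
class ReplicateMap:
    """Groups of matrix rows that are duplicate spots of the same gene."""

    groups: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        norm: dict[str, tuple[str, ...]] = {}
        for label, members in self.groups.items():
            members = tuple(members)
            for m in members:
                if m in seen:
                    raise DataError(f"row {m!r} appears in more than one replicate group")
                seen.add(m)
            norm[label] = members
        self.groups = norm

    def validate_against(self, m: ExpressionMatrix) -> None:
        for label, members in self.groups.items():
            for r in members:
                if r not in m._row_index:
                    raise DataError(f"replicate group {label!r} lists unknown row {r!r}")


@dataclass
class QCReport:
    """What the quality filter removed and the correlations that decided it."""

    dropped_experiments: dict[str, float]
    dropped_rows: dict[str, float]


# ---------------------------------------------------------------------------
# File I/O (tab-separated text; empty cell = missing)
# ---------------------------------------------------------------------------

def _read_table(path) -> tuple[tuple[str, ...], list[str], list[list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"{path}: empty file") from None
        exp_ids = _check_ids(header[1:], "experiment")
        gene_ids: list[str] = []
        rows: list[list[str]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise DataError(
                    f"{path}: row {lineno} has {len(rec)} fields, expected {len(header)}"
                )
            gene_ids.append(rec[0])
            rows.append(rec[1:])
    return exp_ids, gene_ids, rows


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header of experiment ids, one row per gene).

    Empty cells (or ``NA``/``nan``) are missing. Duplicate gene ids and ragged
    rows raise :class:`DataError`.
    """
    exp_ids, gene_ids, rows = _read_table(path)
    values = np.empty((len(gene_ids), len(exp_ids)))
    for i, rec in enumerate(rows):
        for j, cell in enumerate(rec):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise DataError(
                        f"{path}: non-numeric value {cell!r} for gene "
                        f"{gene_ids[i]!r}, experiment {exp_ids[j]!r}"
                    ) from None
    return ExpressionMatrix(tuple(gene_ids), exp_ids, values)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; finite values round-trip bit-exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("gene_id",) + m.experiment_ids)
        for g, row in zip(m.gene_ids, m.values):
            w.writerow([g] + [(repr(float(v)) if np.isfinite(v) else "") for v in row])


def read_discretized(path) -> DiscretizedMatrix:
    exp_ids, gene_ids, rows = _read_table(path)
    states = np.empty((len(gene_ids), len(exp_ids)), dtype=np.int8)
    for i, rec in enumerate(rows):
        for j, cell in enumerate(rec):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                states[i, j] = MISSING_STATE
            else:
                try:
                    states[i, j] = int(cell)
                except ValueError:
                    raise DataError(f"{path}: non-integer state {cell!r}") from None
    return DiscretizedMatrix(tuple(gene_ids), exp_ids, states)


def write_discretized(m: DiscretizedMatrix, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("gene_id",) + m.experiment_ids)
        for g, row in zip(m.gene_ids, m.states):
            w.writerow([g] + [("" if v == MISSING_STATE else str(int(v))) for v in row])


def read_replicate_map(path) -> ReplicateMap:
    """Read a two-column TSV (``group``, ``row_id``)."""
    groups: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise DataError(f"{path}: empty replicate map")
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != 2:
                raise DataError(f"{path}: row {lineno} must have 2 fields")
            groups.setdefault(rec[0], []).append(rec[1])
    return ReplicateMap({k: tuple(v) for k, v in groups.items()})


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def _pearson_pairs(xs: np.ndarray, ys: np.ndarray) -> float:
    """Pearson r of two paired vectors; NaN if undefined (<3 points or no variance)."""
    if xs.size < 3:
        return np.nan
    if np.std(xs) == 0 or np.std(ys) == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def quality_filter_detailed(
    m: ExpressionMatrix,
    reps: ReplicateMap,
    chip_threshold: float = 0.5,
    spot_threshold: float = 0.5,
) -> tuple[ExpressionMatrix, QCReport]:
    """Replicate-concordance quality filter, with a report of what was dropped.

    Two passes. First, each experiment (chip) is scored by the Pearson
    correlation between duplicate-spot values on that chip (all within-group
    member pairs pooled); chips scoring below ``chip_threshold`` are dropped.
    Second, each replicate row is scored by its mean Pearson correlation with
    its group partners across the surviving chips; rows below
    ``spot_threshold`` are dropped. Surviving groups are collapsed to a single
    row (named by the group label) by averaging present values. Undefined
    correlations (too few points, zero variance) never cause removal.
    """
    for name, t in (("chip_threshold", chip_threshold), ("spot_threshold", spot_threshold)):
        if not -1.0 <= t <= 1.0:
            raise ConfigError(f"{name} must be in [-1, 1], got {t}")
    reps.validate_against(m)

    pairs: list[tuple[int, int]] = []
    for members in reps.groups.values():
        idx = [m.row_number(r) for r in members]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                pairs.append((idx[a], idx[b]))

    # chip pass
    dropped_exps: dict[str, float] = {}
    keep_cols: list[int] = []
    for c in range(m.n_experiments):
        if pairs:
            xs, ys = [], []
            for a, b in pairs:
                va, vb = m.values[a, c], m.values[b, c]
                if np.isfinite(va) and np.isfinite(vb):
                    xs.append(va)
                    ys.append(vb)
            r = _pearson_pairs(np.asarray(xs), np.asarray(ys))
        else:
            r = np.nan
        if np.isfinite(r) and r < chip_threshold:
            dropped_exps[m.experiment_ids[c]] = r
        else:
            keep_cols.append(c)

    vals = m.values[:, keep_cols]
    exp_ids = tuple(m.experiment_ids[c] for c in keep_cols)

    # spot pass
    dropped_rows: dict[str, float] = {}
    surviving: dict[str, list[int]] = {}
    for label, members in reps.groups.items():
        idx = [m.row_number(r) for r in members]
        keep: list[int] = []
        for i, ri in enumerate(idx):
            rs = []
            for j, rj in enumerate(idx):
                if i == j:
                    continue
                both = np.isfinite(vals[ri]) & np.isfinite(vals[rj])
                rs.append(_pearson_pairs(vals[ri][both], vals[rj][both]))
            rs_arr = np.asarray(rs, dtype=float)
            mean_r = float(np.mean(rs_arr[np.isfinite(rs_arr)])) if np.isfinite(rs_arr).any() else np.nan
            if np.isfinite(mean_r) and mean_r < spot_threshold:
                dropped_rows[members[i]] = float(mean_r)
            else:
                keep.append(ri)
        if keep:
            surviving[label] = keep

    grouped = {r for members in reps.groups.values() for r in members}
    out_ids: list[str] = []
    out_rows: list[np.ndarray] = []
    emitted: set[str] = set()
    for i, g in enumerate(m.gene_ids):
        if g not in grouped:
            out_ids.append(g)
            out_rows.append(vals[i])
            continue
        label = next(l for l, members in reps.groups.items() if g in members)
        if label in emitted or label not in surviving:
            continue
        emitted.add(label)
        with np.errstate(invalid="ignore"):
            collapsed = np.nanmean(vals[surviving[label]], axis=0)
        out_ids.append(label)
        out_rows.append(collapsed)

    out = ExpressionMatrix(tuple(out_ids), exp_ids, np.vstack(out_rows) if out_rows else
                           np.empty((0, len(exp_ids))))
    return out, QCReport(dropped_exps, dropped_rows)


def quality_filter(
    m: ExpressionMatrix,
    reps: ReplicateMap,
    chip_threshold: float = 0.5,
    spot_threshold: float = 0.5,
) -> ExpressionMatrix:
    return quality_filter_detailed(m, reps, chip_threshold, spot_threshold)[0]


# ---------------------------------------------------------------------------
# Scaling, discretization, shuffling
# ---------------------------------------------------------------------------

def median_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each experiment's median (of present values); idempotent."""
    vals = m.values.copy()
    for c in range(m.n_experiments):
        col = vals[:, c]
        present = np.isfinite(col)
        if not present.any():
            raise DataError(f"experiment {m.experiment_ids[c]!r} has no present values")
        vals[present, c] = col[present] - np.median(col[present])
    return ExpressionMatrix(m.gene_ids, m.experiment_ids, vals)


def discretize(m: ExpressionMatrix, method: str = "zscore", c: float = 1.0) -> DiscretizedMatrix:
    """Map each gene's values to 3 states relative to its own distribution.

    ``zscore``: per gene, state 0 if (x - mean)/sd < -c, state 2 if > +c,
    else 1 (sample sd, ddof=1; a zero-variance gene maps entirely to state 1).
    ``tertile``: per-gene equal-frequency thirds by rank.
    Missing entries stay missing.
    """
    if method not in ("zscore", "tertile"):
        raise ConfigError(f"unknown discretization method {method!r}")
    if c <= 0:
        raise ConfigError(f"c must be positive, got {c}")
    states = np.full(m.values.shape, MISSING_STATE, dtype=np.int8)
    for i in range(m.n_genes):
        row = m.values[i]
        present = np.isfinite(row)
        vals = row[present]
        if method == "zscore":
            if vals.size < 2:
                raise DataError(
                    f"gene {m.gene_ids[i]!r} has <2 present values; zscore undefined"
                )
            sd = np.std(vals, ddof=1)
            if sd == 0:
                s = np.ones(vals.size, dtype=np.int8)
            else:
                z = (vals - np.mean(vals)) / sd
                s = np.ones(vals.size, dtype=np.int8)
                s[z < -c] = 0
                s[z > c] = 2
        else:  # tertile
            if vals.size == 0:
                continue
            ranks = rankdata(vals, method="ordinal") - 1
            s = ((ranks * 3) // vals.size).astype(np.int8)
        states[i, present] = s
    return DiscretizedMatrix(m.gene_ids, m.experiment_ids, states)


def shuffle(m: DiscretizedMatrix, seed: int) -> DiscretizedMatrix:
    """Independently permute each gene's present states across experiments.

    Destroys all inter-gene dependence while conserving every per-gene state
    multiset (the null used to flatten the core-network score distribution).
    Missing positions stay fixed. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    states = m.states.copy()
    for i in range(m.n_genes):
        present = np.flatnonzero(states[i] != MISSING_STATE)
        states[i, present] = states[i, present][rng.permutation(present.size)]
    return DiscretizedMatrix(m.gene_ids, m.experiment_ids, states)
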