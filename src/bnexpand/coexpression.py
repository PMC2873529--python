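"""Co-expression baseline: rank genes by their best Pearson correlation with
any core gene.

This is the pairwise alternative to single-gene expansion: a gene's
co-expression score is the maximum (signed, by default) Pearson correlation
between its profile and each core gene's profile, computed on pairwise-
complete experiments. Equivalently, the minimum correlation distance to the
core. Correlations are computed on continuous values (post-scaling,
pre-discretization); Pearson on 3 states is near-degenerate, but a
discretized matrix is accepted for completeness (its states are treated as
numeric).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Union

import numpy as np
import pandas as pd

from .dag_core import CoreNetwork
from .data_model import DiscretizedMatrix, ExpressionMatrix
from .errors import ConfigError, DataError
from .expansion import RankTable, top_fraction

__all__ = [
    "CoexpressionResult",
    "CoexpressionTable",
    "MethodOverlap",
    "coexpression_score",
    "rank_genes_by_coexpression",
    "method_overlap",
    "write_coexpression_table",
]

Matrix = Union[ExpressionMatrix, DiscretizedMatrix]


@dataclass
class CoexpressionResult:
    gene_id: str
    score: float  # NaN = undefined (no qualifying core pair / zero variance)
    rank: int | None
    n_valid_pairs: int


@dataclass
class CoexpressionTable:
    """Ranked results (descending score) followed by unranked undefined ones."""

    results: list[CoexpressionResult]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.results)

    def ranked(self) -> list[CoexpressionResult]:
        return [r for r in self.results if r.rank is not None]

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.results]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.results],
                "coexpression_score": [r.score for r in self.results],
                "rank": [r.rank for r in self.results],
                "n_valid_pairs": [r.n_valid_pairs for r in self.results],
            }
        )


class MethodOverlap(NamedTuple):
    both: frozenset[str]
    bayes_only: frozenset[str]
    coexp_only: frozenset[str]


def _values(data: Matrix) -> np.ndarray:
    if isinstance(data, DiscretizedMatrix):
        return data.as_float()
    return data.values


def _pairwise_r(x: np.ndarray, y: np.ndarray, min_overlap: int) -> float:
    both = np.isfinite(x) & np.isfinite(y)
    n = int(both.sum())
    if n < min_overlap or n < 2:
        return np.nan
    xv, yv = x[both], y[both]
    if np.std(xv) == 0 or np.std(yv) == 0:
        return np.nan
    return float(np.corrcoef(xv, yv)[0, 1])


def coexpression_score(
    gene: str,
    core: CoreNetwork,
    data: Matrix,
    min_overlap: int = 6,
    absolute: bool = False,
) -> tuple[float, int]:
    """(max Pearson r to any core gene, number of core genes with a valid r).

    The score is NaN (undefined) when no core pairing has ``min_overlap``
    pairwise-complete experiments with nonzero variance on both sides.
    """
    vals = _values(data)
    x = vals[data.row_number(gene)]
    best = -np.inf
    n_valid = 0
    for node in core.nodes:
        row_id = core.gene_map[node]
        r = _pairwise_r(x, vals[data.row_number(row_id)], min_overlap)
        if math.isnan(r):
            continue
        n_valid += 1
        v = abs(r) if absolute else r
        if v > best:
            best = v
    return (best if n_valid else np.nan), n_valid


def rank_genes_by_coexpression(
    core: CoreNetwork,
    data: Matrix,
    min_overlap: int = 6,
    absolute: bool = False,
) -> CoexpressionTable:
    """Rank every non-core gene by co-expression score, best first.

    Undefined scores are quarantined at the end, unranked. Ties break
    lexicographically by gene id.
    """
    core_rows = set(core.gene_map.values())
    for n, r in core.gene_map.items():
        if r not in data.gene_ids:
            raise DataError(f"core gene {n!r} (row {r!r}) missing from data")
    results = []
    for gene in data.gene_ids:
        if gene in core_rows:
            continue
        score, n_valid = coexpression_score(gene, core, data, min_overlap, absolute)
        results.append(CoexpressionResult(gene, score, None, n_valid))
    defined = sorted((r for r in results if not math.isnan(r.score)),
                     key=lambda r: (-r.score, r.gene_id))
    undefined = sorted((r for r in results if math.isnan(r.score)),
                       key=lambda r: r.gene_id)
    for i, r in enumerate(defined, start=1):
        r.rank = i
    return CoexpressionTable(defined + undefined,
                             {"core": core.dag.edge_string(), "min_overlap": min_overlap,
                              "absolute": absolute})


def write_coexpression_table(t: CoexpressionTable, path) -> None:
    t.to_frame().to_csv(path, sep="\t", index=False)


def method_overlap(
    bayes: RankTable,
    coexp: CoexpressionTable,
    fraction: float,
) -> MethodOverlap:
    """Partition the two methods' top-fraction gene lists.

    Both lists are cut at ceil(fraction * N) genes where N is the shared
    candidate universe size (for co-expression, unranked undefined genes can
    leave its list shorter). Returns (found by both, expansion only,
    co-expression only).
    """
    universe_b = set(bayes.gene_ids())
    universe_c = set(coexp.gene_ids())
    if universe_b != universe_c:
        raise DataError("rank tables cover different candidate universes")
    if not 0 < fraction <= 1:
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * len(universe_b))
    top_b = set(r.gene_id for r in bayes.results[:k])
    top_c = set(r.gene_id for r in coexp.ranked()[:k])
    return MethodOverlap(
        frozenset(top_b & top_c),
        frozenset(top_b - top_c),
        frozenset(top_c - top_b),
    )
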