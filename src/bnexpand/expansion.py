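"""Genome-wide single-gene expansion ranking, top-fraction selection, and
exhaustive scoring of all 5-node core wirings.

The expansion workflow attaches every non-core gene to the fixed core, one at
a time, in every acyclic way, and ranks genes by their Bayesian addition
score. Genes are scored independently, so results do not depend on evaluation
order; exact score ties break lexicographically by gene id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bde_scoring import AdditionScoreResult, ScoreConfig, _family_ll, addition_score
from .dag_core import DAG, CoreNetwork, _acyclic_edge_masks, _edge_list, enumerate_extensions
from .data_model import DiscretizedMatrix, shuffle
from .errors import ConfigError, DataError

__all__ = [
    "RankTable",
    "CoreScanResult",
    "rank_genes",
    "top_fraction",
    "score_all_core_dags",
    "write_rank_table",
    "read_rank_table",
]


@dataclass
class RankTable:
    """Addition-score results in descending score order, rank 1 = best."""

    results: list[AdditionScoreResult]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.results)

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.results]

    def rank_of(self, gene_id: str) -> int:
        for r in self.results:
            if r.gene_id == gene_id:
                return r.rank
        raise DataError(f"gene {gene_id!r} not in rank table")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.results],
                "addition_score": [r.addition_score for r in self.results],
                "rank": [r.rank for r in self.results],
                "best_in_edges": [",".join(sorted(r.best_extension.in_edges))
                                  for r in self.results],
                "best_out_edges": [",".join(sorted(r.best_extension.out_edges))
                                   for r in self.results],
                "n_dependences": [r.n_dependences for r in self.results],
            }
        )


def rank_genes(
    core: CoreNetwork,
    data: DiscretizedMatrix,
    cfg: ScoreConfig = ScoreConfig(),
    candidates: Sequence[str] | None = None,
) -> RankTable:
    """Score every candidate gene's best attachment to the core and rank.

    Candidates default to every matrix row not mapped to a core node.
    Descending addition score; ties broken lexicographically by gene id.
    """
    core_rows = set(core.gene_map.values())
    for n, r in core.gene_map.items():
        if r not in data.gene_ids:
            raise DataError(f"core gene {n!r} (row {r!r}) missing from data")
    if candidates is None:
        candidates = [g for g in data.gene_ids if g not in core_rows]
    results = []
    for gene in candidates:
        res = addition_score(core, enumerate_extensions(core, f"+{gene}"), data, cfg,
                             new_gene_row=gene)
        results.append(res)
    results.sort(key=lambda r: (-r.addition_score, r.gene_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return RankTable(results, {"core": core.dag.edge_string(), "cfg": cfg,
                               "n_experiments": data.n_experiments})


def top_fraction(t: RankTable, fraction: float) -> RankTable:
    """First ceil(fraction * N) rows of the table."""
    if not 0 < fraction <= 1:
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * len(t.results))
    return RankTable(t.results[:k], {**t.metadata, "fraction": fraction})


def write_rank_table(t: RankTable, path) -> None:
    t.to_frame().to_csv(path, sep="\t", index=False)


def read_rank_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"gene_id": str, "best_in_edges": str, "best_out_edges": str})


# ---------------------------------------------------------------------------
# Exhaustive 5-node core scan
# ---------------------------------------------------------------------------

@dataclass
class CoreScanResult:
    """Scores of every DAG over the chosen core genes, best first optional.

    ``table`` columns: ``edges`` (canonical edge string), ``score``, plus
    ``score_shuffled`` and/or ``bootstrap_sd`` when requested. Row order is
    the deterministic enumeration order.
    """

    table: pd.DataFrame
    reference_rank: int | None = None


def _family_lookup(rows: list[np.ndarray], cfg: ScoreConfig) -> np.ndarray:
    """lookup[child, parent_node_mask] = BDeu family score; invalid (child in
    mask) entries left at 0 and never indexed."""
    k = len(rows)
    lookup = np.zeros((k, 1 << k))
    for child in range(k):
        for pmask in range(1 << k):
            if pmask >> child & 1:
                continue
            parents = [rows[i] for i in range(k) if pmask >> i & 1]
            lookup[child, pmask] = _family_ll(rows[child], parents, cfg.ess, cfg.arity)
    return lookup


def _all_dag_scores(rows: list[np.ndarray], cfg: ScoreConfig,
                    masks: np.ndarray, parent_masks: list[np.ndarray]) -> np.ndarray:
    lookup = _family_lookup(rows, cfg)
    scores = np.zeros(masks.shape[0])
    for j in range(len(rows)):
        scores += lookup[j][parent_masks[j]]
    return scores


def score_all_core_dags(
    data: DiscretizedMatrix,
    gene_ids: Sequence[str],
    cfg: ScoreConfig = ScoreConfig(),
    with_shuffled: bool = False,
    seed: int = 0,
    reference: DAG | None = None,
    bootstrap: int = 0,
) -> CoreScanResult:
    """Score all 29,281 DAGs over 5 chosen genes (Bayesian score of every
    possible core wiring), optionally alongside one per-gene-shuffled
    realization of the same data and a bootstrap SD per graph.

    The 80 distinct (child, parent-set) family scores are precomputed once,
    making each graph's score a table lookup.
    """
    gene_ids = list(gene_ids)
    if len(gene_ids) != 5:
        raise DataError(f"exactly 5 gene ids required, got {len(gene_ids)}")
    k = 5
    rows = [data.row(g) for g in gene_ids]
    masks = _acyclic_edge_masks(k)
    edges = _edge_list(k)
    parent_masks = []
    for j in range(k):
        pm = np.zeros(masks.shape, dtype=np.uint8)
        for b, (i, jj) in enumerate(edges):
            if jj == j:
                pm |= ((masks >> np.uint32(b)) & 1).astype(np.uint8) << i
        parent_masks.append(pm)

    cols: dict[str, np.ndarray | list[str]] = {}
    edge_strings = []
    for mask in masks:
        mask = int(mask)
        es = sorted(f"{gene_ids[i]}->{gene_ids[j]}"
                    for b, (i, j) in enumerate(edges) if mask >> b & 1)
        edge_strings.append(";".join(es))
    cols["edges"] = edge_strings
    scores = _all_dag_scores(rows, cfg, masks, parent_masks)
    cols["score"] = scores

    if with_shuffled:
        sub = data.subset(gene_ids)
        shuffled = shuffle(sub, seed)
        srows = [shuffled.row(g) for g in gene_ids]
        cols["score_shuffled"] = _all_dag_scores(srows, cfg, masks, parent_masks)

    if bootstrap:
        if bootstrap < 2:
            raise ConfigError("bootstrap must be 0 or >= 2")
        rng = np.random.default_rng(seed)
        m = data.n_experiments
        acc = np.empty((bootstrap, masks.shape[0]))
        for b in range(bootstrap):
            idx = rng.integers(0, m, size=m)
            acc[b] = _all_dag_scores([r[idx] for r in rows], cfg, masks, parent_masks)
        cols["bootstrap_sd"] = acc.std(axis=0, ddof=1)

    table = pd.DataFrame(cols)
    ref_rank = None
    if reference is not None:
        label_to_idx = {g: i for i, g in enumerate(gene_ids)}
        if set(reference.nodes) != set(gene_ids):
            raise DataError("reference DAG nodes must equal the 5 gene ids")
        ref_score = 0.0
        for j, g in enumerate(gene_ids):
            pmask = 0
            for p in reference.parents(g):
                pmask |= 1 << label_to_idx[p]
            parents = [rows[label_to_idx[p]] for p in reference.parents(g)]
            ref_score += _family_ll(rows[j], parents, cfg.ess, cfg.arity)
        # best rank among ties: 1 + number of strictly better graphs
        ref_rank = int(1 + np.sum(scores > ref_score + 1e-12))
    return CoreScanResult(table, ref_rank)
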