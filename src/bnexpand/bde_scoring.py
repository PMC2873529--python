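"""Bayesian (BDeu) scoring of discrete networks and single-gene addition scores.

The score of a network G given 3-state data D is the log marginal likelihood
log P(D|G) under a uniform likelihood-equivalent Dirichlet parameter prior
(BDeu) with equivalent sample size ``ess``. With a uniform structure prior
over a fixed node set, log P(G|D) differs from log P(D|G) only by a constant,
so the structure-prior term is dropped and all comparisons are pure
log-marginal-likelihood differences.

The score decomposes over families (one child plus its parents):

    log P(D|G) = sum_i FamScore(V_i, Pa(V_i))

    FamScore = sum_j [ lgamma(a_j) - lgamma(a_j + N_j)
                       + sum_k ( lgamma(a_jk + N_jk) - lgamma(a_jk) ) ]

where j runs over the q = arity^|Pa| parent configurations, N_jk counts
experiments with parent configuration j and child state k, a_jk = ess/(arity*q)
and a_j = ess/q. An experiment contributes to a family iff the child and all
its parents are present there (per-family complete cases) — the simplest
policy consistent with a merged heterogeneous dataset.

The *Bayesian addition score* of a candidate gene is the best score of any
acyclic (k+1)-node network formed by attaching the gene to the core, minus
the core's own score. By decomposability only the new gene's family and the
core families that gain the new gene as a parent ever need rescoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .dag_core import DAG, CoreNetwork, Extension
from .data_model import MISSING_STATE, DiscretizedMatrix
from .errors import ConfigError, DataError

__all__ = [
    "ScoreConfig",
    "ScoredNetwork",
    "AdditionScoreResult",
    "family_score",
    "score_network",
    "addition_score",
    "bootstrap_score_sd",
]


@dataclass(frozen=True)
class ScoreConfig:
    """BDeu hyperparameters.

    ess: Dirichlet equivalent sample size (total prior pseudo-count).
    arity: number of discrete states per variable (3 for under/normal/over).
    missing_policy: how missing entries are handled; only per-family
        complete-case counting is implemented.
    """

    ess: float = 1.0
    arity: int = 3
    missing_policy: str = "family_complete_cases"

    def __post_init__(self) -> None:
        if self.ess <= 0:
            raise ConfigError(f"ess must be positive, got {self.ess}")
        if self.arity < 2:
            raise ConfigError(f"arity must be >= 2, got {self.arity}")
        if self.missing_policy != "family_complete_cases":
            raise ConfigError(f"unknown missing policy {self.missing_policy!r}")


@dataclass
class ScoredNetwork:
    dag: DAG
    score: float
    family_scores: dict[str, float]


@dataclass
class AdditionScoreResult:
    """Outcome of single-gene expansion for one candidate gene."""

    gene_id: str
    addition_score: float
    best_extension: Extension
    n_dependences: int
    rank: int | None = None


# ---------------------------------------------------------------------------
# Family scores on raw state arrays
# ---------------------------------------------------------------------------

def _family_ll(child: np.ndarray, parents: Sequence[np.ndarray], ess: float, arity: int) -> float:
    """BDeu log marginal likelihood of one family; complete cases only."""
    ok = child != MISSING_STATE
    for p in parents:
        ok = ok & (p != MISSING_STATE)
    cs = child[ok]
    if cs.size == 0:
        return 0.0
    q = arity ** len(parents)
    j = np.zeros(cs.shape, dtype=np.int64)
    for p in parents:
        j = j * arity + p[ok]
    counts = np.bincount(j * arity + cs, minlength=q * arity).astype(np.float64)
    counts = counts.reshape(q, arity)
    a_jk = ess / (arity * q)
    a_j = ess / q
    n_j = counts.sum(axis=1)
    score = float(np.sum(gammaln(a_j) - gammaln(a_j + n_j)))
    score += float(np.sum(gammaln(a_jk + counts) - gammaln(a_jk)))
    return score


def family_score(
    child: str,
    parents: Sequence[str],
    data: DiscretizedMatrix,
    cfg: ScoreConfig = ScoreConfig(),
) -> float:
    """BDeu family score for ``child`` given ``parents`` (matrix row ids)."""
    rows = [child, *parents]
    if len(set(rows)) != len(rows):
        raise DataError("child and parents must be distinct rows")
    return _family_ll(data.row(child), [data.row(p) for p in parents], cfg.ess, cfg.arity)


def _score_states(
    dag: DAG,
    states: Mapping[str, np.ndarray],
    cfg: ScoreConfig,
) -> dict[str, float]:
    return {
        node: _family_ll(states[node], [states[p] for p in dag.parents(node)],
                         cfg.ess, cfg.arity)
        for node in dag.nodes
    }


def score_network(
    g: DAG,
    data: DiscretizedMatrix,
    mapping: Mapping[str, str] | None = None,
    cfg: ScoreConfig = ScoreConfig(),
) -> ScoredNetwork:
    """Score a network: sum of BDeu family scores over its nodes."""
    if mapping is None:
        mapping = {n: n for n in g.nodes}
    states: dict[str, np.ndarray] = {}
    for node in g.nodes:
        if node not in mapping:
            raise DataError(f"node {node!r} has no expression-row mapping")
        states[node] = data.row(mapping[node])
    fams = _score_states(g, states, cfg)
    return ScoredNetwork(g, sum(fams.values()), fams)


# ---------------------------------------------------------------------------
# Addition scores
# ---------------------------------------------------------------------------

def addition_score(
    core: CoreNetwork,
    extensions: Iterable[Extension],
    data: DiscretizedMatrix,
    cfg: ScoreConfig = ScoreConfig(),
    new_gene_row: str | None = None,
) -> AdditionScoreResult:
    """Best score gain from attaching one new gene to the core in any
    acyclic way; the first extension attaining the maximum (in stream order)
    is reported, with its edge count as the gene's dependence count.

    Decomposability makes each extension cheap: its gain is the new gene's
    family score given its in-edge parents, plus, for each core node gaining
    the new gene as a parent, that family's score change. Both pieces are
    cached across extensions.
    """
    gm = core.gene_map
    new_states: np.ndarray | None = None
    base_fam: dict[str, float] = {}
    fam_new_cache: dict[frozenset[str], float] = {}
    delta_child_cache: dict[str, float] = {}
    core_states = {n: data.row(gm[n]) for n in core.nodes}

    best: tuple[float, Extension] | None = None
    gene: str | None = None
    for ext in extensions:
        if gene is None:
            gene = ext.new_gene
            row_id = new_gene_row if new_gene_row is not None else gene
            new_states = data.row(row_id)
            base_fam = {
                n: _family_ll(core_states[n],
                              [core_states[p] for p in core.dag.parents(n)],
                              cfg.ess, cfg.arity)
                for n in core.nodes
            }
        elif ext.new_gene != gene:
            raise DataError(
                f"extension stream mixes genes {gene!r} and {ext.new_gene!r}"
            )
        key = ext.in_edges
        if key not in fam_new_cache:
            fam_new_cache[key] = _family_ll(
                new_states, [core_states[p] for p in sorted(key)], cfg.ess, cfg.arity
            )
        gain = fam_new_cache[key]
        for child in ext.out_edges:
            if child not in delta_child_cache:
                with_new = _family_ll(
                    core_states[child],
                    [core_states[p] for p in core.dag.parents(child)] + [new_states],
                    cfg.ess, cfg.arity,
                )
                delta_child_cache[child] = with_new - base_fam[child]
            gain += delta_child_cache[child]
        if best is None or gain > best[0]:
            best = (gain, ext)
    if best is None:
        raise DataError("empty extension stream")
    return AdditionScoreResult(
        gene_id=new_gene_row if new_gene_row is not None else gene,
        addition_score=best[0],
        best_extension=best[1],
        n_dependences=best[1].n_edges,
    )


# ---------------------------------------------------------------------------
# Bootstrap variability
# ---------------------------------------------------------------------------

def bootstrap_score_sd(
    g: DAG,
    data: DiscretizedMatrix,
    mapping: Mapping[str, str] | None = None,
    cfg: ScoreConfig = ScoreConfig(),
    B: int = 100,
    seed: int = 0,
) -> float:
    """SD (ddof=1) of the network score over B resamples of the experiments
    (columns drawn with replacement); deterministic given ``seed``."""
    if B < 2:
        raise ConfigError(f"B must be >= 2, got {B}")
    if mapping is None:
        mapping = {n: n for n in g.nodes}
    rows = {n: data.row(mapping[n]) for n in g.nodes}
    m = data.n_experiments
    rng = np.random.default_rng(seed)
    scores = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, m, size=m)
        states = {n: r[idx] for n, r in rows.items()}
        scores[b] = sum(_score_states(g, states, cfg).values())
    return float(np.std(scores, ddof=1))
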