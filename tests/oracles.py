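"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: DAG enumeration by
filtering every edge subset through networkx; the BDeu family score via the
sequential prior-predictive product; addition scores by naive full-network
rescoring; Markov equivalence via the skeleton + v-structure criterion.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from bnexpand.bde_scoring import ScoreConfig, score_network
from bnexpand.dag_core import DAG, CoreNetwork, Extension
from bnexpand.data_model import MISSING_STATE


def brute_force_dag_edge_sets(n: int) -> list[frozenset[tuple[int, int]]]:
    """Every acyclic subset of the n(n-1) possible directed edges."""
    edges = [(i, j) for i in range(n) for j in range(n) if i != j]
    out = []
    for r in range(len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            g.add_edges_from(combo)
            if nx.is_directed_acyclic_graph(g):
                out.append(frozenset(combo))
    return out


def brute_force_extensions(core: CoreNetwork, new_gene: str) -> set[tuple]:
    """All acyclic attachments, by checking each of the 4^k in/out subsets
    on the combined graph with networkx."""
    nodes = core.dag.nodes
    out = set()
    for in_sub in _subsets(nodes):
        for out_sub in _subsets(nodes):
            if set(in_sub) & set(out_sub):
                continue
            g = core.dag.to_networkx()
            g.add_node(new_gene)
            g.add_edges_from((c, new_gene) for c in in_sub)
            g.add_edges_from((new_gene, c) for c in out_sub)
            if nx.is_directed_acyclic_graph(g):
                out.add((frozenset(in_sub), frozenset(out_sub)))
    return out


def _subsets(items):
    for r in range(len(items) + 1):
        yield from itertools.combinations(items, r)


def sequential_predictive_ll(
    child: np.ndarray,
    parents: list[np.ndarray],
    ess: float,
    arity: int,
) -> float:
    """log marginal likelihood as the chained prior-predictive product:
    P(D) = prod_t P(x_t | x_<t), each factor (a_jk + N_jk) / (a_j + N_j)
    with counts accumulated over the preceding complete cases."""
    q = arity ** len(parents)
    a_jk = ess / (arity * q)
    counts = np.zeros((q, arity))
    ll = 0.0
    for t in range(child.shape[0]):
        if child[t] == MISSING_STATE or any(p[t] == MISSING_STATE for p in parents):
            continue
        j = 0
        for p in parents:
            j = j * arity + int(p[t])
        k = int(child[t])
        num = a_jk + counts[j, k]
        den = arity * a_jk + counts[j].sum()
        ll += math.log(num / den)
        counts[j, k] += 1
    return ll


def naive_addition_score(core, extensions, data, cfg=ScoreConfig(), new_gene_row=None):
    """max over extensions of [score(core+ext) - score(core)] by rescoring
    the whole expanded network each time."""
    core_score = score_network(core.dag, data, core.gene_map, cfg).score
    best = None
    for ext in extensions:
        mapping = dict(core.gene_map)
        mapping[ext.new_gene] = new_gene_row if new_gene_row is not None else ext.new_gene
        combined = ext.combined_dag(core)
        s = score_network(combined, data, mapping, cfg).score
        gain = s - core_score
        if best is None or gain > best[0]:
            best = (gain, ext)
    return best


def markov_equivalence_key(dag: DAG):
    """Verma-Pearl characterisation: skeleton + set of v-structures."""
    skeleton = frozenset(frozenset(e) for e in dag.edges)
    vstructs = set()
    for node in dag.nodes:
        ps = dag.parents(node)
        for a, b in itertools.combinations(ps, 2):
            if (a, b) not in dag.edges and (b, a) not in dag.edges:
                vstructs.add((frozenset((a, b)), node))
    return skeleton, frozenset(vstructs)
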