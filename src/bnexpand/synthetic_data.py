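"""Synthetic expression datasets with known ground truth.

Emulates the regime the method targets — thousands of heterogeneous
experiments over a few hundred to a few thousand genes, a small core pathway
with known wiring — while keeping every planted dependence auditable:

* **core** genes: ancestral samples from a 5-node discrete Bayesian network
  with asymmetric conditional probability tables (chain with a fork).
* **pairwise** genes: copy one random core gene's state, corrupted by a
  state-flip at rate ``pairwise_noise`` — detectable by plain correlation.
* **higher_order** genes: a deterministic two-parent rule over two random
  core genes, corrupted at ``higher_order_noise``. The default ``xor_like``
  rule, state = (s1 + s2) mod 3, is the canonical dependence invisible to
  pairwise correlation (marginally independent of each parent when parent
  marginals are uniform) yet fully captured by a 2-parent family.
  ``and_like`` is state = min(s1, s2).
* **independent** genes: uniform over the 3 states.
* **lowquality** genes: uniform states with inflated continuous emission
  noise, mimicking the high-variance low-quality tail of real arrays.

When ``continuous_emission`` is set, each state emits a Gaussian value
(state means straddling zero so a z-score discretizer with c = 1
approximately recovers the generating states); otherwise states are returned
directly. Entries are dropped (missing) at ``missing_rate``. All randomness
flows from one seed through per-gene substreams, so datasets are bit-exactly
reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import yaml

from .dag_core import DAG, CoreNetwork
from .data_model import MISSING_STATE, DiscretizedMatrix, ExpressionMatrix
from .errors import ConfigError, DataError

__all__ = [
    "CoreModel",
    "ContinuousEmission",
    "GeneratorSpec",
    "GroundTruth",
    "sample_dataset",
    "default_core_spec",
    "write_ground_truth",
    "spec_to_yaml",
    "spec_from_yaml",
]

ARITY = 3


@dataclass
class CoreModel:
    """A small discrete Bayesian network: DAG plus per-node CPTs.

    ``cpds[node]`` has shape (3,)*len(parents) + (3,), indexed by parent
    states in the order ``dag.parents(node)`` (sorted); every row must sum
    to 1.
    """

    dag: DAG
    cpds: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.cpds:
                raise DataError(f"no CPT for core node {node!r}")
            t = np.asarray(self.cpds[node], dtype=float)
            expect = (ARITY,) * len(self.dag.parents(node)) + (ARITY,)
            if t.shape != expect:
                raise DataError(f"CPT for {node!r} has shape {t.shape}, expected {expect}")
            if (t < 0).any() or (t > 1).any():
                raise DataError(f"CPT for {node!r} has probabilities outside [0,1]")
            if not np.allclose(t.sum(axis=-1), 1.0, atol=1e-12):
                raise DataError(f"CPT rows for {node!r} do not sum to 1")
            self.cpds[node] = t

    def marginals(self) -> dict[str, np.ndarray]:
        """Exact per-node state marginals by summing the full joint (the
        core is tiny, so 3^k enumeration is exact and cheap)."""
        from itertools import product

        nodes = self.dag.nodes
        margs = {n: np.zeros(ARITY) for n in nodes}
        parent_lists = {n: self.dag.parents(n) for n in nodes}
        for assignment in product(range(ARITY), repeat=len(nodes)):
            state = dict(zip(nodes, assignment))
            p = 1.0
            for n in nodes:
                idx = tuple(state[q] for q in parent_lists[n]) + (state[n],)
                p *= self.cpds[n][idx]
            for n in nodes:
                margs[n][state[n]] += p
        return margs


@dataclass
class ContinuousEmission:
    """Per-state Gaussian emission for the continuous output path."""

    means: tuple[float, float, float] = (-1.5, 0.0, 1.5)
    sds: tuple[float, float, float] = (0.3, 0.3, 0.3)
    lowquality_sd: float = 2.5

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sds) or self.lowquality_sd <= 0:
            raise ConfigError("emission sds must be positive")


@dataclass
class GeneratorSpec:
    """Full description of a synthetic dataset (reproducible from seed)."""

    core: CoreModel
    n_pairwise: int = 20
    pairwise_noise: float = 0.1
    n_higher_order: int = 10
    higher_order_rule: str = "xor_like"
    higher_order_noise: float = 0.05
    n_independent: int = 400
    n_lowquality: int = 30
    m_experiments: int = 500
    continuous_emission: Optional[ContinuousEmission] = None
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairwise", "n_higher_order", "n_independent",
                     "n_lowquality", "m_experiments"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.pairwise_noise <= 0.5:
            raise ConfigError("pairwise_noise must be in [0, 0.5]")
        if not 0 <= self.higher_order_noise <= 0.5:
            raise ConfigError("higher_order_noise must be in [0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.higher_order_rule not in ("xor_like", "and_like"):
            raise ConfigError(f"unknown higher_order_rule {self.higher_order_rule!r}")

    @property
    def n_genes(self) -> int:
        return (len(self.core.dag.nodes) + self.n_pairwise + self.n_higher_order
                + self.n_independent + self.n_lowquality)


@dataclass
class GroundTruth:
    """Per-gene class labels and, for planted genes, their core parents."""

    classes: dict[str, str]
    parents: dict[str, tuple[str, ...]]

    def genes_of_class(self, label: str) -> list[str]:
        return [g for g, c in self.classes.items() if c == label]


def _flip_states(states: np.ndarray, rate: float, rng) -> np.ndarray:
    """With probability ``rate`` replace a state by one of the other two."""
    out = states.copy()
    flip = rng.random(states.size) < rate
    if flip.any():
        shift = rng.integers(1, ARITY, size=int(flip.sum()))
        out[flip] = (out[flip] + shift) % ARITY
    return out


def xor_like(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    return ((s1 + s2) % ARITY).astype(np.int8)


def and_like(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    return np.minimum(s1, s2).astype(np.int8)


_RULES = {"xor_like": xor_like, "and_like": and_like}


def sample_dataset(
    spec: GeneratorSpec,
) -> tuple[Union[DiscretizedMatrix, ExpressionMatrix], GroundTruth]:
    """Draw one dataset from ``spec``.

    Returns a :class:`DiscretizedMatrix` (or :class:`ExpressionMatrix` when
    ``spec.continuous_emission`` is set) plus the ground truth. Deterministic
    given ``spec.seed``.
    """
    m = spec.m_experiments
    core_nodes = spec.core.dag.nodes
    import networkx as nx

    order = list(nx.topological_sort(spec.core.dag.to_networkx()))

    ss = np.random.SeedSequence(spec.seed)
    n_planted = spec.n_pairwise + spec.n_higher_order + spec.n_independent + spec.n_lowquality
    streams = ss.spawn(3 + n_planted)
    core_rng = np.random.default_rng(streams[0])
    emission_rng = np.random.default_rng(streams[1])
    missing_rng = np.random.default_rng(streams[2])
    gene_streams = iter(streams[3:])

    core_states: dict[str, np.ndarray] = {}
    for node in order:
        parents = spec.core.dag.parents(node)
        t = spec.core.cpds[node]
        if parents:
            idx = np.zeros(m, dtype=np.int64)
            for p in parents:
                idx = idx * ARITY + core_states[p]
            rows = t.reshape(-1, ARITY)[idx]
            cum = rows.cumsum(axis=1)
            u = core_rng.random(m)
            core_states[node] = (u[:, None] > cum).sum(axis=1).astype(np.int8)
        else:
            cum = t.cumsum()
            u = core_rng.random(m)
            core_states[node] = (u[:, None] > cum[None, :]).sum(axis=1).astype(np.int8)

    gene_ids: list[str] = list(core_nodes)
    states_rows: list[np.ndarray] = [core_states[n] for n in core_nodes]
    classes: dict[str, str] = {n: "core" for n in core_nodes}
    parents_of: dict[str, tuple[str, ...]] = {}

    for i in range(spec.n_pairwise):
        rng = np.random.default_rng(next(gene_streams))
        parent = core_nodes[rng.integers(len(core_nodes))]
        s = _flip_states(core_states[parent], spec.pairwise_noise, rng)
        g = f"pair{i + 1:03d}"
        gene_ids.append(g)
        states_rows.append(s)
        classes[g] = "pairwise"
        parents_of[g] = (parent,)

    rule = _RULES[spec.higher_order_rule]
    for i in range(spec.n_higher_order):
        rng = np.random.default_rng(next(gene_streams))
        p1, p2 = (core_nodes[j] for j in rng.choice(len(core_nodes), size=2, replace=False))
        s = rule(core_states[p1], core_states[p2])
        s = _flip_states(s, spec.higher_order_noise, rng)
        g = f"hi{i + 1:03d}"
        gene_ids.append(g)
        states_rows.append(s)
        classes[g] = "higher_order"
        parents_of[g] = (p1, p2)

    for i in range(spec.n_independent):
        rng = np.random.default_rng(next(gene_streams))
        g = f"ind{i + 1:03d}"
        gene_ids.append(g)
        states_rows.append(rng.integers(0, ARITY, size=m).astype(np.int8))
        classes[g] = "independent"

    for i in range(spec.n_lowquality):
        rng = np.random.default_rng(next(gene_streams))
        g = f"low{i + 1:03d}"
        gene_ids.append(g)
        states_rows.append(rng.integers(0, ARITY, size=m).astype(np.int8))
        classes[g] = "lowquality"

    states = np.vstack(states_rows)
    exp_ids = tuple(f"exp{j + 1:04d}" for j in range(m))
    missing = missing_rng.random(states.shape) < spec.missing_rate
    truth = GroundTruth(classes, parents_of)

    if spec.continuous_emission is None:
        st = states.copy()
        st[missing] = MISSING_STATE
        return DiscretizedMatrix(tuple(gene_ids), exp_ids, st), truth

    em = spec.continuous_emission
    means = np.asarray(em.means)[states]
    sds = np.asarray(em.sds)[states]
    lowq = np.array([classes[g] == "lowquality" for g in gene_ids])
    sds[lowq, :] = em.lowquality_sd
    values = means + sds * emission_rng.standard_normal(states.shape)
    values[missing] = np.nan
    return ExpressionMatrix(tuple(gene_ids), exp_ids, values), truth


def default_core_model() -> CoreModel:
    """The documented 5-node chain/fork core: C1->C2, C2->C3, C2->C4, C4->C5,
    with asymmetric CPTs (children track their parent ~60-75% of the time)."""
    dag = DAG(("C1", "C2", "C3", "C4", "C5"),
              [("C1", "C2"), ("C2", "C3"), ("C2", "C4"), ("C4", "C5")])
    cpds = {
        "C1": np.array([0.5, 0.3, 0.2]),
        "C2": np.array([[0.70, 0.20, 0.10],
                        [0.15, 0.70, 0.15],
                        [0.10, 0.20, 0.70]]),
        "C3": np.array([[0.75, 0.15, 0.10],
                        [0.20, 0.60, 0.20],
                        [0.05, 0.25, 0.70]]),
        "C4": np.array([[0.60, 0.30, 0.10],
                        [0.25, 0.50, 0.25],
                        [0.10, 0.30, 0.60]]),
        "C5": np.array([[0.70, 0.20, 0.10],
                        [0.15, 0.70, 0.15],
                        [0.10, 0.20, 0.70]]),
    }
    return CoreModel(dag, cpds)


def strong_core_model(diag: float = 0.9) -> CoreModel:
    """Same wiring as :func:`default_core_model` but with strongly
    deterministic CPTs (each child tracks its parent with probability
    ``diag``). In this regime the dependence signal in the data dominates
    the BDeu complexity-penalty spread across graphs, so the score
    distribution over all 5-node wirings is much wider on intact than on
    shuffled data — the regime in which scoring the full graph space
    visibly separates signal from the permutation null."""
    if not 1 / ARITY < diag < 1:
        raise ConfigError(f"diag must be in (1/3, 1), got {diag}")
    off = (1 - diag) / 2
    cpt = np.full((ARITY, ARITY), off)
    np.fill_diagonal(cpt, diag)
    dag = default_core_model().dag
    cpds = {"C1": np.array([0.5, 0.3, 0.2])}
    for node in ("C2", "C3", "C4", "C5"):
        cpds[node] = cpt.copy()
    return CoreModel(dag, cpds)


def default_core_spec(seed: int = 0) -> GeneratorSpec:
    """The reference synthetic regime: 5 core + 20 pairwise + 10 higher-order
    + 400 independent + 30 low-quality genes over 500 experiments with 2%
    missing entries, returned as 3-state data directly (no continuous
    emission, so planted dependences are not diluted by discretization
    error; pass a :class:`ContinuousEmission` to exercise that path)."""
    return GeneratorSpec(
        core=default_core_model(),
        n_pairwise=20,
        pairwise_noise=0.1,
        n_higher_order=10,
        higher_order_rule="xor_like",
        higher_order_noise=0.05,
        n_independent=400,
        n_lowquality=30,
        m_experiments=500,
        continuous_emission=None,
        missing_rate=0.02,
        seed=seed,
    )


def core_network(model: CoreModel) -> CoreNetwork:
    """The generator core as a CoreNetwork (identity row mapping)."""
    return CoreNetwork(model.dag)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "class", "parents"])
        for g, c in truth.classes.items():
            w.writerow([g, c, ",".join(truth.parents.get(g, ()))])


def spec_to_yaml(spec: GeneratorSpec, path) -> None:
    doc = {
        "core": {
            "nodes": list(spec.core.dag.nodes),
            "edges": sorted([list(e) for e in spec.core.dag.edges]),
            "cpds": {n: np.asarray(t).tolist() for n, t in spec.core.cpds.items()},
        },
        "n_pairwise": spec.n_pairwise,
        "pairwise_noise": spec.pairwise_noise,
        "n_higher_order": spec.n_higher_order,
        "higher_order_rule": spec.higher_order_rule,
        "higher_order_noise": spec.higher_order_noise,
        "n_independent": spec.n_independent,
        "n_lowquality": spec.n_lowquality,
        "m_experiments": spec.m_experiments,
        "continuous_emission": (
            None if spec.continuous_emission is None else {
                "means": list(spec.continuous_emission.means),
                "sds": list(spec.continuous_emission.sds),
                "lowquality_sd": spec.continuous_emission.lowquality_sd,
            }
        ),
        "missing_rate": spec.missing_rate,
        "seed": spec.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> GeneratorSpec:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    core_doc = doc["core"]
    dag = DAG(core_doc["nodes"], [tuple(e) for e in core_doc["edges"]])
    cpds = {n: np.asarray(t) for n, t in core_doc["cpds"].items()}
    ce = doc.get("continuous_emission")
    emission = None if ce is None else ContinuousEmission(
        tuple(ce["means"]), tuple(ce["sds"]), ce["lowquality_sd"]
    )
    return GeneratorSpec(
        core=CoreModel(dag, cpds),
        n_pairwise=doc["n_pairwise"],
        pairwise_noise=doc["pairwise_noise"],
        n_higher_order=doc["n_higher_order"],
        higher_order_rule=doc["higher_order_rule"],
        higher_order_noise=doc["higher_order_noise"],
        n_independent=doc["n_independent"],
        n_lowquality=doc["n_lowquality"],
        m_experiments=doc["m_experiments"],
        continuous_emission=emission,
        missing_rate=doc["missing_rate"],
        seed=doc["seed"],
    )
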