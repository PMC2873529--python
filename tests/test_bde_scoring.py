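import math
from dataclasses import replace

import numpy as np
import pytest

from bnexpand.bde_scoring import (
    ScoreConfig,
    addition_score,
    bootstrap_score_sd,
    family_score,
    score_network,
)
from bnexpand.dag_core import DAG, CoreNetwork, enumerate_extensions
from bnexpand.data_model import DiscretizedMatrix, shuffle
from bnexpand.errors import ConfigError, DataError
from bnexpand.expansion import score_all_core_dags
from bnexpand.synthetic_data import GeneratorSpec, sample_dataset, strong_core_model
from conftest import random_discretized
from oracles import markov_equivalence_key, naive_addition_score, sequential_predictive_ll


def dm(states, prefix="g"):
    states = np.asarray(states, dtype=np.int8)
    return DiscretizedMatrix(
        tuple(f"{prefix}{i}" for i in range(states.shape[0])),
        tuple(f"e{j}" for j in range(states.shape[1])),
        states,
    )


class TestFamilyScore:
    def test_no_usable_data_scores_zero(self):
        d = dm([[-1, -1], [0, 1]])
        assert family_score("g0", ["g1"], d) == 0.0

    def test_parentless_ternary_uniform_counts(self):
        # prior-predictive product (1/3)(1/6)(1/9) = 1/162
        d = dm([[0, 1, 2]])
        assert family_score("g0", [], d) == pytest.approx(math.log(1 / 162), abs=1e-12)

    def test_parentless_binary_single_observation(self):
        d = dm([[1]])
        cfg = ScoreConfig(ess=1.0, arity=2)
        assert family_score("g0", [], d, cfg) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_duplicate_rows_rejected(self):
        d = dm([[0, 1], [1, 2]])
        with pytest.raises(DataError):
            family_score("g0", ["g0"], d)

    @pytest.mark.parametrize("case", range(10))
    def test_matches_sequential_predictive_oracle(self, case):
        # 10 parametrized cases x 12 draws = 120 random instances
        rng = np.random.default_rng(100 + case)
        for _ in range(12):
            n = int(rng.integers(1, 5))
            m = int(rng.integers(1, 11))
            d = random_discretized(rng, n, m, missing_rate=0.15)
            child = "g0"
            parents = [f"g{i}" for i in range(1, n)]
            ess = float(rng.choice([0.5, 1.0, 3.0]))
            cfg = ScoreConfig(ess=ess)
            expected = sequential_predictive_ll(
                d.row(child), [d.row(p) for p in parents], ess, 3
            )
            assert family_score(child, parents, d, cfg) == pytest.approx(
                expected, abs=1e-9
            )

    def test_copy_parent_improves_family_score(self):
        # deterministic child == parent: conditioning must help at m >= 5
        rng = np.random.default_rng(0)
        row = rng.integers(0, 3, size=30).astype(np.int8)
        d = dm(np.vstack([row, row.copy()]))
        assert family_score("g0", ["g1"], d) > family_score("g0", [], d)


class TestScoreNetwork:
    def test_decomposability_exact(self):
        rng = np.random.default_rng(1)
        d = random_discretized(rng, 4, 25, missing_rate=0.1)
        g = DAG(d.gene_ids, [("g0", "g1"), ("g0", "g2"), ("g1", "g3"), ("g2", "g3")])
        res = score_network(g, d)
        assert res.score == sum(res.family_scores.values())
        assert res.score == pytest.approx(
            sum(family_score(n, list(g.parents(n)), d) for n in g.nodes), abs=1e-12
        )

    def test_score_negative_on_nonempty_data(self):
        rng = np.random.default_rng(2)
        d = random_discretized(rng, 3, 10)
        assert score_network(DAG(d.gene_ids), d).score < 0

    def test_two_node_reversal_equivalence(self):
        # complete data: with per-family complete-case counting, missing
        # entries give the two orientations different effective samples
        rng = np.random.default_rng(3)
        d = random_discretized(rng, 2, 40)
        ab = score_network(DAG(("g0", "g1"), [("g0", "g1")]), d).score
        ba = score_network(DAG(("g0", "g1"), [("g1", "g0")]), d).score
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_markov_equivalent_three_node_dags_score_identically(self):
        from bnexpand.dag_core import enumerate_dags

        rng = np.random.default_rng(4)
        d = random_discretized(rng, 3, 60)
        by_class: dict = {}
        for g in enumerate_dags(3, labels=d.gene_ids):
            key = markov_equivalence_key(g)
            by_class.setdefault(key, []).append(score_network(g, d).score)
        assert len(by_class) == 11  # known 3-node equivalence class count
        for scores in by_class.values():
            assert max(scores) - min(scores) < 1e-9

    def test_unmapped_node_raises(self):
        d = dm([[0, 1, 2]])
        with pytest.raises(DataError, match="g9"):
            score_network(DAG(("g0", "g9"), []), d, {"g0": "g0"})


class TestAdditionScore:
    def test_disconnected_best_equals_marginal_family(self, chain_core):
        # candidate independent of the core: its best attachment is usually
        # the empty one, and then the gain is exactly its own marginal score
        rng = np.random.default_rng(5)
        states = np.vstack(
            [rng.integers(0, 3, size=(3, 200)),
             rng.integers(0, 3, size=(1, 200))]
        ).astype(np.int8)
        d = DiscretizedMatrix(("a", "b", "c", "x"), tuple(f"e{j}" for j in range(200)),
                              states)
        res = addition_score(chain_core, enumerate_extensions(chain_core, "x"), d)
        if not res.best_extension.n_edges:
            assert res.addition_score == pytest.approx(
                family_score("x", [], d), abs=1e-12
            )
        assert res.n_dependences == res.best_extension.n_edges

    @pytest.mark.parametrize("seed", range(20))
    def test_decomposed_equals_naive_full_rescoring(self, seed):
        rng = np.random.default_rng(200 + seed)
        d = random_discretized(rng, 4, 12, missing_rate=0.2)
        core = CoreNetwork(DAG(("g0", "g1", "g2"), [("g0", "g1")]))
        fast = addition_score(core, enumerate_extensions(core, "g3"), d)
        gain, ext = naive_addition_score(
            core, enumerate_extensions(core, "g3"), d
        )
        assert fast.addition_score == pytest.approx(gain, abs=1e-9)
        assert (fast.best_extension.in_edges, fast.best_extension.out_edges) == (
            ext.in_edges, ext.out_edges
        )

    def test_copy_of_core_gene_beats_noise_gene(self):
        rng = np.random.default_rng(6)
        m = 50
        a = rng.integers(0, 3, size=m).astype(np.int8)
        b = rng.integers(0, 3, size=m).astype(np.int8)
        copy_a = a.copy()
        noise = rng.integers(0, 3, size=m).astype(np.int8)
        d = DiscretizedMatrix(("a", "b", "dup", "noise"),
                              tuple(f"e{j}" for j in range(m)),
                              np.vstack([a, b, copy_a, noise]))
        core = CoreNetwork(DAG(("a", "b"), [("a", "b")]))
        s_dup = addition_score(core, enumerate_extensions(core, "dup"), d)
        s_noise = addition_score(core, enumerate_extensions(core, "noise"), d)
        assert s_dup.addition_score > s_noise.addition_score

    def test_empty_stream_raises(self, chain_core):
        d = dm([[0, 1], [1, 2], [2, 0]], prefix="n")
        with pytest.raises(DataError):
            addition_score(chain_core, iter(()), d)


class TestBootstrap:
    def test_single_experiment_sd_zero(self):
        d = dm([[1], [2]])
        g = DAG(("g0", "g1"), [("g0", "g1")])
        assert bootstrap_score_sd(g, d, B=10, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_and_nonnegative(self):
        rng = np.random.default_rng(7)
        d = random_discretized(rng, 2, 30)
        g = DAG(("g0", "g1"), [("g0", "g1")])
        a = bootstrap_score_sd(g, d, B=25, seed=3)
        b = bootstrap_score_sd(g, d, B=25, seed=3)
        assert a == b >= 0

    def test_b_too_small(self):
        d = dm([[0, 1]])
        with pytest.raises(ConfigError):
            bootstrap_score_sd(DAG(("g0",)), d, B=1, seed=0)


class TestConsistency:
    def test_true_dag_beats_everything_outside_its_equivalence_class(self):
        # ancestral samples from a strongly-dependent 5-node network at
        # m=2000: the generating DAG must outscore every DAG not Markov
        # equivalent to it
        model = strong_core_model()
        spec = GeneratorSpec(core=model, n_pairwise=0, n_higher_order=0,
                             n_independent=0, n_lowquality=0,
                             m_experiments=2000, missing_rate=0.0, seed=9)
        data, _ = sample_dataset(spec)
        res = score_all_core_dags(data, list(model.dag.nodes),
                                  reference=model.dag)
        true_key = markov_equivalence_key(model.dag)
        true_score = score_network(model.dag, data).score
        from bnexpand.dag_core import enumerate_dags

        worst_violation = 0.0
        for g, s in zip(enumerate_dags(5, labels=model.dag.nodes),
                        res.table.score):
            if markov_equivalence_key(g) != true_key:
                assert s <= true_score + 1e-9
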