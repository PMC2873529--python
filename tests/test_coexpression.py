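import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnexpand.coexpression import (
    coexpression_score,
    method_overlap,
    rank_genes_by_coexpression,
)
from bnexpand.dag_core import DAG, CoreNetwork
from bnexpand.data_model import ExpressionMatrix
from bnexpand.errors import DataError
from bnexpand.expansion import rank_genes
from bnexpand.synthetic_data import core_network, default_core_spec, sample_dataset


def em(rows, ids):
    rows = np.asarray(rows, dtype=float)
    return ExpressionMatrix(tuple(ids), tuple(f"e{j}" for j in range(rows.shape[1])),
                            rows)


@pytest.fixture
def single_core():
    return CoreNetwork(DAG(("a",)))


class TestCoexpressionScore:
    def test_identical_profile_scores_one(self, single_core):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        d = em([x, x.copy()], ["a", "g"])
        score, n = coexpression_score("g", single_core, d)
        assert score == pytest.approx(1.0)
        assert n == 1

    def test_constant_gene_is_undefined(self, single_core):
        rng = np.random.default_rng(1)
        d = em([rng.normal(size=20), np.full(20, 3.0)], ["a", "g"])
        score, n = coexpression_score("g", single_core, d)
        assert math.isnan(score) and n == 0

    def test_negated_profile_scores_minus_one(self, single_core):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        d = em([x, -x], ["a", "g"])
        assert coexpression_score("g", single_core, d)[0] == pytest.approx(-1.0)

    def test_absolute_mode_flips_negation(self, single_core):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        d = em([x, -x], ["a", "g"])
        assert coexpression_score("g", single_core, d, absolute=True)[0] == (
            pytest.approx(1.0)
        )

    def test_min_overlap_enforced(self, single_core):
        x = np.array([1.0, 2.0, 3.0, np.nan, np.nan, np.nan, np.nan, np.nan])
        y = np.array([1.0, 2.5, 2.9, 4.0, 5.0, 6.0, 7.0, 8.0])
        d = em([y, x], ["a", "g"])
        assert math.isnan(coexpression_score("g", single_core, d, min_overlap=6)[0])
        assert not math.isnan(coexpression_score("g", single_core, d, min_overlap=3)[0])

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(4)
        core_row = rng.normal(size=30)
        gene = 0.6 * core_row + rng.normal(scale=0.5, size=30)
        d1 = em([core_row, gene], ["a", "g"])
        d2 = em([core_row, scale * gene + offset], ["a", "g"])
        core = CoreNetwork(DAG(("a",)))
        assert coexpression_score("g", core, d1)[0] == pytest.approx(
            coexpression_score("g", core, d2)[0], abs=1e-9
        )

    def test_xor_gene_scores_far_below_pairwise_genes(self):
        # the ternary-xor child is exactly independent of each parent under
        # uniform parent marginals; with the core's correlated, skewed
        # marginals a small residual correlation (~0.2 max) survives, far
        # below the pairwise-copy genes
        spec = default_core_spec(seed=3)
        data, truth = sample_dataset(spec)
        core = core_network(spec.core)
        pairwise_scores = [coexpression_score(g, core, data)[0]
                           for g in truth.genes_of_class("pairwise")]
        for g in truth.genes_of_class("higher_order"):
            score, _ = coexpression_score(g, core, data)
            assert score < min(pairwise_scores)

    def test_xor_of_independent_parents_is_uncorrelated(self):
        # the clean version of the claim: with independent uniform parents
        # the ternary-xor child is exactly independent of each parent, so
        # its empirical correlation at m=500 is near zero
        from bnexpand.synthetic_data import xor_like

        rng = np.random.default_rng(20)
        p1 = rng.integers(0, 3, size=500).astype(np.int8)
        p2 = rng.integers(0, 3, size=500).astype(np.int8)
        child = xor_like(p1, p2)
        for p in (p1, p2):
            assert abs(np.corrcoef(child, p)[0, 1]) < 0.2


class TestRanking:
    def test_duplicate_of_core_ranks_above_noise(self):
        rng = np.random.default_rng(5)
        m = 200
        a = rng.normal(size=m)
        rows = [a, a + rng.normal(scale=0.2, size=m)] + [
            rng.normal(size=m) for _ in range(5)
        ]
        d = em(rows, ["a", "dup", "n1", "n2", "n3", "n4", "n5"])
        t = rank_genes_by_coexpression(CoreNetwork(DAG(("a",))), d)
        assert t.results[0].gene_id == "dup"

    def test_single_core_reduces_to_plain_correlation(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(6, 40))
        d = em(vals, [f"g{i}" for i in range(6)])
        core = CoreNetwork(DAG(("g0",)))
        t = rank_genes_by_coexpression(core, d)
        expected = sorted(
            ((np.corrcoef(vals[0], vals[i])[0, 1], f"g{i}") for i in range(1, 6)),
            key=lambda p: (-p[0], p[1]),
        )
        assert [g for _, g in expected] == [r.gene_id for r in t.results]

    def test_invariant_to_experiment_order(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(5, 30))
        d = em(vals, [f"g{i}" for i in range(5)])
        perm = rng.permutation(30)
        d2 = ExpressionMatrix(d.gene_ids,
                              tuple(d.experiment_ids[j] for j in perm),
                              vals[:, perm])
        core = CoreNetwork(DAG(("g0", "g1")))
        t1 = rank_genes_by_coexpression(core, d)
        t2 = rank_genes_by_coexpression(core, d2)
        assert t1.gene_ids() == t2.gene_ids()

    def test_undefined_scores_quarantined_last(self):
        rng = np.random.default_rng(8)
        rows = [rng.normal(size=20), rng.normal(size=20), np.full(20, 1.0)]
        d = em(rows, ["a", "g1", "flat"])
        t = rank_genes_by_coexpression(CoreNetwork(DAG(("a",))), d)
        assert t.results[-1].gene_id == "flat"
        assert t.results[-1].rank is None
        assert [r.rank for r in t.ranked()] == [1]

    def test_core_gene_absent_raises(self):
        rng = np.random.default_rng(9)
        d = em(rng.normal(size=(2, 10)), ["g1", "g2"])
        with pytest.raises(DataError):
            rank_genes_by_coexpression(CoreNetwork(DAG(("zzz",))), d)


class TestMethodOverlap:
    @staticmethod
    def _bayes_table():
        spec = replace(default_core_spec(seed=1), n_pairwise=3, n_higher_order=0,
                       n_independent=8, n_lowquality=0, m_experiments=80)
        data, _ = sample_dataset(spec)
        return rank_genes(core_network(spec.core), data)

    @staticmethod
    def _coexp_stub(gene_order):
        from bnexpand.coexpression import CoexpressionResult, CoexpressionTable

        return CoexpressionTable(
            [CoexpressionResult(g, 1.0 - 0.01 * i, i + 1, 5)
             for i, g in enumerate(gene_order)]
        )

    def test_identical_rankings_have_empty_side_sets(self):
        bayes = self._bayes_table()
        ov = method_overlap(bayes, self._coexp_stub(bayes.gene_ids()), 0.3)
        assert not ov.coexp_only and not ov.bayes_only
        assert len(ov.both) == len(top := bayes.results[: len(ov.both)])

    def test_reversed_rankings_have_empty_both(self):
        bayes = self._bayes_table()
        ov = method_overlap(bayes, self._coexp_stub(bayes.gene_ids()[::-1]), 0.2)
        assert not ov.both
        assert len(ov.bayes_only) == len(ov.coexp_only)

    def test_mismatched_universe_raises(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(4, 30))
        d = em(vals, ["a", "g1", "g2", "g3"])
        core = CoreNetwork(DAG(("a",)))
        coexp = rank_genes_by_coexpression(core, d)
        d2 = em(vals[:3], ["a", "g1", "g2"])
        disc_states = np.clip(np.round(vals[:3]), 0, 2).astype(np.int8)
        from bnexpand.data_model import DiscretizedMatrix

        disc = DiscretizedMatrix(("a", "g1", "g2"), d2.experiment_ids, disc_states)
        bayes = rank_genes(core, disc)
        with pytest.raises(DataError):
            method_overlap(bayes, coexp, 0.5)
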