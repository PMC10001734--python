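"""Expert weighting, judgment aggregation, consistency, and priority extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ifmcdm.ahp import (
    ExpertProfile,
    JudgmentMatrix,
    WeightVector,
    aggregate_judgments,
    consistency_ratio,
    eigenvector_weights,
    entropy_weights,
    expert_weights,
    global_weights,
    reciprocal_matrix,
    row_ifn,
    weigh_hierarchy,
)
from ifmcdm.ifs import IFN, ifwa
from ifmcdm.synthetic import _relevance_ifn


def consistent_matrix(v, elements=None):
    """Judgment matrix whose defuzzified ratios come from one priority vector."""
    n = len(v)
    elements = elements or [f"E{i+1}" for i in range(n)]
    cells = [[_relevance_ifn(0.5) for _ in range(n)] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j:
                cells[i][j] = _relevance_ifn(min(0.95, v[i] / v[j]))
    return JudgmentMatrix(elements, cells)


class TestExpertWeights:
    def test_reproduces_published_panel(self, expert_panel):
        w = expert_weights(expert_panel)
        assert w[:5] == pytest.approx([0.171429] * 5, abs=1e-6)
        assert w[5] == pytest.approx(0.142857, abs=1e-6)

    def test_identical_experts_share_equally(self):
        panel = [ExpertProfile(f"E{k}", IFN(0.5, 0.4)) for k in range(4)]
        assert expert_weights(panel) == pytest.approx([0.25] * 4)

    def test_matches_hand_evaluated_scores(self):
        # scores: 0.9 + 0.05*0.9/0.95 = 0.947368; 0.5 + 0.1*0.5/0.9 = 0.555556
        panel = [ExpertProfile("a", IFN(0.9, 0.05)), ExpertProfile("b", IFN(0.5, 0.4))]
        s = np.array([0.9 + 0.05 * 0.9 / 0.95, 0.5 + 0.1 * 0.5 / 0.9])
        assert expert_weights(panel) == pytest.approx(s / s.sum(), abs=1e-12)

    def test_rejects_undefined_score(self):
        with pytest.raises(ValueError, match="undefined"):
            expert_weights([ExpertProfile("x", IFN(0.0, 0.0))])

    def test_order_by_score_equals_order_by_weight(self):
        panel = [
            ExpertProfile("a", IFN(0.25, 0.6)),
            ExpertProfile("b", IFN(0.9, 0.05)),
            ExpertProfile("c", IFN(0.5, 0.4)),
        ]
        w = expert_weights(panel)
        assert w[1] > w[2] > w[0]


class TestAggregation:
    def test_single_expert_identity(self, equipment_judgments):
        agg = aggregate_judgments([equipment_judgments], [1.0])
        for i in range(agg.n):
            for j in range(agg.n):
                assert agg.cells[i][j].as_tuple() == pytest.approx(
                    equipment_judgments.cells[i][j].as_tuple()
                )

    def test_identical_experts_idempotent(self, equipment_judgments):
        agg = aggregate_judgments([equipment_judgments] * 3, [0.2, 0.5, 0.3])
        for i in range(agg.n):
            for j in range(agg.n):
                assert agg.cells[i][j].as_tuple() == pytest.approx(
                    equipment_judgments.cells[i][j].as_tuple(), abs=1e-9
                )

    def test_cellwise_equals_per_cell_ifwa(self, rng):
        n, k = 3, 3
        w = rng.dirichlet(np.ones(k))
        mats = []
        for _ in range(k):
            cells = [
                [IFN(*sorted(rng.uniform(0, 0.5, 2))) for _ in range(n)]
                for _ in range(n)
            ]
            mats.append(JudgmentMatrix([f"E{i}" for i in range(n)], cells))
        agg = aggregate_judgments(mats, w)
        for i in range(n):
            for j in range(n):
                expected = ifwa([m.cells[i][j] for m in mats], w)
                assert agg.cells[i][j].as_tuple() == pytest.approx(expected.as_tuple())

    def test_mismatched_elements_rejected(self, equipment_judgments):
        other = JudgmentMatrix(
            ["X", "Y", "Z"], [row[:] for row in equipment_judgments.cells]
        )
        with pytest.raises(ValueError, match="mismatch"):
            aggregate_judgments([equipment_judgments, other], [0.5, 0.5])


class TestConsistencyRatio:
    @pytest.mark.parametrize("n", range(3, 10))
    def test_consistent_matrix_has_zero_cr(self, n, rng):
        # increasing with bounded gaps so every upper-triangle ratio is
        # representable as a membership without clipping
        gaps = rng.uniform(0.06, 0.3, n - 1)
        v = np.exp(np.concatenate([[0.0], np.cumsum(gaps)]))
        rep = consistency_ratio(consistent_matrix(list(v)))
        assert rep.cr == pytest.approx(0.0, abs=1e-8)
        assert rep.consistent

    def test_published_equipment_matrix_is_consistent(self, equipment_judgments):
        rep = consistency_ratio(equipment_judgments)
        assert rep.cr < 0.10
        assert rep.consistent

    def test_matches_power_iteration_oracle(self, rng):
        n = 4
        cells = [
            [IFN(*sorted(rng.uniform(0.05, 0.45, 2))) for _ in range(n)]
            for _ in range(n)
        ]
        mat = JudgmentMatrix([f"E{i}" for i in range(n)], cells)
        A = reciprocal_matrix(mat)
        x = np.ones(n)
        for _ in range(2000):  # independent eigenvalue estimate
            x = A @ x
            x = x / np.linalg.norm(x)
        lam_oracle = float(x @ A @ x)
        rep = consistency_ratio(mat)
        cr_oracle = (lam_oracle - n) / (n - 1) / 0.90
        assert rep.cr == pytest.approx(cr_oracle, abs=1e-8)

    def test_cr_zero_for_two_elements(self):
        mat = JudgmentMatrix(["a", "b"], [[IFN(0.4, 0.4)] * 2] * 2)
        assert consistency_ratio(mat).cr == 0.0

    def test_inconsistent_matrix_warns(self):
        # strongly cyclic preferences: a > b, b > c, c > a
        hi, lo, eq = IFN(0.85, 0.1), IFN(0.05, 0.9), IFN(0.45, 0.45)
        cells = [[eq, hi, lo], [lo, eq, hi], [hi, lo, eq]]
        with pytest.warns(UserWarning, match="inconsistent"):
            rep = consistency_ratio(JudgmentMatrix(["a", "b", "c"], cells))
        assert not rep.consistent


class TestRowIFN:
    def test_reproduces_published_row_means(self, equipment_judgments):
        rows = row_ifn(equipment_judgments)
        got = [(round(r.mu, 3), round(r.nu, 3)) for r in rows]
        assert got == [(0.083, 0.195), (0.084, 0.186), (0.103, 0.177)]

    def test_constant_row_is_identity(self):
        x = IFN(0.3, 0.5)
        mat = JudgmentMatrix(["a", "b"], [[x, x], [x, x]])
        assert row_ifn(mat)[0].as_tuple() == pytest.approx(x.as_tuple())


class TestEntropyWeights:
    def test_identical_rows_give_equal_weights(self):
        wv = entropy_weights([IFN(0.3, 0.5)] * 4)
        assert wv.local_array() == pytest.approx([0.25] * 4)

    def test_matches_scalar_oracle(self):
        # hand evaluation of the entropy formula for two elements
        def ent(mu, nu):
            pi = 1 - mu - nu
            t = 0.0
            for x in (mu, nu):
                t += x * math.log(x) if x > 0 else 0.0
            t -= (1 - pi) * math.log(1 - pi) if pi < 1 else 0.0
            t -= pi * math.log(2)
            return -t / math.log(2)

        e1, e2 = ent(0.4, 0.4), ent(0.1, 0.8)
        w1 = (1 - e1) / (2 - (e1 + e2))
        w2 = (1 - e2) / (2 - (e1 + e2))
        wv = entropy_weights([IFN(0.4, 0.4), IFN(0.1, 0.8)])
        assert wv.local_array() == pytest.approx(
            np.array([w1, w2]) / (w1 + w2), abs=1e-12
        )

    def test_permutation_equivariant(self, equipment_judgments):
        rows = row_ifn(equipment_judgments)
        wv = entropy_weights(rows, equipment_judgments.elements)
        perm = [2, 0, 1]
        wv_p = entropy_weights(
            [rows[i] for i in perm], [equipment_judgments.elements[i] for i in perm]
        )
        for e in equipment_judgments.elements:
            assert wv_p.local[e] == pytest.approx(wv.local[e], abs=1e-12)


class TestGlobalWeights:
    def test_reproduces_published_overall_weights(self):
        from ifmcdm import load_fixture

        ref = load_fixture("reference_weights")
        crits = ref[ref.parent.isna()]
        parent = WeightVector(
            list(crits.element),
            dict(zip(crits.element, crits.local / crits.local.sum())),
        )
        children = {}
        for crit in crits.element:
            sub = ref[ref.parent == crit]
            children[crit] = WeightVector(
                list(sub.element),
                dict(zip(sub.element, sub.local / sub.local.sum())),
            )
        gw = global_weights(parent, children)
        # spot checks against the printed overall weights (3 d.p.)
        assert gw.global_["SH8"] == pytest.approx(0.358 * 0.119, abs=2e-3)
        assert round(gw.global_["SH8"], 3) == pytest.approx(0.043, abs=1e-3)
        assert round(gw.global_["SH6"], 3) == pytest.approx(0.038, abs=1e-3)
        assert sum(gw.global_.values()) == pytest.approx(1.0, abs=1e-6)

    def test_single_criterion_passthrough(self):
        parent = WeightVector(["C"], {"C": 1.0})
        child = WeightVector(["a", "b"], {"a": 0.7, "b": 0.3})
        gw = global_weights(parent, {"C": child})
        assert gw.global_ == pytest.approx({"a": 0.7, "b": 0.3})

    def test_orphan_cluster_rejected(self):
        parent = WeightVector(["C"], {"C": 1.0})
        child = WeightVector(["a", "b"], {"a": 0.7, "b": 0.3})
        with pytest.raises(ValueError, match="orphan"):
            global_weights(parent, {"D": child})


class TestEigenvectorWeights:
    def test_recovers_priority_from_consistent_matrix(self):
        v = [0.3, 0.5, 0.8, 1.0]
        wv = eigenvector_weights(consistent_matrix(v))
        assert wv.local_array() == pytest.approx(np.array(v) / sum(v), abs=1e-9)
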