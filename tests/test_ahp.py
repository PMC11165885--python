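"""AHP machinery: matrix expansion, weight extraction, consistency.

numpy.linalg.eig serves as the independent eigensolver oracle; the
implementation itself uses power iteration.
"""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epiprior as ep
from epiprior.ahp import (RANDOM_INDEX, SCALE, JudgmentMatrix, JudgmentSet,
                          consistency)


def jset(pairs, group="G1", stream="risk"):
    return JudgmentSet(group, stream,
                       {k: Fraction(v) for k, v in pairs.items()})


class TestParseJudgment:
    @pytest.mark.parametrize("text,value", [
        ("1", 1), ("9", 9), ("1/2", Fraction(1, 2)), ("1/9", Fraction(1, 9)),
    ])
    def test_admissible_values(self, text, value):
        assert ep.parse_judgment(text) == value

    @pytest.mark.parametrize("text", ["10", "0", "9.5", "2/3", "1/10", "-3"])
    def test_out_of_scale_rejected(self, text):
        with pytest.raises(ValueError):
            ep.parse_judgment(text)


class TestExpandMatrix:
    def test_all_equal_judgments_give_unit_matrix(self):
        m = ep.expand_matrix(
            jset({("a", "b"): 1, ("a", "c"): 1, ("b", "c"): 1}),
            ["a", "b", "c"])
        assert m.n_cells == 9
        assert np.allclose(m.to_array(), np.ones((3, 3)))

    def test_reciprocal_fill_is_exact(self):
        m = ep.expand_matrix(
            jset({("a", "b"): 2, ("a", "c"): 4, ("b", "c"): 2}),
            ["a", "b", "c"])
        for i in range(3):
            for j in range(3):
                assert m.entries[i][j] * m.entries[j][i] == 1
        assert m.entries[1][0] == Fraction(1, 2)
        assert m.entries[2][0] == Fraction(1, 4)

    def test_missing_pair_names_pair(self):
        with pytest.raises(ValueError, match="missing judgment"):
            ep.expand_matrix(
                jset({("a", "b"): 2, ("a", "c"): 4}), ["a", "b", "c"])

    def test_disease_stream_needs_six_judgments(self):
        order = ["severity", "prevalence", "transmissibility", "strategy"]
        pairs = {(order[i], order[j]): 1
                 for i in range(4) for j in range(i + 1, 4)}
        assert ep.expand_matrix(jset(pairs, stream="disease"), order).n_cells == 16
        pairs.popitem()
        with pytest.raises(ValueError, match="missing"):
            ep.expand_matrix(jset(pairs, stream="disease"), order)


class TestComputeWeights:
    @pytest.mark.parametrize("n", [3, 4])
    def test_all_ones_matrix_gives_uniform_weights(self, n):
        m = JudgmentMatrix([f"c{i}" for i in range(n)],
                           [[Fraction(1)] * n for _ in range(n)])
        wv = ep.compute_weights(m)
        assert np.allclose(wv.weights, 1 / n, atol=1e-12)
        assert wv.lambda_max == pytest.approx(n, abs=1e-9)
        assert wv.consistency_ratio == pytest.approx(0, abs=1e-9)

    @pytest.mark.parametrize("method", ["eigenvector", "geometric-mean"])
    def test_consistent_matrix_recovers_ratio_weights(self, consistent_3x3,
                                                      method):
        wv = ep.compute_weights(consistent_3x3, method)
        assert np.allclose(wv.weights, [4 / 7, 2 / 7, 1 / 7], atol=1e-9)
        assert wv.lambda_max == pytest.approx(3, abs=1e-9)
        assert not wv.inconsistent

    def test_cyclic_matrix_lambda_and_cr(self, cyclic_3x3):
        wv = ep.compute_weights(cyclic_3x3)
        assert wv.lambda_max == pytest.approx(13 / 3, abs=1e-9)
        assert wv.consistency_index == pytest.approx(2 / 3, abs=1e-9)
        assert wv.consistency_ratio == pytest.approx((2 / 3) / 0.58, abs=1e-6)
        assert wv.inconsistent

    def test_eigenvector_matches_numpy_eig_oracle(self, cyclic_3x3):
        a = cyclic_3x3.to_array()
        vals, vecs = np.linalg.eig(a)
        k = np.argmax(vals.real)
        oracle = np.abs(vecs[:, k].real)
        oracle /= oracle.sum()
        wv = ep.compute_weights(cyclic_3x3)
        assert np.allclose(wv.weights, oracle, atol=1e-9)
        assert wv.lambda_max == pytest.approx(vals[k].real, abs=1e-9)

    def test_weights_positive_and_sum_one(self, cyclic_3x3):
        wv = ep.compute_weights(cyclic_3x3)
        assert (wv.weights > 0).all()
        assert wv.weights.sum() == pytest.approx(1, abs=1e-9)

    def test_unknown_method_rejected(self, consistent_3x3):
        with pytest.raises(ValueError):
            ep.compute_weights(consistent_3x3, "median")

    def test_non_reciprocal_matrix_rejected(self):
        bad = JudgmentMatrix(["a", "b"],
                             [[Fraction(1), Fraction(2)],
                              [Fraction(1), Fraction(1)]])
        with pytest.raises(ValueError, match="reciprocity"):
            ep.compute_weights(bad)


def test_consistency_trivial_below_n3():
    m = JudgmentMatrix(["a", "b"], [[Fraction(1), Fraction(3)],
                                    [Fraction(1, 3), Fraction(1)]])
    lam, ci, cr, flag, notes = consistency(m, ep.compute_weights(m).weights)
    assert cr == 0 and not flag and notes


def _consistent_matrix_from(wraw):
    w = np.asarray(wraw) / sum(wraw)
    n = len(w)
    entries = [[Fraction(1)] * n for _ in range(n)]
    arr = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            arr[i][j] = w[i] / w[j]
    return arr, w


@settings(derandomize=True, max_examples=60)
@given(wraw=st.lists(st.floats(0.05, 1.0), min_size=3, max_size=5))
def test_eigen_and_geometric_mean_agree_on_consistent_matrices(wraw):
    """Both extraction methods recover w from a_ij = w_i/w_j."""
    arr, w = _consistent_matrix_from(wraw)
    n = len(w)
    m = JudgmentMatrix([f"c{i}" for i in range(n)],
                       [[Fraction(arr[i][j]).limit_denominator(10**9)
                         if i != j else Fraction(1) for j in range(n)]
                        for i in range(n)])
    # rebuild exact reciprocity from the upper triangle
    for i in range(n):
        for j in range(i + 1, n):
            m.entries[j][i] = 1 / m.entries[i][j]
    we = ep.compute_weights(m, "eigenvector").weights
    wg = ep.compute_weights(m, "geometric-mean").weights
    assert np.allclose(we, wg, atol=1e-6)
    assert np.allclose(we, w, atol=1e-6)


@settings(derandomize=True, max_examples=60)
@given(data=st.data())
def test_permutation_equivariance_and_lambda_bound(data):
    """Permuting criteria permutes weights; λmax >= n always."""
    n = data.draw(st.integers(3, 4))
    pairs = {}
    labels = [f"c{i}" for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            pairs[(labels[i], labels[j])] = data.draw(st.sampled_from(SCALE))
    m = ep.expand_matrix(JudgmentSet("g", "risk", dict(pairs)), labels)
    wv = ep.compute_weights(m)
    assert wv.lambda_max >= n - 1e-9
    perm = data.draw(st.permutations(list(range(n))))
    pm = JudgmentMatrix([labels[p] for p in perm],
                        [[m.entries[pi][pj] for pj in perm] for pi in perm])
    wp = ep.compute_weights(pm)
    assert np.allclose(wp.weights, wv.weights[list(perm)], atol=1e-9)
    assert wp.lambda_max == pytest.approx(wv.lambda_max, abs=1e-9)


def test_random_index_table_has_standard_values():
    assert RANDOM_INDEX[3] == 0.58 and RANDOM_INDEX[4] == 0.90
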