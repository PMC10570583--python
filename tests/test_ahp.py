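import numpy as np
import pytest

from smcrisk import (
    PairwiseComparisonMatrix,
    SyntheticSpec,
    WeightVector,
    column_normalize,
    consistency,
    generate_pcm,
    lambda_max,
    rank,
    synthesize,
    weights,
)
from smcrisk.ahp import CriterionNode, Hierarchy, RANDOM_INDEX
from smcrisk.errors import (
    IncompleteHierarchyError,
    InvalidInputError,
    MissingRandomIndexError,
)
from conftest import PRINTED_SUB_PCMS


def _pcm(labels, entries):
    return PairwiseComparisonMatrix(list(labels), np.asarray(entries, float))


def _consistent(w):
    w = np.asarray(w, float)
    return _pcm([f"f{i}" for i in range(w.size)], np.outer(w, 1.0 / w))


def test_column_normalize_makes_columns_stochastic(us2019_config):
    norm = column_normalize(us2019_config.criteria_pcm)
    np.testing.assert_allclose(norm.sum(axis=0), 1.0)
    np.testing.assert_allclose(norm[:, 0], [0.1, 0.4, 0.5])
    labels, env = PRINTED_SUB_PCMS["environment"]
    np.testing.assert_allclose(
        np.round(column_normalize(_pcm(labels, env))[:, 0], 3),
        [0.083, 0.25, 0.417, 0.25],
    )
    ones = _pcm("abc", np.ones((3, 3)))
    np.testing.assert_allclose(column_normalize(ones), 1 / 3)


def test_two_by_two_weights_are_closed_form():
    wv = weights(_pcm(["R5", "R6"], [[1, 9], [1 / 9, 1]]))
    np.testing.assert_allclose(wv.weights, [0.9, 0.1], atol=1e-12)


def test_driver_behavior_weights_match_eigenvector_not_rowmean():
    labels, db = PRINTED_SUB_PCMS["driver_behavior"]
    pcm = _pcm(labels, db)
    eig = weights(pcm, method="eigen")
    np.testing.assert_allclose(np.round(eig.weights, 3), [0.493, 0.196, 0.311])
    rm = weights(pcm, method="rowmean")
    # methods agree within 0.005 per component on this CR < 0.10 matrix
    assert np.max(np.abs(eig.weights - rm.weights)) < 0.005


def test_weights_recover_generating_vector_on_consistent_pcm():
    w = np.array([0.5, 0.25, 0.15, 0.1])
    got = weights(_consistent(w))
    np.testing.assert_allclose(got.weights, w, atol=1e-12)


def test_weights_rejects_invalid_pcm_and_unknown_method():
    bad = _pcm(["a", "b"], [[1, 2], [3, 1]])
    with pytest.raises(InvalidInputError):
        weights(bad)
    with pytest.raises(InvalidInputError):
        weights(_consistent([0.6, 0.4]), method="magic")


def test_lambda_max_estimator_properties(us2019_config):
    # consistent matrix: estimator equals the order exactly
    pcm = _consistent([0.2, 0.3, 0.5])
    assert lambda_max(pcm, weights(pcm)) == pytest.approx(3.0, abs=1e-9)
    # case-study criteria matrix: principal eigenvalue ≈ 3.0055
    crit = us2019_config.criteria_pcm
    lam = lambda_max(crit, weights(crit))
    assert round(lam, 4) == 3.0055
    class DegenerateWeights:
        labels = list("abc")
        weights = np.array([0.5, 0.5, 0.0])

    with pytest.raises(InvalidInputError):
        lambda_max(pcm, DegenerateWeights())


def test_consistency_report_values_and_rules():
    rep = consistency(3.0055, 3)
    assert rep.ci == pytest.approx(0.00275)
    assert round(rep.cr, 6) == 0.004741
    assert rep.passed
    rep2 = consistency(4.0, 4)
    assert rep2.ci == 0 and rep2.cr == 0
    # order 2 has no independent judgment: CR defined as 0
    rep3 = consistency(2.0, 2)
    assert rep3.cr == 0 and rep3.passed
    with pytest.raises(MissingRandomIndexError):
        consistency(9.5, 9)
    assert consistency(9.5, 9, allow_extended=True).ri == 1.45
    with pytest.raises(InvalidInputError):
        consistency(1.0, 1)


def test_random_index_table_is_nondecreasing():
    vals = [RANDOM_INDEX[n] for n in sorted(RANDOM_INDEX)]
    assert vals == sorted(vals)
    assert RANDOM_INDEX[1] == RANDOM_INDEX[2] == 0


def test_lambda_max_at_least_n_on_perturbed_matrices():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(3, 7))
        spec = SyntheticSpec(n_factors=n, noise_sigma=0.3, seed=int(rng.integers(2**31)))
        _, pcm = generate_pcm(spec)
        lam = lambda_max(pcm, weights(pcm))
        assert lam >= n - 1e-9


def test_synthesize_multiplies_down_the_tree():
    h = Hierarchy(
        goal="g",
        criteria=[
            CriterionNode("c1", 0.433, ["R5", "R6"], np.array([0.9, 0.1])),
            CriterionNode("c2", 0.567, ["R7"], np.array([1.0])),
        ],
    )
    gw = synthesize(h)
    assert gw["R5"] == pytest.approx(0.433 * 0.9)
    assert gw.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_synthesize_rejects_incomplete_hierarchies():
    with pytest.raises(IncompleteHierarchyError):
        synthesize(Hierarchy("g", [CriterionNode("c", None, ["x"], np.array([1.0]))]))
    with pytest.raises(IncompleteHierarchyError):
        synthesize(Hierarchy("g", [CriterionNode("c", 1.0, [], None)]))
    with pytest.raises(IncompleteHierarchyError):
        synthesize(
            Hierarchy("g", [CriterionNode("c", 1.0, ["x", "y"], np.array([0.6, 0.6]))])
        )


def test_competition_ranking_with_ties():
    wv = WeightVector(list("abcd"), np.array([0.4, 0.25, 0.25, 0.1]))
    rk = rank(wv)
    assert [r.rank for r in rk.records] == [1, 2, 2, 4]
    assert [r.tied for r in rk.records] == [False, True, True, False]
    assert rk.records[0].percent == 40

    flat = rank(WeightVector(list("abc"), np.array([1 / 3, 1 / 3, 1 / 3])))
    assert all(r.rank == 1 and r.tied for r in flat.records)

    plain = rank(WeightVector(list("abc"), np.array([0.5, 0.3, 0.2])))
    assert [r.rank for r in plain.records] == [1, 2, 3]
    assert not any(r.tied for r in plain.records)


def test_rank_invariant_under_leaf_permutation():
    w = np.array([0.35, 0.3, 0.2, 0.15])
    labels = list("abcd")
    base = {r.label: r.rank for r in rank(WeightVector(labels, w)).records}
    perm = [2, 0, 3, 1]
    shuffled = rank(
        WeightVector([labels[i] for i in perm], w[perm])
    )
    assert {r.label: r.rank for r in shuffled.records} == base
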