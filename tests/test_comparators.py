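import numpy as np
import pytest

from smcrisk import (
    BwmInput,
    FucomInput,
    bwm_weights,
    compare_methods,
    derive_comparator_inputs,
    fucom_weights,
    weights as ahp_weights,
)
from smcrisk.comparators import bwm_from_pcm, fucom_from_pcm
from smcrisk.errors import InvalidInputError
from smcrisk.pcm import PairwiseComparisonMatrix
from oracles import bwm_deviation, fucom_deviation, grid_minimax


def test_derive_inputs_from_driver_state_scores():
    bwm, fucom = derive_comparator_inputs({"R5": 18.2, "R6": 2.0})
    assert bwm.labels[bwm.best_index] == "R5"
    assert bwm.labels[bwm.worst_index] == "R6"
    assert bwm.best_to_others[bwm.worst_index] == 9  # quantized 9.1
    assert fucom.labels == ["R5", "R6"]


def test_derive_inputs_orders_fucom_by_score():
    _, fucom = derive_comparator_inputs({"R7": 17.9, "R8": 8.8, "R9": 12.0})
    assert fucom.labels == ["R7", "R9", "R8"]


def test_derive_inputs_equal_scores_warns_and_is_trivial():
    with pytest.warns(UserWarning, match="tied"):
        bwm, fucom = derive_comparator_inputs({"a": 5.0, "b": 5.0, "c": 5.0})
    assert np.all(bwm.best_to_others == 1)
    assert np.all(fucom.comparative_priorities == 1)
    wv, xi = bwm_weights(bwm)
    assert xi == pytest.approx(0.0, abs=1e-8)
    np.testing.assert_allclose(wv.weights, 1 / 3, atol=1e-6)


def test_bwm_recovers_consistent_weights():
    truth = np.array([0.6, 0.3, 0.1])
    inp = BwmInput(
        labels=list("abc"), best_index=0, worst_index=2,
        best_to_others=truth[0] / truth, others_to_worst=truth / truth[2],
    )
    wv, xi = bwm_weights(inp)
    np.testing.assert_allclose(wv.weights, truth, atol=1e-6)
    assert xi == pytest.approx(0.0, abs=1e-7)


def test_bwm_two_factor_single_ratio():
    inp = BwmInput(["a", "b"], 0, 1, np.array([1.0, 9.0]), np.array([9.0, 1.0]))
    wv, xi = bwm_weights(inp)
    np.testing.assert_allclose(wv.weights, [0.9, 0.1], atol=1e-6)


@pytest.mark.parametrize(
    "bto,otw",
    [
        ([1, 2, 4], [4, 2, 1]),
        ([1, 3, 5], [5, 2, 1]),
    ],
)
def test_bwm_matches_simplex_grid_oracle_n3(bto, otw):
    bto, otw = np.array(bto, float), np.array(otw, float)
    inp = BwmInput(list("abc"), 0, 2, bto, otw)
    wv, xi = bwm_weights(inp)
    w_star, xi_star = grid_minimax(
        lambda W: bwm_deviation(W, 0, 2, bto, otw), 3, coarse=0.01
    )
    assert np.max(np.abs(wv.weights - w_star)) < 2e-3
    assert xi <= xi_star + 1e-6


def test_bwm_matches_grid_oracle_n4_consistent_chain():
    # a_Bj * a_jW = a_BW = 8 for every j, so the optimum is unique (xi* = 0)
    # and the grid argmin must land on the exact ratio solution
    bto = np.array([1.0, 2.0, 4.0, 8.0])
    otw = np.array([8.0, 4.0, 2.0, 1.0])
    inp = BwmInput(list("abcd"), 0, 3, bto, otw)
    wv, xi = bwm_weights(inp)
    w_star, xi_star = grid_minimax(
        lambda W: bwm_deviation(W, 0, 3, bto, otw), 4, coarse=0.02
    )
    assert np.max(np.abs(wv.weights - w_star)) < 2e-3
    assert xi <= xi_star + 1e-6
    assert xi == pytest.approx(0.0, abs=1e-7)


def test_bwm_objective_matches_grid_oracle_n4_inconsistent():
    # order-4 inconsistent input: optimal weights need not be unique in the
    # nonlinear BWM, so compare the optimal deviation, not the argmin
    bto = np.array([1.0, 3.0, 5.0, 9.0])
    otw = np.array([9.0, 5.0, 2.0, 1.0])
    inp = BwmInput(list("abcd"), 0, 3, bto, otw)
    wv, xi = bwm_weights(inp)
    _, xi_star = grid_minimax(
        lambda W: bwm_deviation(W, 0, 3, bto, otw), 4, coarse=0.02
    )
    assert xi <= xi_star + 1e-6
    assert abs(xi - xi_star) < 1e-3


def test_bwm_input_validation():
    with pytest.raises(InvalidInputError):
        BwmInput(list("ab"), 0, 1, np.array([2.0, 9.0]), np.array([9.0, 1.0]))
    with pytest.raises(InvalidInputError):
        BwmInput(list("ab"), 0, 1, np.array([1.0, 0.5]), np.array([9.0, 1.0]))


def test_fucom_exact_chain_and_uniform():
    wv, chi = fucom_weights(FucomInput(list("abc"), np.array([2.0, 2.0])))
    np.testing.assert_allclose(wv.weights, [4 / 7, 2 / 7, 1 / 7], atol=1e-6)
    assert chi == pytest.approx(0.0, abs=1e-8)

    wv, chi = fucom_weights(FucomInput(list("abcd"), np.ones(3)))
    np.testing.assert_allclose(wv.weights, 0.25, atol=1e-6)


def test_fucom_matches_simplex_grid_oracle():
    phi = np.array([1.5, 2.5])
    wv, chi = fucom_weights(FucomInput(list("abc"), phi))
    w_star, chi_star = grid_minimax(
        lambda W: fucom_deviation(W, phi), 3, coarse=0.01
    )
    assert np.max(np.abs(wv.weights - w_star)) < 2e-3
    assert chi <= chi_star + 1e-6


def test_fucom_requires_chain_shape():
    with pytest.raises(InvalidInputError):
        FucomInput(list("abc"), np.array([2.0]))
    with pytest.raises(InvalidInputError):
        FucomInput(list("abc"), np.array([0.5, 2.0]))


def test_three_methods_agree_on_noise_free_inputs():
    truth = np.array([0.55, 0.25, 0.12, 0.08])
    labels = list("abcd")
    pcm = PairwiseComparisonMatrix(labels, np.outer(truth, 1.0 / truth))
    ahp_w = ahp_weights(pcm).weights
    bwm_w = bwm_weights(
        BwmInput(labels, 0, 3, truth[0] / truth, truth / truth[3])
    )[0].weights
    fucom_w = fucom_weights(
        FucomInput(labels, truth[:-1] / truth[1:])
    )[0].weights
    np.testing.assert_allclose(ahp_w, truth, atol=1e-9)
    np.testing.assert_allclose(bwm_w, truth, atol=1e-6)
    np.testing.assert_allclose(fucom_w, truth, atol=1e-6)


def test_solver_outputs_are_positive_and_normalized():
    for inp in [
        BwmInput(list("abc"), 0, 2, np.array([1.0, 5.0, 9.0]), np.array([9.0, 3.0, 1.0])),
    ]:
        wv, xi = bwm_weights(inp)
        assert np.all(wv.weights > 0)
        assert wv.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert xi >= 0
    wv, chi = fucom_weights(FucomInput(list("abc"), np.array([3.0, 2.0])))
    assert np.all(wv.weights > 0) and chi >= 0


def test_comparator_inputs_from_expert_pcm(us2019_config):
    crit = us2019_config.criteria_pcm
    bwm = bwm_from_pcm(crit)
    assert bwm.labels[bwm.best_index] == "C3"
    assert bwm.labels[bwm.worst_index] == "C1"
    fucom = fucom_from_pcm(crit)
    assert fucom.labels[0] == "C3" and fucom.labels[-1] == "C1"


def test_compare_methods_unanimous_extremes_on_case_study(us2019_config, us2019_evidence):
    scores = {g: dict(t.importance_score) for g, t in us2019_evidence.items()}
    groups = {c.name: c.evidence_group for c in us2019_config.criteria}
    res = compare_methods(us2019_config.criteria_pcm, scores, groups)
    for method in ("ahp", "bwm", "fucom"):
        assert res.ranks_by_method[method]["R5"] == 1
        assert res.ranks_by_method[method]["R1"] == 9
    assert res.max_divergence < 0.1


def test_compare_methods_top_rank_stable_under_small_noise():
    rng = np.random.default_rng(11)
    truth = {"a": 40.0, "b": 20.0, "c": 10.0}
    for _ in range(5):
        noisy = {k: v * float(np.exp(rng.normal(0, 0.1))) for k, v in truth.items()}
        bwm_in, fucom_in = derive_comparator_inputs(noisy)
        top_bwm = max(bwm_weights(bwm_in)[0].as_dict().items(), key=lambda kv: kv[1])[0]
        top_fucom = max(fucom_weights(fucom_in)[0].as_dict().items(), key=lambda kv: kv[1])[0]
        assert top_bwm == "a" == top_fucom
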