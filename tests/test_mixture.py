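"""Mixture fitting, BIC selection, the ternary call and concordance."""

import numpy as np
import pytest

from telcontent import (ClassifierConfig, MixtureFit, TelomereCall, bic,
                        classification_boundaries, classify, concordance,
                        fit_mixture, select_model, simulate_cohort_deltas)
from telcontent.mixture import GAIN, LOSS, NO_CHANGE, n_free_parameters
from telcontent.simulate import CohortSimParams


def _example_fit(mu=(-0.6, 0.4), sigma=0.5, weights=(0.5, 0.5)):
    return MixtureFit(n_components=2, means=np.array(mu),
                      variances=np.array([sigma ** 2] * 2),
                      weights=np.array(weights), variance_model="equal",
                      log_likelihood=0.0, n_samples=100, converged=True,
                      seed=0)


def test_single_component_closed_form():
    rng = np.random.default_rng(3)
    x = rng.normal(0.0, 0.3, 500)
    fit = fit_mixture(x, G=1)
    assert fit.means[0] == pytest.approx(np.mean(x), abs=1e-12)
    assert fit.variances[0] == pytest.approx(np.mean((x - x.mean()) ** 2),
                                             abs=1e-12)
    assert abs(fit.means[0]) < 0.05
    assert fit.variances[0] == pytest.approx(0.09, rel=0.25)


def test_two_component_recovery():
    rng = np.random.default_rng(3)
    n_low = 210  # 70% of 300
    x = np.concatenate([rng.normal(-0.5, 0.3, n_low),
                        rng.normal(1.0, 0.3, 300 - n_low)])
    fit = fit_mixture(x, G=2, variance_model="equal", seed=3)
    assert fit.means[0] == pytest.approx(-0.5, abs=0.1)
    assert fit.means[1] == pytest.approx(1.0, abs=0.1)
    assert fit.weights[0] == pytest.approx(0.7, abs=0.07)
    assert fit.converged
    assert np.all(np.diff(fit.means) > 0)


def test_fit_agrees_with_sklearn():
    sklearn = pytest.importorskip("sklearn.mixture")
    x, _ = simulate_cohort_deltas(CohortSimParams(n_samples=300, seed=12))
    mine = fit_mixture(x, G=2, variance_model="unequal", seed=1)
    ref = sklearn.GaussianMixture(n_components=2, covariance_type="diag",
                                  n_init=5, tol=1e-8, max_iter=1000,
                                  random_state=0).fit(x.reshape(-1, 1))
    order = np.argsort(ref.means_.ravel())
    assert mine.means == pytest.approx(ref.means_.ravel()[order], abs=0.02)
    assert mine.log_likelihood == pytest.approx(ref.score(x.reshape(-1, 1))
                                                * len(x), abs=0.5)


def test_degenerate_and_invalid_inputs():
    with pytest.raises(ValueError):
        fit_mixture(np.ones(50), G=2)
    with pytest.raises(ValueError):
        fit_mixture(np.array([0.1, 0.2, np.nan]), G=1)
    with pytest.raises(ValueError):
        fit_mixture(np.array([0.1, 0.2, 0.3]), G=2)
    with pytest.raises(ValueError):
        fit_mixture(np.arange(10.0), G=2, variance_model="spherical")


def test_em_loglik_nondecreasing():
    x, _ = simulate_cohort_deltas(CohortSimParams(n_samples=235, seed=7))
    for vm in ("equal", "unequal"):
        fit = fit_mixture(x, G=2, variance_model=vm, seed=7)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-7)


@pytest.mark.parametrize("G,vm,p", [
    (1, "equal", 2),
    (2, "equal", 4),
    (2, "unequal", 5),
    (3, "equal", 6),
    (3, "unequal", 8),
])
def test_bic_parameter_counts(G, vm, p):
    assert n_free_parameters(G, vm) == p
    fit = MixtureFit(n_components=G, means=np.arange(G, dtype=float),
                     variances=np.ones(G), weights=np.full(G, 1 / G),
                     variance_model=vm, log_likelihood=-123.4, n_samples=50,
                     converged=True, seed=0)
    assert bic(fit) == pytest.approx(2 * -123.4 - p * np.log(50))


def test_select_model_tiny_unimodal_input():
    fit = select_model(np.array([0.1, 0.2, 0.4]), G_range=[1])
    assert fit.n_components == 1
    assert fit.means[0] == pytest.approx(0.7 / 3)


def test_select_model_bimodal_cohort():
    x, _ = simulate_cohort_deltas(CohortSimParams(n_samples=235, seed=3))
    fit = select_model(x, seed=3)
    assert fit.n_components == 2
    assert fit.variance_model == "equal"
    assert fit.means[0] == pytest.approx(-0.5, abs=0.1)
    assert fit.means[1] == pytest.approx(1.0, abs=0.1)


def test_classification_boundaries_worked_example():
    gain_b, loss_b = classification_boundaries(_example_fit())
    assert gain_b == pytest.approx(-0.6 + 2.3263 * 0.5, abs=2e-4)
    assert loss_b == pytest.approx(0.4 - 2.3263 * 0.5, abs=2e-4)


@pytest.mark.parametrize("value,expected", [
    (0.0, NO_CHANGE),
    (0.8, GAIN),
    (-1.0, LOSS),
])
def test_classify_worked_examples(value, expected):
    [call] = classify([value], _example_fit())
    assert call.call == expected
    assert call.gain_boundary == pytest.approx(0.5632, abs=1e-4)
    assert call.loss_boundary == pytest.approx(-0.7632, abs=1e-4)


def test_classify_tail_probabilities():
    calls = classify([0.8], _example_fit())
    # one-sided tails under each component at alpha = 0.01
    assert calls[0].p_vs_lower_component < 0.01
    assert calls[0].p_vs_upper_component > 0.01


def test_classify_requires_two_components():
    fit1 = MixtureFit(1, np.array([0.0]), np.array([1.0]), np.array([1.0]),
                      "equal", 0.0, 10, True, 0)
    with pytest.raises(ValueError):
        classify([0.0], fit1)


def test_classify_monotone_in_delta_t():
    order = {LOSS: 0, NO_CHANGE: 1, GAIN: 2}
    grid = np.linspace(-3, 3, 601)
    for fit in (_example_fit(), _example_fit(mu=(-0.5, 1.0), sigma=0.3)):
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                codes = [order[c.call] for c in classify(grid, fit)]
        assert codes == sorted(codes)


def test_classify_crossed_boundaries_assigns_all():
    # 5-sigma separation inverts the boundaries; max posterior takes over
    fit = _example_fit(mu=(-0.5, 1.0), sigma=0.1)
    with pytest.warns(UserWarning):
        calls = classify(np.linspace(-1, 1.5, 101), fit)
    assert len(calls) == 101
    assert {c.call for c in calls} <= {GAIN, LOSS, NO_CHANGE}


def test_classify_permutation_invariance():
    x, _ = simulate_cohort_deltas(CohortSimParams(n_samples=50, seed=5))
    fit = _example_fit()
    base = [c.call for c in classify(x, fit)]
    perm = np.random.default_rng(0).permutation(50)
    permuted = [c.call for c in classify(x[perm], fit)]
    assert [base[i] for i in perm] == permuted


def test_classify_recovers_generator_labels():
    params = CohortSimParams(n_samples=400, means=(-0.5, 1.0), sigma=0.3,
                             weight_low=0.7, seed=21)
    x, labels = simulate_cohort_deltas(params)
    fit = fit_mixture(x, G=2, seed=21)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        calls = classify(x, fit)
    gain_b, loss_b = calls[0].gain_boundary, calls[0].loss_boundary
    sigma = 0.3
    clear = [(c, lab) for c, lab, v in zip(calls, labels, x)
             if abs(v - gain_b) >= sigma and abs(v - loss_b) >= sigma]
    intended = {0: LOSS, 1: GAIN}
    hits = sum(1 for c, lab in clear if c.call == intended[lab])
    assert hits / len(clear) >= 0.95


def test_alpha_validation():
    with pytest.raises(ValueError):
        ClassifierConfig(alpha=0.7)
    assert ClassifierConfig().alpha == 0.01


def _call(pid, call):
    return TelomereCall(pair_id=pid, delta_t=0.0, call=call,
                        p_vs_lower_component=0.5, p_vs_upper_component=0.5,
                        gain_boundary=1.0, loss_boundary=-1.0)


def test_concordance_fish_mapping():
    calls = [_call("a", GAIN), _call("b", LOSS), _call("c", NO_CHANGE)]
    external = {"a": "abnormal", "b": "normal", "c": "normal"}
    assert concordance(calls, external, mode="fish") == pytest.approx(100.0)


def test_concordance_qpcr_sign_match():
    calls = [_call("a", GAIN), _call("b", GAIN)]
    assert concordance(calls, {"a": 0.4, "b": -0.2},
                       mode="qpcr") == pytest.approx(50.0)


def test_concordance_excludes_no_change_for_qpcr():
    calls = [_call("a", GAIN), _call("b", NO_CHANGE)]
    assert concordance(calls, {"a": 0.4, "b": -0.2},
                       mode="qpcr") == pytest.approx(100.0)


def test_concordance_counting_oracle():
    rng = np.random.default_rng(17)
    statuses = [GAIN, LOSS, NO_CHANGE]
    calls = [_call(f"s{i}", statuses[rng.integers(3)]) for i in range(9)]
    external = {}
    for i, c in enumerate(calls):
        truth = "abnormal" if c.call == GAIN else "normal"
        external[c.pair_id] = truth
    # flip one label to create a single disagreement: 8 of 9 match
    external["s0"] = "abnormal" if external["s0"] == "normal" else "normal"
    assert concordance(calls, external, mode="fish") == pytest.approx(100 * 8 / 9)


def test_concordance_requires_overlap():
    with pytest.raises(ValueError):
        concordance([_call("a", GAIN)], {"zzz": "normal"}, mode="fish")
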