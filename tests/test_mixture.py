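"""Unit tests for the ordinal mixture model: response model, likelihood
(against a brute-force oracle), EM, posteriors, BIC and serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdqprofiles.mixture import (
    FitConfig,
    MixtureParams,
    bic,
    em_fit,
    entropy_r2,
    loglikelihood,
    posterior,
    select_model,
)
from sdqprofiles.records import MISSING, ModelSpec, to_score_array, from_score_array


def make_params(spec, pi, beta, alpha=None, parameterization="adjacent"):
    if alpha is None:
        alpha = np.zeros((spec.n_informants, spec.n_scales, spec.n_categories))
    return MixtureParams(
        spec=spec,
        pi=np.asarray(pi, dtype=float),
        beta=np.asarray(beta, dtype=float),
        alpha=np.asarray(alpha, dtype=float),
        parameterization=parameterization,
    )


# ---------------------------------------------------------------------------
# brute-force oracle: direct per-subject enumeration over classes, all
# probabilities computed with plain math.exp, no shared code path
# ---------------------------------------------------------------------------


def oracle_category_prob(alpha_vec, beta_scalar, k):
    weights = [math.exp(alpha_vec[j] + beta_scalar * j) for j in range(len(alpha_vec))]
    return weights[k] / sum(weights)


def oracle_loglik(X, pi, beta, alpha):
    total = 0.0
    n, I, S = X.shape
    for subj in range(n):
        mix = 0.0
        for c in range(len(pi)):
            lik = 1.0
            for i in range(I):
                for s in range(S):
                    k = X[subj, i, s]
                    if k == MISSING:
                        continue
                    lik *= oracle_category_prob(alpha[i, s], beta[c, i, s], k)
            mix += pi[c] * lik
        total += math.log(mix)
    return total


@st.composite
def small_instances(draw):
    K = draw(st.integers(1, 3))
    I = draw(st.integers(1, 2))
    S = draw(st.integers(1, 2))
    C = draw(st.integers(2, 3))
    n = draw(st.integers(1, 4))
    finite = st.floats(-2, 2, allow_nan=False)
    pi = np.array(draw(st.lists(st.floats(0.05, 1), min_size=K, max_size=K)))
    pi = pi / pi.sum()
    beta = np.array(
        draw(st.lists(finite, min_size=K * I * S, max_size=K * I * S))
    ).reshape(K, I, S)
    alpha = np.array(
        draw(st.lists(finite, min_size=I * S * C, max_size=I * S * C))
    ).reshape(I, S, C)
    alpha[..., 0] = 0.0
    X = np.array(
        draw(st.lists(st.integers(-1, C - 1), min_size=n * I * S, max_size=n * I * S))
    ).reshape(n, I, S)
    return pi, beta, alpha, X, C, I, S


@settings(max_examples=200, deadline=None, derandomize=True)
@given(small_instances())
def test_loglikelihood_matches_enumeration_oracle(instance):
    """The vectorized likelihood equals exhaustive class enumeration."""
    pi, beta, alpha, X, C, I, S = instance
    spec = ModelSpec(
        scales=tuple(f"s{j}" for j in range(S)),
        informants=("self", "parent")[:I],
        n_categories=C,
    )
    params = make_params(spec, pi, beta, alpha)
    assert loglikelihood(X, params) == pytest.approx(
        oracle_loglik(X, pi, beta, alpha), abs=1e-10
    )


# ---------------------------------------------------------------------------
# response model
# ---------------------------------------------------------------------------


def test_category_probs_uniform_when_all_logits_zero():
    spec = ModelSpec()
    params = make_params(spec, [1.0], np.zeros((1, 2, 5)))
    probs = params.category_probs(0, "self", "emotional")
    assert probs == pytest.approx(np.full(11, 1 / 11), abs=1e-12)


def test_category_probs_two_categories_hand_computed():
    # beta = ln 3 with zero intercepts: weights (1, 3) -> (0.25, 0.75)
    spec = ModelSpec(scales=("a",), informants=("self",), n_categories=2)
    params = make_params(spec, [1.0], np.full((1, 1, 1), math.log(3.0)))
    assert params.category_probs(0, "self", "a") == pytest.approx(
        [0.25, 0.75], abs=1e-12
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(small_instances())
def test_category_probs_normalized(instance):
    pi, beta, alpha, _X, C, I, S = instance
    spec = ModelSpec(
        scales=tuple(f"s{j}" for j in range(S)),
        informants=("self", "parent")[:I],
        n_categories=C,
    )
    params = make_params(spec, pi, beta, alpha)
    table = params.category_prob_table()
    assert np.abs(table.sum(axis=-1) - 1.0).max() < 1e-12


def test_category_probs_invalid_index_raises():
    spec = ModelSpec()
    params = make_params(spec, [1.0], np.zeros((1, 2, 5)))
    with pytest.raises(IndexError):
        params.category_probs(3, "self", "emotional")
    with pytest.raises(KeyError):
        params.category_probs(0, "teacher", "emotional")


# ---------------------------------------------------------------------------
# likelihood conventions
# ---------------------------------------------------------------------------


def test_subject_with_no_records_contributes_zero():
    spec = ModelSpec()
    params = make_params(spec, [0.4, 0.6], np.zeros((2, 2, 5)))
    X = np.full((1, 2, 5), MISSING)
    assert loglikelihood(X, params) == pytest.approx(0.0, abs=1e-14)


def test_single_record_uniform_categories_forced_value():
    # one informant record, 5 scales, uniform 11-category model
    spec = ModelSpec()
    params = make_params(spec, [1.0], np.zeros((1, 2, 5)))
    X = np.full((1, 2, 5), MISSING)
    X[0, 0, :] = 4
    assert loglikelihood(X, params) == pytest.approx(5 * math.log(1 / 11), abs=1e-9)


def test_out_of_range_score_rejected():
    spec = ModelSpec(scales=("a",), informants=("self",), n_categories=3)
    params = make_params(spec, [1.0], np.zeros((1, 1, 1)))
    with pytest.raises(ValueError):
        loglikelihood(np.array([[[5]]]), params)


# ---------------------------------------------------------------------------
# posteriors
# ---------------------------------------------------------------------------


def test_posterior_single_class_is_one():
    spec = ModelSpec()
    params = make_params(spec, [1.0], np.zeros((1, 2, 5)))
    X = np.full((2, 5), MISSING)
    X[0, 0] = 3
    result = posterior(X, params)
    assert result.probabilities == pytest.approx([1.0])
    assert result.modal_class == 0


def test_posterior_without_data_returns_prior():
    spec = ModelSpec()
    pi = [0.2, 0.5, 0.3]
    params = make_params(spec, pi, np.zeros((3, 2, 5)))
    result = posterior(np.full((2, 5), MISSING), params)
    assert result.probabilities == pytest.approx(pi, abs=1e-14)


def test_posterior_bayes_rule_hand_example():
    # class likelihoods 0.09 and 0.01 with equal priors -> (0.9, 0.1)
    spec = ModelSpec(scales=("a",), informants=("self",), n_categories=3)
    logits = np.zeros((2, 1, 1, 3))
    logits[0, 0, 0] = np.log([0.09, 0.455, 0.455]) - math.log(0.09)
    logits[1, 0, 0] = np.log([0.01, 0.495, 0.495]) - math.log(0.01)
    params = make_params(spec, [0.5, 0.5], logits, parameterization="multinomial")
    result = posterior(np.array([[0]]), params)
    assert result.probabilities == pytest.approx([0.9, 0.1], abs=1e-12)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def test_one_class_fit_matches_observed_frequencies(rng):
    spec = ModelSpec(scales=("a", "b"), informants=("self",), n_categories=4)
    X = rng.integers(0, 4, size=(400, 1, 2))
    fit = em_fit(X, 1, spec, FitConfig(n_starts=2, seed=0))
    table = fit.params.category_prob_table()
    for s in range(2):
        observed = np.bincount(X[:, 0, s], minlength=4) / len(X)
        assert table[0, 0, s] == pytest.approx(observed, abs=1e-6)


def test_em_loglik_nondecreasing(rng):
    spec = ModelSpec(scales=("a", "b"), informants=("self", "parent"), n_categories=4)
    X = rng.integers(0, 4, size=(150, 2, 2))
    fit = em_fit(X, 2, spec, FitConfig(n_starts=3, start_iters=None, max_iter=60, seed=5))
    hist = np.array(fit.history)
    assert (np.diff(hist) >= -1e-9 * np.abs(hist[:-1])).all()


def test_em_requires_valid_arguments():
    spec = ModelSpec()
    with pytest.raises(ValueError):
        em_fit(np.zeros((5, 2, 5), dtype=int), 0, spec)
    with pytest.raises(ValueError):
        em_fit(np.zeros((0, 2, 5), dtype=int), 2, spec)


def test_permutation_invariance_of_likelihood_and_posteriors(rng):
    spec = ModelSpec(scales=("a",), informants=("self",), n_categories=3)
    beta = np.array([[[0.5]], [[-0.7]]])
    params = make_params(spec, [0.3, 0.7], beta)
    perm = make_params(spec, [0.7, 0.3], beta[::-1])
    X = rng.integers(0, 3, size=(40, 1, 1))
    assert loglikelihood(X, params) == pytest.approx(loglikelihood(X, perm), abs=1e-12)
    p0 = posterior(X[0], params).probabilities
    p1 = posterior(X[0], perm).probabilities
    assert p0 == pytest.approx(p1[::-1], abs=1e-12)


def test_canonical_class_order_ascending_total_difficulties():
    spec = ModelSpec()
    beta = np.zeros((2, 2, 5))
    beta[0, :, :4] = 1.0   # class 0 severe on the four difficulties scales
    params = make_params(spec, [0.5, 0.5], beta).canonicalized()
    totals = params.expected_total_difficulties()
    assert totals[0] < totals[1]


# ---------------------------------------------------------------------------
# model selection and diagnostics
# ---------------------------------------------------------------------------


def test_bic_formula():
    assert bic(-100.0, 10, 100) == pytest.approx(200 + 10 * math.log(100), abs=1e-4)


def test_select_model_single_candidate(rng):
    spec = ModelSpec(scales=("a",), informants=("self",), n_categories=3)
    X = rng.integers(0, 3, size=(60, 1, 1))
    fit, table = select_model(X, {2}, spec, FitConfig(n_starts=2, seed=3))
    assert fit.params.K == 2
    assert table["K"].tolist() == [2]
    assert table.loc[0, "bic"] == pytest.approx(
        bic(fit.loglik, fit.n_free_params, 60), abs=1e-9
    )


def test_entropy_r2_hand_values():
    spec = ModelSpec(scales=("a",), informants=("self",), n_categories=2)
    params = make_params(spec, [0.5, 0.5], np.zeros((2, 1, 1)))

    def fake_fit(posts):
        from sdqprofiles.mixture import FitResult, _posterior_result

        return FitResult(
            params=params, loglik=0.0, bic=0.0, n_free_params=0,
            posteriors=[_posterior_result(np.array(p)) for p in posts],
        )

    assert entropy_r2(fake_fit([[1.0, 0.0], [0.0, 1.0]])) == pytest.approx(1.0)
    assert entropy_r2(fake_fit([[0.5, 0.5], [0.5, 0.5]])) == pytest.approx(0.0, abs=1e-12)
    expected = 1 - (0.325083 + 0.693147) / (2 * math.log(2))
    assert entropy_r2(fake_fit([[0.9, 0.1], [0.5, 0.5]])) == pytest.approx(
        expected, abs=1e-4
    )
    with pytest.raises(ValueError):
        entropy_r2(fake_fit([[1.0]]))


def test_params_json_round_trip(tmp_path):
    spec = ModelSpec()
    alpha = np.zeros((2, 5, 11))
    alpha[..., 1:] = 0.25
    params = make_params(spec, [0.25, 0.75], np.full((2, 2, 5), 0.125), alpha)
    path = tmp_path / "model.json"
    params.to_json(path)
    loaded = MixtureParams.from_json(path)
    assert loaded.spec == params.spec
    assert (loaded.pi == params.pi).all()
    assert (loaded.beta == params.beta).all()
    assert (loaded.alpha == params.alpha).all()


def test_score_array_round_trip(rng):
    spec = ModelSpec()
    X = rng.integers(0, 11, size=(10, 2, 5))
    X[3, 1, :] = MISSING
    X[5, 0, 2] = MISSING
    back = to_score_array(from_score_array(X, spec), spec)
    assert (back == X).all()
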