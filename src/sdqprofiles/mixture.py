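"""Two-level finite mixture model for multi-informant ordinal subscale scores.

Subjects belong to one of ``K`` latent profiles.  Conditional on the
profile, each observed informant report contributes independent ordinal
subscale scores.  The default response model is an adjacent-category
(linear-by-linear) logit with equidistant category scores::

    P(score = k | class c, informant i, scale s)
        ∝ exp(alpha[i, s, k] + beta[c, i, s] * k),   k = 0..C-1

where the category intercepts ``alpha`` are shared across classes
(``alpha[i, s, 0] = 0``) and the scalar location ``beta`` shifts the whole
distribution of a scale up or down per class.  A saturated per-category
multinomial parameterization is available via ``parameterization
="multinomial"``, in which case ``beta`` holds a full logit vector per
(class, informant, scale) with the first category fixed at zero and
``alpha`` is unused (all zero).

The adjacent-category model has one non-identified direction per
(informant, scale) block: adding d to every class's beta while subtracting
d*k from alpha[k] leaves all probabilities unchanged.  Fitted parameters
are therefore reported in the gauge where the unweighted class mean of
beta is zero within each block, and the BIC's free-parameter count takes
the constraint into account.

Estimation is by EM with multiple seeded random starts.  Informant records
(and single scores) may be missing; they simply drop out of the likelihood,
which is the maximum-likelihood treatment under missingness at random.
Classes are reported in ascending order of expected total-difficulties
score so that repeated runs label profiles consistently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .records import MISSING, ModelSpec, SubjectRecord, to_score_array

PROB_FLOOR = 1e-10  # guards log(0) for degenerate categories during EM

MODEL_SCHEMA_VERSION = 1


class NumericalError(RuntimeError):
    """Raised when the likelihood becomes non-finite during estimation."""


@dataclass
class FitConfig:
    """EM estimation settings.

    ``n_starts`` random initializations are each run for ``start_iters``
    EM iterations; the most promising is then run to convergence
    (relative log-likelihood change below ``tol`` or ``max_iter``
    iterations).  ``start_iters=None`` runs every start to convergence.
    """

    n_starts: int = 20
    start_iters: int | None = 30
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0
    parameterization: str = "adjacent"  # or "multinomial"

    def __post_init__(self):
        if self.parameterization not in ("adjacent", "multinomial"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        if self.n_starts < 1 or self.max_iter < 1:
            raise ValueError("n_starts and max_iter must be >= 1")


@dataclass
class MixtureParams:
    """Fitted (or true) parameters of a K-class multi-informant mixture."""

    spec: ModelSpec
    pi: np.ndarray          # (K,)
    beta: np.ndarray        # adjacent: (K, I, S); multinomial: (K, I, S, C)
    alpha: np.ndarray       # (I, S, C), alpha[..., 0] == 0
    parameterization: str = "adjacent"
    meta: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.pi)

    def validate(self) -> None:
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if (self.pi <= 0).any():
            raise ValueError("pi entries must be > 0")
        if np.abs(self.alpha[..., 0]).max() > 0:
            raise ValueError("alpha[..., 0] must be exactly 0")
        probs = self.category_prob_table()
        if np.abs(probs.sum(axis=-1) - 1.0).max() > 1e-12:
            raise ValueError("category probabilities must sum to 1")

    # -- response model ----------------------------------------------------

    def category_logits(self) -> np.ndarray:
        """(K, I, S, C) unnormalized log response probabilities."""
        if self.parameterization == "adjacent":
            k = np.arange(self.spec.n_categories)
            return self.alpha[None] + self.beta[..., None] * k
        return self.beta + self.alpha[None]

    def log_category_probs(self) -> np.ndarray:
        logits = self.category_logits()
        return logits - logsumexp(logits, axis=-1, keepdims=True)

    def category_prob_table(self) -> np.ndarray:
        return np.exp(self.log_category_probs())

    def category_probs(self, class_idx: int, informant: str, scale: str) -> np.ndarray:
        """P(score = k | class, informant, scale) for k = 0..C-1."""
        if not 0 <= class_idx < self.K:
            raise IndexError(f"class index {class_idx} out of range for K={self.K}")
        i = self.spec.informant_index(informant)
        s = self.spec.scale_index(scale)
        return self.category_prob_table()[class_idx, i, s]

    # -- canonical form ----------------------------------------------------

    def expected_scores(self) -> np.ndarray:
        """(K, I, S) expected score per class/informant/scale."""
        probs = self.category_prob_table()
        k = np.arange(self.spec.n_categories)
        return probs @ k

    def expected_total_difficulties(self) -> np.ndarray:
        """Per class, expected sum of difficulty-scale scores, averaged over
        informants; used as the deterministic class ordering key."""
        means = self.expected_scores()
        idx = [self.spec.scale_index(s) for s in self.spec.difficulty_scales]
        return means[:, :, idx].sum(axis=2).mean(axis=1)

    def canonicalized(self) -> "MixtureParams":
        """Gauge-fix the adjacent-category betas (class mean zero per block)
        and order classes by ascending expected total difficulties."""
        beta = self.beta.copy()
        alpha = self.alpha.copy()
        if self.parameterization == "adjacent":
            shift = beta.mean(axis=0)                      # (I, S)
            beta -= shift[None]
            alpha += shift[..., None] * np.arange(self.spec.n_categories)
            alpha -= alpha[..., :1]                        # keep alpha[...,0] == 0 exactly
        order = np.argsort(
            MixtureParams(self.spec, self.pi, beta, alpha,
                          self.parameterization).expected_total_difficulties(),
            kind="stable",
        )
        return MixtureParams(
            spec=self.spec,
            pi=self.pi[order].copy(),
            beta=beta[order].copy(),
            alpha=alpha,
            parameterization=self.parameterization,
            meta=dict(self.meta, class_order="ascending expected total difficulties"),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "scales": list(self.spec.scales),
            "informants": list(self.spec.informants),
            "n_categories": self.spec.n_categories,
            "parameterization": self.parameterization,
            "pi": self.pi.tolist(),
            "beta": self.beta.tolist(),
            "alpha": self.alpha.tolist(),
            "meta": self.meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "MixtureParams":
        version = payload.get("schema_version")
        if version != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {version!r}")
        spec = ModelSpec(
            scales=tuple(payload["scales"]),
            informants=tuple(payload["informants"]),
            n_categories=int(payload["n_categories"]),
        )
        return cls(
            spec=spec,
            pi=np.asarray(payload["pi"], dtype=float),
            beta=np.asarray(payload["beta"], dtype=float),
            alpha=np.asarray(payload["alpha"], dtype=float),
            parameterization=payload["parameterization"],
            meta=dict(payload.get("meta", {})),
        )

    @classmethod
    def from_json(cls, path) -> "MixtureParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PosteriorResult:
    """Posterior class membership for one subject."""

    probabilities: np.ndarray
    modal_class: int
    entropy_contribution: float


@dataclass
class FitResult:
    params: MixtureParams
    loglik: float
    bic: float
    n_free_params: int
    posteriors: list[PosteriorResult]
    history: list[float] = field(default_factory=list)

    @property
    def posterior_matrix(self) -> np.ndarray:
        return np.vstack([p.probabilities for p in self.posteriors])


# ---------------------------------------------------------------------------
# likelihood machinery (dense-array fast path)
# ---------------------------------------------------------------------------


def _as_array(data, spec: ModelSpec) -> np.ndarray:
    if isinstance(data, np.ndarray):
        return data
    return to_score_array(data, spec)


def _check_scores(X: np.ndarray, spec: ModelSpec) -> None:
    if X.size and X.max() >= spec.n_categories:
        raise ValueError(
            f"score {X.max()} outside [0, {spec.n_categories - 1}]"
        )


def _class_loglik(X: np.ndarray, params: MixtureParams) -> np.ndarray:
    """(n, K) log-likelihood of each subject's observed scores per class."""
    logp = params.log_category_probs()            # (K, I, S, C)
    n, I, S = X.shape
    mask = X != MISSING
    Xc = np.where(mask, X, 0)
    out = np.zeros((n, params.K))
    ii = np.arange(I)[:, None]
    ss = np.arange(S)[None, :]
    for c in range(params.K):
        g = logp[c][ii, ss, Xc]                   # (n, I, S)
        out[:, c] = np.where(mask, g, 0.0).sum(axis=(1, 2))
    return out


def loglikelihood(data, params: MixtureParams) -> float:
    """Observed-data log-likelihood; absent records/scores contribute no factor."""
    X = _as_array(data, params.spec)
    _check_scores(X, params.spec)
    if (params.pi <= 0).any():
        raise ValueError("pi entries must be > 0")
    ll = _class_loglik(X, params)
    return float(logsumexp(ll + np.log(params.pi)[None, :], axis=1).sum())


def _posterior_matrix(X: np.ndarray, params: MixtureParams) -> tuple[np.ndarray, float]:
    lp = _class_loglik(X, params) + np.log(params.pi)[None, :]
    norm = logsumexp(lp, axis=1)
    return np.exp(lp - norm[:, None]), float(norm.sum())


def posterior(record: SubjectRecord | np.ndarray, params: MixtureParams) -> PosteriorResult:
    """Posterior profile probabilities for a single subject.

    Handles any subset of observed informants/scales; with no observed
    scores the posterior equals the mixing proportions (the prior).
    """
    if isinstance(record, SubjectRecord):
        X = to_score_array([record], params.spec)
    else:
        X = np.asarray(record).reshape(1, params.spec.n_informants, params.spec.n_scales)
    _check_scores(X, params.spec)
    probs, _ = _posterior_matrix(X, params)
    return _posterior_result(probs[0])


def _posterior_result(p: np.ndarray) -> PosteriorResult:
    ent = float(-(p * np.log(np.clip(p, 1e-300, None))).sum())
    return PosteriorResult(probabilities=p, modal_class=int(np.argmax(p)),
                           entropy_contribution=ent)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _weighted_counts(X: np.ndarray, resp: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """(K, I, S, C) posterior-weighted category counts."""
    n, I, S = X.shape
    K = resp.shape[1]
    C = spec.n_categories
    N = np.zeros((K, I, S, C))
    for i in range(I):
        for s in range(S):
            obs = X[:, i, s] != MISSING
            x = X[obs, i, s]
            w = resp[obs]
            for c in range(K):
                N[c, i, s] = np.bincount(x, weights=w[:, c], minlength=C)
    return N


def _block_objective(theta: np.ndarray, N: np.ndarray, K: int, C: int):
    """Negative expected complete-data log-likelihood of one (informant,
    scale) block under the adjacent-category model, with gradient.

    theta = [alpha_1..alpha_{C-1}, beta_0..beta_{K-1}];  N is (K, C).
    """
    alpha = np.concatenate(([0.0], theta[: C - 1]))
    beta = theta[C - 1:]
    k = np.arange(C)
    logits = alpha[None, :] + beta[:, None] * k          # (K, C)
    logz = logsumexp(logits, axis=1)
    logp = logits - logz[:, None]
    T = N.sum(axis=1)                                    # (K,)
    q = float((N * logp).sum())
    p = np.exp(logp)
    resid = N - T[:, None] * p                           # (K, C)
    grad_alpha = resid.sum(axis=0)[1:]
    grad_beta = (resid * k).sum(axis=1)
    return -q, -np.concatenate([grad_alpha, grad_beta])


def _mstep_adjacent(
    N: np.ndarray, alpha: np.ndarray, beta: np.ndarray, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(informant, scale) block maximization, warm-started at the
    current parameters; L-BFGS with analytic gradients.  Because each
    solve starts from the current point and never increases the negative
    objective, the overall EM step cannot decrease the likelihood."""
    K, I, S = beta.shape
    C = spec.n_categories
    alpha_new = alpha.copy()
    beta_new = beta.copy()
    for i in range(I):
        for s in range(S):
            x0 = np.concatenate([alpha[i, s, 1:], beta[:, i, s]])
            res = minimize(
                _block_objective,
                x0,
                args=(N[:, i, s, :], K, C),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 60, "ftol": 1e-12, "gtol": 1e-9},
            )
            alpha_new[i, s, 1:] = res.x[: C - 1]
            beta_new[:, i, s] = res.x[C - 1:]
    return alpha_new, beta_new


def _mstep_multinomial(N: np.ndarray) -> np.ndarray:
    """Closed-form per-category logits from weighted counts (floored)."""
    T = N.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(T > 0, N / np.where(T > 0, T, 1.0), 1.0 / N.shape[-1])
    p = np.clip(p, PROB_FLOOR, None)
    p /= p.sum(axis=-1, keepdims=True)
    logits = np.log(p)
    return logits - logits[..., :1]


def _random_init(K: int, spec: ModelSpec, rng: np.random.Generator,
                 parameterization: str) -> MixtureParams:
    pi = rng.dirichlet(np.full(K, 5.0))
    if parameterization == "adjacent":
        beta = rng.normal(0.0, 1.0, size=(K, spec.n_informants, spec.n_scales))
        alpha = np.zeros((spec.n_informants, spec.n_scales, spec.n_categories))
    else:
        beta = rng.normal(0.0, 0.5,
                          size=(K, spec.n_informants, spec.n_scales, spec.n_categories))
        beta[..., 0] = 0.0
        alpha = np.zeros((spec.n_informants, spec.n_scales, spec.n_categories))
    return MixtureParams(spec=spec, pi=pi, beta=beta, alpha=alpha,
                         parameterization=parameterization)


def _em_run(
    X: np.ndarray,
    params: MixtureParams,
    tol: float,
    max_iter: int,
) -> tuple[MixtureParams, list[float]]:
    spec = params.spec
    history: list[float] = []
    for _ in range(max_iter):
        resp, ll = _posterior_matrix(X, params)
        if not np.isfinite(ll):
            raise NumericalError(
                f"non-finite log-likelihood at iteration {len(history)}"
            )
        if history and abs(ll - history[-1]) <= tol * abs(history[-1]):
            history.append(ll)
            break
        history.append(ll)
        pi = resp.mean(axis=0)
        pi = np.clip(pi, PROB_FLOOR, None)
        pi /= pi.sum()
        N = _weighted_counts(X, resp, spec)
        if params.parameterization == "adjacent":
            alpha, beta = _mstep_adjacent(N, params.alpha, params.beta, spec)
        else:
            beta = _mstep_multinomial(N)
            alpha = params.alpha
        params = MixtureParams(spec=spec, pi=pi, beta=beta, alpha=alpha,
                               parameterization=params.parameterization)
    return params, history


def n_free_parameters(K: int, spec: ModelSpec, parameterization: str) -> int:
    """Free-parameter count for the BIC; the adjacent-category count
    subtracts one gauge constraint per (informant, scale) block."""
    blocks = spec.n_informants * spec.n_scales
    if parameterization == "adjacent":
        return (K - 1) + blocks * ((spec.n_categories - 1) + (K - 1))
    return (K - 1) + blocks * K * (spec.n_categories - 1)


def bic(loglik: float, n_free_params: int, n_subjects: int) -> float:
    """BIC = -2 loglik + n_free_params * ln(n_subjects); the sample size is
    the number of level-2 units (subjects), where the classes live."""
    return -2.0 * loglik + n_free_params * np.log(n_subjects)


def em_fit(data, K: int, spec: ModelSpec | None = None,
           config: FitConfig | None = None) -> FitResult:
    """Fit a K-class mixture by multi-start EM.

    ``data`` is a list of :class:`SubjectRecord` or a dense score array.
    Deterministic given ``config.seed``; the best final log-likelihood
    wins, ties broken by lowest start index.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    config = config or FitConfig()
    spec = spec or ModelSpec()
    X = _as_array(data, spec)
    if X.shape[0] == 0:
        raise ValueError("data must contain at least one subject")
    _check_scores(X, spec)
    rng = np.random.default_rng(config.seed)

    starts = [_random_init(K, spec, rng, config.parameterization)
              for _ in range(config.n_starts)]
    histories: list[list[float]] = [[] for _ in starts]
    if config.start_iters is not None and config.n_starts > 1:
        short = []
        for j, p0 in enumerate(starts):
            p1, h = _em_run(X, p0, config.tol, config.start_iters)
            histories[j] = h
            short.append((h[-1], j, p1))
        best_ll, best_j, best_params = max(short, key=lambda t: (t[0], -t[1]))
        params, h2 = _em_run(X, best_params, config.tol, config.max_iter)
        history = histories[best_j] + h2
    else:
        best = None
        for j, p0 in enumerate(starts):
            p1, h = _em_run(X, p0, config.tol, config.max_iter)
            if best is None or h[-1] > best[0]:
                best = (h[-1], j, p1, h)
        _, best_j, params, history = best

    params = params.canonicalized()
    params.meta.update(
        final_loglik=history[-1],
        n_iterations=len(history),
        seed=config.seed,
        n_starts=config.n_starts,
        parameterization=config.parameterization,
    )
    resp, ll = _posterior_matrix(X, params)
    p_free = n_free_parameters(K, spec, config.parameterization)
    posteriors = [_posterior_result(resp[i]) for i in range(X.shape[0])]
    return FitResult(
        params=params,
        loglik=ll,
        bic=bic(ll, p_free, X.shape[0]),
        n_free_params=p_free,
        posteriors=posteriors,
        history=history,
    )


def select_model(data, K_range, spec: ModelSpec | None = None,
                 config: FitConfig | None = None):
    """Fit each K in ``K_range``; return (best FitResult, selection table).

    The minimum-BIC fit is selected.  A failed fit is recorded in the table
    and excluded from selection; all candidates failing is an error.
    The table is a pandas DataFrame with columns K, loglik, n_free_params,
    bic, error.
    """
    import pandas as pd

    Ks = sorted(set(int(k) for k in K_range))
    if not Ks:
        raise ValueError("K_range must be non-empty")
    config = config or FitConfig()
    spec = spec or ModelSpec()
    rows = []
    fits: dict[int, FitResult] = {}
    for K in Ks:
        try:
            fit = em_fit(data, K, spec, config)
        except Exception as exc:  # recorded, not raised
            rows.append({"K": K, "loglik": np.nan, "n_free_params": np.nan,
                         "bic": np.nan, "error": str(exc)})
            continue
        fits[K] = fit
        rows.append({"K": K, "loglik": fit.loglik,
                     "n_free_params": fit.n_free_params,
                     "bic": fit.bic, "error": ""})
    table = pd.DataFrame(rows)
    if not fits:
        raise NumericalError("every candidate fit failed")
    best_K = min(fits, key=lambda K: fits[K].bic)
    return fits[best_K], table


def entropy_r2(fit: FitResult) -> float:
    """Entropy-based R²: 1 - (sum of posterior entropies) / (n ln K).

    1 means perfectly separated classes, 0 means uniform posteriors.
    Undefined for K = 1.
    """
    K = len(fit.posteriors[0].probabilities) if fit.posteriors else fit.params.K
    if K < 2:
        raise ValueError("entropy_r2 is undefined for K=1")
    n = len(fit.posteriors)
    total = sum(p.entropy_contribution for p in fit.posteriors)
    return float(1.0 - total / (n * np.log(K)))
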