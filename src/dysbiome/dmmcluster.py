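"""Dirichlet-multinomial mixture (DMM) community typing.

Count compositions are clustered by an EM fit of a K-component mixture of
Dirichlet-multinomial distributions.  The M-step updates each component's
Dirichlet parameters with Minka's fixed-point iteration (a
minorise-maximise step, so the observed-data log-likelihood is monotone
non-decreasing).  The number of community types is chosen by minimising a
Laplace-approximate negative log model evidence over K = 1..15, mirroring
the standard "Laplace goodness of fit" criterion for DMMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp, polygamma, psi

from .coredata import CountTable, DysbiomeError


@dataclass
class DMMModel:
    K: int
    weights: np.ndarray  # mixture proportions, sums to 1
    alpha: np.ndarray  # K x n_taxa positive Dirichlet parameters
    responsibilities: np.ndarray  # n_samples x K, rows sum to 1
    log_likelihood: float
    log_likelihood_trace: list[float]
    laplace_evidence: float  # negative log evidence, lower is better
    labels: np.ndarray  # argmax responsibility
    sample_ids: list[str]
    converged: bool


def _dm_loglik_matrix(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """n_samples x K matrix of Dirichlet-multinomial log-densities (without
    the multinomial coefficient, constant across components)."""
    n = X.sum(axis=1)
    A = alpha.sum(axis=1)
    out = (gammaln(A)[None, :] - gammaln(n[:, None] + A[None, :])
           + (gammaln(X[:, None, :] + alpha[None, :, :])
              - gammaln(alpha)[None, :, :]).sum(axis=2))
    return out


def _minka_update(X: np.ndarray, r: np.ndarray, alpha: np.ndarray,
                  n_inner: int = 20) -> np.ndarray:
    """Weighted Minka fixed-point update of one component's alpha."""
    n = X.sum(axis=1)
    for _ in range(n_inner):
        A = alpha.sum()
        num = (r[:, None] * (psi(X + alpha[None, :]) - psi(alpha)[None, :])).sum(axis=0)
        den = (r * (psi(n + A) - psi(A))).sum()
        if den <= 0:
            break
        alpha = np.clip(alpha * num / den, 1e-8, 1e8)
    return alpha


def fit_dmm(
    counts: CountTable,
    K: int,
    n_init: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> DMMModel:
    """EM fit of a K-component Dirichlet-multinomial mixture; best of
    ``n_init`` random initialisations is kept."""
    X = counts.values().astype(float)
    n_samples, n_taxa = X.shape
    if K < 1:
        raise DysbiomeError("K must be >= 1")
    if K > n_samples:
        raise DysbiomeError("K exceeds the number of samples")
    rng = np.random.default_rng(seed)

    best: DMMModel | None = None
    props = (X + 0.5) / (X + 0.5).sum(axis=1, keepdims=True)
    for _ in range(max(1, n_init)):
        # initialise alphas from the compositions of random seed samples
        centers = rng.choice(n_samples, size=K, replace=False)
        alpha = np.clip(props[centers] * 50.0, 1e-3, None)
        weights = np.full(K, 1.0 / K)
        trace: list[float] = []
        converged = False
        for _it in range(max_iter):
            logp = _dm_loglik_matrix(X, alpha) + np.log(weights)[None, :]
            ll = float(logsumexp(logp, axis=1).sum())
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(ll)):
                converged = True
                break
            r = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
            weights = np.clip(r.mean(axis=0), 1e-12, None)
            weights /= weights.sum()
            for k in range(K):
                alpha[k] = _minka_update(X, r[:, k], alpha[k])
        logp = _dm_loglik_matrix(X, alpha) + np.log(weights)[None, :]
        r = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        ll = float(logsumexp(logp, axis=1).sum())
        model = DMMModel(
            K=K, weights=weights, alpha=alpha, responsibilities=r,
            log_likelihood=ll, log_likelihood_trace=trace,
            laplace_evidence=np.nan, labels=np.argmax(r, axis=1),
            sample_ids=counts.sample_ids, converged=converged)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    best.laplace_evidence = _laplace_evidence(X, best)
    return best


_LOG_ALPHA_PRIOR_SD = 10.0  # vague N(0, sd^2) prior on log alpha


def _laplace_evidence(X: np.ndarray, model: DMMModel) -> float:
    """Negative log model evidence by the Laplace approximation:
    ``-log L - log prior + (d/2) log 2pi`` terms plus half the log
    determinant of the negative Hessian.

    Parameters are the component alphas on the log scale (positivity) plus
    K-1 mixture weights; the Hessian is approximated block-diagonally per
    component from the responsibility-weighted DM likelihood.  The prior is
    a vague independent normal on log alpha and a flat Dirichlet on the
    weights, so extra parameters pay their prior volume.
    """
    K, p = model.alpha.shape
    d = K * p + (K - 1)
    neg_logdet = 0.0
    n = X.sum(axis=1)
    for k in range(K):
        a = model.alpha[k]
        r = model.responsibilities[:, k]
        A = a.sum()
        # Hessian of the weighted log-likelihood wrt alpha
        common = float((r * (polygamma(1, A) - polygamma(1, n + A))).sum())
        diag = (r[:, None] * (polygamma(1, X + a[None, :])
                              - polygamma(1, a)[None, :])).sum(axis=0)
        H = np.full((p, p), common)
        H[np.diag_indices(p)] += diag
        # chain rule to theta = log alpha: H_theta = D H D + diag(grad * a)
        grad = (r[:, None] * (psi(X + a[None, :]) - psi(a)[None, :])).sum(axis=0) \
            + float((r * (psi(A) - psi(n + A))).sum()) * np.ones(p)
        Ht = (a[:, None] * H * a[None, :])
        Ht[np.diag_indices(p)] += grad * a
        # flat / degenerate directions (near-empty or duplicated components)
        # must not reward extra components: floor the curvature eigenvalues
        eig = np.linalg.eigvalsh(-(Ht + Ht.T) / 2)
        neg_logdet += float(np.log(np.maximum(eig, 1.0)).sum())
    # weight block: multinomial information determinant N^(K-1) / prod(w_k)
    N = X.shape[0]
    if K > 1:
        w = np.clip(model.weights, 1e-12, None)
        neg_logdet += float((K - 1) * np.log(N) - np.log(w).sum())
    theta = np.log(np.clip(model.alpha, 1e-12, None)).ravel()
    sd = _LOG_ALPHA_PRIOR_SD
    neg_log_prior = float(
        0.5 * (theta ** 2).sum() / sd ** 2
        + K * p * 0.5 * np.log(2 * np.pi * sd ** 2)
        - gammaln(K)  # flat Dirichlet density on the weight simplex
    )
    return float(-model.log_likelihood + neg_log_prior
                 - 0.5 * d * np.log(2 * np.pi) + 0.5 * neg_logdet)


def select_n_clusters(
    counts: CountTable,
    k_range: range | list[int] | None = None,
    n_init: int = 5,
    seed: int = 0,
) -> tuple[int, dict[int, float], dict[int, DMMModel]]:
    """Fit each K in ``k_range`` (default 1..15, capped at n_samples) and
    return the K minimising the Laplace negative log evidence, with the full
    trace."""
    if k_range is None:
        k_range = range(1, 16)
    ks = [k for k in k_range if 1 <= k <= counts.n_samples]
    if not ks:
        raise DysbiomeError("k_range out of bounds")
    trace: dict[int, float] = {}
    models: dict[int, DMMModel] = {}
    for k in ks:
        try:
            m = fit_dmm(counts, k, n_init=n_init, seed=seed + k)
        except Exception as exc:
            warnings.warn(f"K={k} failed to converge and was skipped: {exc}")
            continue
        eff_n = m.responsibilities.sum(axis=0)
        if k > 1 and eff_n.min() < 2.0:
            warnings.warn(
                f"K={k} produced a component supported by fewer than 2 "
                "samples (non-identified); skipped")
            continue
        trace[k] = m.laplace_evidence
        models[k] = m
    if not trace:
        raise DysbiomeError("no K converged")
    best = min(trace, key=trace.get)
    return best, trace, models


def fit_single_dm_mle(counts: CountTable) -> np.ndarray:
    """Direct maximum-likelihood Dirichlet-multinomial fit (K = 1 oracle)
    by quasi-Newton optimisation over log alpha."""
    from scipy.optimize import minimize

    X = counts.values().astype(float)
    n = X.sum(axis=1)
    props = (X + 0.5) / (X + 0.5).sum(axis=1, keepdims=True)
    theta0 = np.log(np.clip(props.mean(axis=0) * 10.0, 1e-3, None))

    def negloglik(theta):
        a = np.exp(theta)
        A = a.sum()
        ll = (gammaln(A) - gammaln(n + A)
              + (gammaln(X + a[None, :]) - gammaln(a)[None, :]).sum(axis=1)).sum()
        grad_a = ((psi(A) - psi(n + A)).sum()
                  + (psi(X + a[None, :]) - psi(a)[None, :]).sum(axis=0))
        return -float(ll), -grad_a * a

    res = minimize(negloglik, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return np.exp(res.x)
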