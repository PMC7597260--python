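"""Exponential-family definitions and restricted maximum-likelihood fitting.

The response density is the canonical linear exponential family
``pi(y | x) = exp{y * theta - b(theta) + A(y)}`` with ``theta = x' beta``
and unit dispersion.  All family-specific mathematics — the cumulant
``b``, the mean ``mu = b'`` and the variance ``sigma = b''`` — lives in
:class:`FamilySpec`; everything downstream (stepwise search, tuning,
simulation) is family-agnostic.

The working log-likelihood is kept on the per-observation (mean) scale,

    ell(beta) = n^{-1} sum_i [ y_i * eta_i - b(eta_i) ],

dropping the ``A(y)`` term, which is constant in ``beta`` and irrelevant
both to the maximizer and to any likelihood difference used by the
selection criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .data import Dataset

__all__ = [
    "FamilySpec",
    "ModelFit",
    "SingularDesignError",
    "get_family",
    "loglik",
    "fit_glm",
    "predict_mean",
    "GAUSSIAN",
    "BINOMIAL",
    "POISSON",
]

# Linear predictors beyond this are treated as numerically saturated for
# the binomial family (expit is exactly 0/1 in float64 well before 40).
_ETA_CLIP = 40.0

# Iterate sup-norm beyond which a binomial/poisson fit is declared
# divergent (quasi-separation); the best iterate found so far is kept.
_BETA_DIVERGENCE = 30.0


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the restricted design submatrix is rank deficient."""


@dataclass(frozen=True)
class FamilySpec:
    """One canonical exponential family: cumulant and its derivatives."""

    name: str
    b: Callable[[np.ndarray], np.ndarray]
    mu: Callable[[np.ndarray], np.ndarray]
    sigma: Callable[[np.ndarray], np.ndarray]


def _binom_b(theta):
    # log(1 + e^theta), computed stably for large |theta|
    return np.logaddexp(0.0, theta)


def _pois_b(theta):
    with np.errstate(over="ignore"):
        return np.exp(theta)


GAUSSIAN = FamilySpec(
    name="gaussian",
    b=lambda t: 0.5 * np.square(t),
    mu=lambda t: np.asarray(t, dtype=float),
    sigma=lambda t: np.ones_like(np.asarray(t, dtype=float)),
)

BINOMIAL = FamilySpec(name="binomial", b=_binom_b, mu=expit, sigma=lambda t: expit(t) * expit(-t))

POISSON = FamilySpec(name="poisson", b=_pois_b, mu=_pois_b, sigma=_pois_b)

_FAMILIES = {f.name: f for f in (GAUSSIAN, BINOMIAL, POISSON)}


def get_family(name: str) -> FamilySpec:
    """Look up a family by name ('gaussian', 'binomial' or 'poisson')."""
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; expected one of {sorted(_FAMILIES)}"
        ) from None


@dataclass
class ModelFit:
    """A maximum-likelihood fit of the GLM restricted to index set S.

    ``S`` always contains 0 (the intercept column); ``beta`` aligns with
    ``S``; ``loglik`` is the mean log-likelihood at ``beta``.
    """

    S: tuple[int, ...]
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int = 0


def _linear_predictor(S: Sequence[int], beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    return X[:, list(S)] @ np.asarray(beta, dtype=float)


def loglik(S: Sequence[int], beta_S, data: Dataset, fam: FamilySpec) -> float:
    """Mean log-likelihood of the model restricted to S at coefficients beta_S."""
    beta_S = np.asarray(beta_S, dtype=float)
    if beta_S.shape[0] != len(S):
        raise ValueError("beta_S must align with S")
    eta = _linear_predictor(S, beta_S, data.X)
    value = _loglik_from_eta(eta, data.y, fam)
    if not np.isfinite(value):
        raise FloatingPointError(
            f"invalid linear predictor for family {fam.name!r}: log-likelihood not finite"
        )
    return value


def _loglik_from_eta(eta: np.ndarray, y: np.ndarray, fam: FamilySpec) -> float:
    with np.errstate(over="ignore", invalid="ignore"):
        val = float(np.mean(y * eta - fam.b(eta)))
    return val


def fit_glm(
    S: Sequence[int],
    data: Dataset,
    fam: FamilySpec,
    tol: float = 1e-8,
    max_iter: int = 100,
    beta0: np.ndarray | None = None,
) -> ModelFit:
    """Newton–Raphson / IRLS maximizer of the mean log-likelihood on S.

    Gaussian reduces to one least-squares solve.  Step-halving (up to 30
    halvings) is applied when a Newton step fails to increase the
    objective.  Quasi-separated binomial fits (iterate sup-norm above 30)
    return ``converged=False`` with the best iterate found; callers
    compare such fits by their achieved log-likelihood.
    """
    S = tuple(int(j) for j in S)
    if 0 not in S:
        raise ValueError("the intercept index 0 must belong to S")
    if len(S) >= data.n:
        raise ValueError("|S| must be smaller than n")
    Xs = data.X[:, list(S)]
    y = data.y
    n, k = Xs.shape

    if fam.name == "gaussian":
        beta, _, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
        if rank < k:
            raise SingularDesignError(f"design submatrix for S={S} is rank deficient")
        ll = _loglik_from_eta(Xs @ beta, y, fam)
        return ModelFit(S=S, beta=beta, loglik=ll, converged=True, n_iter=1)

    if np.linalg.matrix_rank(Xs) < k:
        raise SingularDesignError(f"design submatrix for S={S} is rank deficient")

    beta = np.zeros(k) if beta0 is None else np.array(beta0, dtype=float)
    eta = Xs @ beta
    ll = _loglik_from_eta(eta, y, fam)
    if not np.isfinite(ll):
        beta = np.zeros(k)
        eta = Xs @ beta
        ll = _loglik_from_eta(eta, y, fam)
    converged = False
    it = 0
    # score tolerance is relative to the response scale: for count data
    # with large means an absolute 1e-8 sits below float64 resolution
    score_tol = tol * max(1.0, float(np.mean(np.abs(y))))
    for it in range(1, max_iter + 1):
        mu = fam.mu(eta)
        score = Xs.T @ (y - mu) / n
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = fam.sigma(eta)
        H = Xs.T @ (Xs * w[:, None]) / n
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            # weight-degenerate Hessian (e.g. saturated probabilities)
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step-halving line search on the mean log-likelihood
        new_beta, new_eta, new_ll = beta, eta, ll
        scale = 1.0
        improved = False
        for _ in range(31):
            cand = beta + scale * step
            cand_eta = Xs @ cand
            cand_ll = _loglik_from_eta(cand_eta, y, fam)
            if np.isfinite(cand_ll) and cand_ll >= ll:
                new_beta, new_eta, new_ll = cand, cand_eta, cand_ll
                improved = True
                break
            scale *= 0.5
        if not improved:
            # a vanishing Newton step means we are at the optimum to
            # machine precision even if the score check just missed tol
            if np.max(np.abs(step)) < 1e-8 * (1.0 + np.max(np.abs(beta))):
                converged = True
            break
        rel_change = abs(new_ll - ll) / max(1.0, abs(ll))
        beta, eta, ll = new_beta, new_eta, new_ll
        if np.max(np.abs(beta)) > _BETA_DIVERGENCE:
            break  # diverging iterates: (quasi-)separation
        if rel_change < tol and np.max(np.abs(Xs.T @ (y - fam.mu(eta)) / n)) < score_tol:
            converged = True
            break
    return ModelFit(S=S, beta=beta, loglik=ll, converged=converged, n_iter=it)


def predict_mean(fit: ModelFit, Xnew: np.ndarray, fam: FamilySpec) -> np.ndarray:
    """Predicted mean response mu(x' beta_S) for each row of ``Xnew``.

    ``Xnew`` must carry columns for every index in ``fit.S`` (intercept at
    column 0 included), i.e. be laid out like :attr:`Dataset.X`.
    """
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim != 2 or Xnew.shape[1] <= max(fit.S):
        raise ValueError(
            f"Xnew must have at least {max(fit.S) + 1} columns to cover S={fit.S}"
        )
    eta = Xnew[:, list(fit.S)] @ fit.beta
    if fam.name == "binomial":
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    return fam.mu(eta)
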