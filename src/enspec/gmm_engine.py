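"""Bivariate Gaussian mixtures with constrained covariance families.

Covariances are parameterized through the eigen-decomposition
``Sigma_k = lambda_k D_k A_k D_k^T`` (volume, orientation, shape).  The eight
families with closed-form M-steps are supported:

====== =============================================
EII    spherical, equal volume
VII    spherical, varying volume
EEI    diagonal, equal volume and shape
VEI    diagonal, varying volume, equal shape
EVI    diagonal, equal volume, varying shape
VVI    diagonal, varying volume and shape
EEE    ellipsoidal, equal volume, shape, orientation
VVV    ellipsoidal, fully varying
====== =============================================

Model selection maximizes BIC = 2*loglik - nu*log(n); ties prefer fewer
parameters, then fewer components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigError, FitError, ValidationError

__all__ = [
    "REQUIRED_MODELS",
    "GMMParams",
    "FitConfig",
    "count_free_params",
    "em_fit",
    "select_model",
    "responsibilities",
]

REQUIRED_MODELS = ("EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE", "VVV")

_LOG2PI = np.log(2.0 * np.pi)


def count_free_params(model: str, K: int, d: int = 2) -> int:
    """Number of free parameters: (K-1) weights + K*d means + covariance terms."""
    if K < 1:
        raise ConfigError("K must be >= 1")
    cov = {
        "EII": lambda: 1,
        "VII": lambda: K,
        "EEI": lambda: d,
        "VEI": lambda: K + d - 1,
        "EVI": lambda: 1 + K * (d - 1),
        "VVI": lambda: K * d,
        "EEE": lambda: d * (d + 1) // 2,
        "VVV": lambda: K * d * (d + 1) // 2,
    }
    if model not in cov:
        raise ConfigError(
            f"unsupported covariance model {model!r}; choose from {REQUIRED_MODELS}"
        )
    return (K - 1) + K * d + cov[model]()


@dataclass
class GMMParams:
    """A fitted (or constructed) bivariate Gaussian mixture."""

    model: str
    K: int
    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, 2)
    covariances: np.ndarray      # (K, 2, 2)
    loglik: float = np.nan
    n: int = 0
    loglik_trace: list = field(default_factory=list, repr=False)
    audit: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValidationError("mixture weights must sum to 1")
        if np.any(self.weights <= 0):
            raise ValidationError("mixture weights must be positive")

    @property
    def nu(self) -> int:
        return count_free_params(self.model, self.K, d=2)

    @property
    def bic(self) -> float:
        return 2.0 * self.loglik - self.nu * np.log(self.n)

    @property
    def sigma1(self) -> np.ndarray:
        return np.sqrt(self.covariances[:, 0, 0])

    @property
    def sigma2(self) -> np.ndarray:
        return np.sqrt(self.covariances[:, 1, 1])

    @property
    def rho(self) -> np.ndarray:
        return self.covariances[:, 0, 1] / (self.sigma1 * self.sigma2)


@dataclass(frozen=True)
class FitConfig:
    """Knobs for EM fitting and model selection."""

    k_range: Sequence[int] = tuple(range(1, 10))
    models: Sequence[str] = REQUIRED_MODELS
    restarts: int = 5
    tol: float = 1e-8
    max_iter: int = 500
    floor_factor: float = 1e-10
    seed: int | None = None

    def __post_init__(self):
        if len(self.k_range) == 0:
            raise ConfigError("k_range must be nonempty")
        if self.tol <= 0:
            raise ConfigError("tolerance must be > 0")
        for m in self.models:
            count_free_params(m, 1)  # validates labels


# ---------------------------------------------------------------------------
# E step


def _component_logpdf(X: np.ndarray, means: np.ndarray, covs: np.ndarray):
    """(n, K) log densities, vectorized via analytic 2x2 inverses."""
    a = covs[:, 0, 0]
    b = covs[:, 0, 1]
    c = covs[:, 1, 1]
    det = a * c - b * b
    if not np.all(det > 0):
        raise FloatingPointError("non-PD covariance in E step")
    d0 = X[:, None, 0] - means[None, :, 0]
    d1 = X[:, None, 1] - means[None, :, 1]
    quad = (c * d0 * d0 - 2.0 * b * d0 * d1 + a * d1 * d1) / det
    return -_LOG2PI - 0.5 * np.log(det)[None, :] - 0.5 * quad


def _estep(X, weights, means, covs):
    logp = _component_logpdf(X, means, covs) + np.log(weights)[None, :]
    norm = logsumexp(logp, axis=1)
    resp = np.exp(logp - norm[:, None])
    return resp, float(norm.sum())


def responsibilities(X, params: GMMParams) -> np.ndarray:
    """Posterior component memberships (rows sum to 1)."""
    resp, _ = _estep(
        np.asarray(X, dtype=float), params.weights, params.means, params.covariances
    )
    return resp


def loglikelihood(X, params: GMMParams) -> float:
    _, ll = _estep(
        np.asarray(X, dtype=float), params.weights, params.means, params.covariances
    )
    return ll


# ---------------------------------------------------------------------------
# M step per covariance family


def _mstep_cov(model: str, W: np.ndarray, nk: np.ndarray, n: int) -> np.ndarray:
    """Covariance update from component scatter matrices W (K, 2, 2)."""
    K = len(nk)
    d = 2
    eye = np.eye(d)
    if model == "VVV":
        return W / nk[:, None, None]
    if model == "EEE":
        shared = W.sum(axis=0) / n
        return np.repeat(shared[None], K, axis=0)
    if model == "VVI":
        out = np.zeros_like(W)
        out[:, 0, 0] = W[:, 0, 0] / nk
        out[:, 1, 1] = W[:, 1, 1] / nk
        return out
    if model == "EEI":
        diag = W.sum(axis=0)
        out = np.zeros_like(W)
        out[:, 0, 0] = diag[0, 0] / n
        out[:, 1, 1] = diag[1, 1] / n
        return out
    if model == "EII":
        lam = np.trace(W.sum(axis=0)) / (n * d)
        return np.repeat((lam * eye)[None], K, axis=0)
    if model == "VII":
        lam = np.trace(W, axis1=1, axis2=2) / (nk * d)
        return lam[:, None, None] * eye[None]
    if model == "EVI":
        diags = np.stack([W[:, 0, 0], W[:, 1, 1]], axis=1)  # (K, 2)
        dets = np.prod(diags, axis=1) ** (1.0 / d)
        dets = np.maximum(dets, 1e-300)
        B = diags / dets[:, None]  # det-1 shapes
        lam = dets.sum() / n
        out = np.zeros_like(W)
        out[:, 0, 0] = lam * B[:, 0]
        out[:, 1, 1] = lam * B[:, 1]
        return out
    if model == "VEI":
        diags = np.stack([W[:, 0, 0], W[:, 1, 1]], axis=1)
        lam = np.trace(W, axis1=1, axis2=2) / (nk * d)  # init from VII
        B = np.ones(d)
        for _ in range(30):
            Bnew = (diags / lam[:, None]).sum(axis=0)
            Bnew = Bnew / np.maximum(np.prod(Bnew), 1e-300) ** (1.0 / d)
            lam_new = (diags / Bnew[None, :]).sum(axis=1) / (nk * d)
            if np.allclose(Bnew, B, rtol=1e-10) and np.allclose(
                lam_new, lam, rtol=1e-10
            ):
                B, lam = Bnew, lam_new
                break
            B, lam = Bnew, lam_new
        out = np.zeros_like(W)
        out[:, 0, 0] = lam * B[0]
        out[:, 1, 1] = lam * B[1]
        return out
    raise ConfigError(f"unsupported covariance model {model!r}")


# ---------------------------------------------------------------------------
# initialization and the EM driver


def _kmeanspp_centers(X, K, rng):
    n = len(X)
    centers = [X[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(
            [np.sum((X - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _initial_resp(X, K, rng):
    centers = _kmeanspp_centers(X, K, rng)
    d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
    resp = np.zeros((len(X), K))
    resp[np.arange(len(X)), np.argmin(d2, axis=1)] = 1.0
    # soften slightly so empty components still receive mass
    resp = resp * 0.95 + 0.05 / K
    return resp


def _single_em(X, K, model, config: FitConfig, rng):
    n = len(X)
    var_floor = config.floor_factor * X.var(axis=0)
    var_floor = np.maximum(var_floor, 1e-300)
    resp = _initial_resp(X, K, rng)
    weights = means = covs = None
    ll = -np.inf
    trace = []
    for it in range(config.max_iter):
        nk = resp.sum(axis=0)
        if np.any(nk < 1.0 / 10.0) and it > 0:
            raise FloatingPointError("component collapsed (empty)")
        means = (resp.T @ X) / nk[:, None]
        diff = X[:, None, :] - means[None]
        W = np.einsum("nk,nki,nkj->kij", resp, diff, diff)
        with np.errstate(invalid="ignore", divide="ignore"):
            covs = _mstep_cov(model, W, nk, n)
        if not np.all(np.isfinite(covs)):
            raise FloatingPointError("non-finite covariance update")
        if np.any(covs[:, 0, 0] < var_floor[0]) or np.any(
            covs[:, 1, 1] < var_floor[1]
        ):
            raise FloatingPointError("component collapsed (variance floor)")
        weights = nk / n
        if np.any(weights < 1.0 / (10.0 * n)):
            raise FloatingPointError("component weight collapsed")
        resp, ll_new = _estep(X, weights, means, covs)
        if not np.isfinite(ll_new):
            raise FloatingPointError("non-finite log-likelihood")
        trace.append(ll_new)
        if it > 0 and abs(ll_new - ll) <= config.tol * abs(ll_new):
            ll = ll_new
            break
        ll = ll_new
    return GMMParams(
        model=model, K=K, weights=weights, means=means, covariances=covs,
        loglik=ll, n=n, loglik_trace=trace,
    )


def em_fit(X, K: int, model: str, config: FitConfig = FitConfig(),
           rng: np.random.Generator | None = None) -> GMMParams:
    """Best-of-restarts EM fit of a K-component mixture under one family."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValidationError("em_fit expects an (n, 2) observation matrix")
    n = len(X)
    if n < 2:
        raise ValidationError("em_fit needs at least 2 observations")
    nu = count_free_params(model, K)
    if n <= nu:
        warnings.warn(
            f"fitting {model} with K={K} ({nu} parameters) on only {n} points",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    best = None
    failures = []
    for r in range(max(1, config.restarts)):
        try:
            fit = _single_em(X, K, model, config, rng)
        except FloatingPointError as exc:
            failures.append(str(exc))
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise FitError(
            f"all {config.restarts} restarts failed for {model}, K={K}: "
            f"{failures[-1] if failures else 'unknown'}"
        )
    return best


def _candidate_order_key(entry):
    # maximize BIC; break ties by smaller nu, then smaller K
    params = entry
    return (-params.bic, params.nu, params.K)


def select_model(X, config: FitConfig = FitConfig()) -> GMMParams:
    """Fit every (K, family) candidate and return the BIC maximizer.

    The returned parameters carry an ``audit`` list with one entry per
    attempted candidate: ``(model, K, loglik, nu, bic)`` or the failure
    message.
    """
    X = np.asarray(X, dtype=float)
    seeds = np.random.SeedSequence(config.seed).spawn(
        len(config.models) * len(config.k_range)
    )
    candidates: list[GMMParams] = []
    audit = []
    i = 0
    for model in config.models:
        for K in config.k_range:
            rng = np.random.default_rng(seeds[i])
            i += 1
            if count_free_params(model, K) >= len(X):
                audit.append((model, K, None, count_free_params(model, K), None,
                              "skipped: more parameters than observations"))
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = em_fit(X, K, model, config, rng=rng)
            except FitError as exc:
                audit.append((model, K, None, count_free_params(model, K), None,
                              str(exc)))
                continue
            audit.append((model, K, fit.loglik, fit.nu, fit.bic, "ok"))
            candidates.append(fit)
    if not candidates:
        raise FitError(
            "model selection failed for every candidate: "
            + "; ".join(f"{a[0]}/K={a[1]}: {a[5]}" for a in audit)
        )
    best = min(candidates, key=_candidate_order_key)
    best.audit = audit
    return best
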