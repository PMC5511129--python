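"""Conjugate-distribution primitives: Normal-Wishart, Wishart and
Beta-Bernoulli machinery underlying every evidence computation.

All Gaussians are parameterized by their *precision* matrix. The
Normal-Wishart density over a mean vector ``m`` and precision ``G`` of
dimension ``d`` is

    NW(m, G; nu, eta, mu, Lam)
        = KNW^-1 det(G)^{(nu-d)/2}
          exp(-[Tr(G Lam^-1) + eta (m-mu)^t G (m-mu)] / 2)

with normalizing constant

    KNW = (2 pi)^{d/2} 2^{nu d/2} eta^{-d/2} det(Lam)^{nu/2} gamma_d(nu/2)

where ``gamma_d`` is the multivariate gamma function.  KNW does not depend
on ``mu``.  The Wishart constant drops the ``(2 pi)^{d/2} eta^{-d/2}``
factors.  Marginal likelihoods of Gaussian data under these priors reduce
to ratios of such constants, which is what makes partition enumeration
affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, multigammaln

__all__ = [
    "NWParams",
    "WishartParams",
    "BetaPrior",
    "GroupStats",
    "nw_posterior",
    "log_knw",
    "log_kw",
    "log_beta_bernoulli",
    "chol_logdet",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_LOG_2 = float(np.log(2.0))


def chol_logdet(a: np.ndarray) -> float:
    """log det of a symmetric positive-definite matrix via Cholesky.

    A Cholesky failure on a theoretically-PD matrix is retried once with a
    diagonal jitter of ``1e-10 * trace / d``; a second failure raises.
    """
    a = np.asarray(a, dtype=float)
    d = a.shape[0]
    if d == 0:
        return 0.0
    try:
        chol = np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * float(np.trace(a)) / d
        try:
            chol = np.linalg.cholesky(a + jitter * np.eye(d))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                "matrix is not positive definite (even after jitter)"
            ) from exc
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def _as_spd(a: np.ndarray, name: str) -> np.ndarray:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    if a.size and not np.allclose(a, a.T, rtol=1e-8, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    return a


@dataclass(frozen=True)
class NWParams:
    """Normal-Wishart hyperparameters (nu, eta, mu, Lam) of dimension d.

    ``nu`` must exceed ``d - 1`` (Wishart validity), ``eta`` must be
    positive and ``lam`` symmetric positive definite.
    """

    nu: float
    eta: float
    mu: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        lam = _as_spd(self.lam, "lam")
        if lam.shape[0] != mu.shape[0]:
            raise ValueError("mu and lam dimensions differ")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.nu <= mu.shape[0] - 1:
            raise ValueError(f"nu must exceed d - 1 = {mu.shape[0] - 1}")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "lam", lam)

    @property
    def dim(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class WishartParams:
    """Wishart hyperparameters (nu_eps, lam_eps) for a noise precision."""

    nu_eps: float
    lam_eps: np.ndarray

    def __post_init__(self) -> None:
        lam = _as_spd(self.lam_eps, "lam_eps")
        if self.nu_eps <= lam.shape[0] - 1:
            raise ValueError(f"nu_eps must exceed d - 1 = {lam.shape[0] - 1}")
        object.__setattr__(self, "lam_eps", lam)

    @property
    def dim(self) -> int:
        return self.lam_eps.shape[0]


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior on the disease prevalence p."""

    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta parameters must be positive")


@dataclass(frozen=True)
class GroupStats:
    """Sufficient statistics of an index set: count, mean, covariance.

    ``rbar`` uses divisor ``n`` (not ``n - 1``): the evidence derivation
    writes the Gaussian exponent as ``n * rbar`` which requires the
    maximum-likelihood normalization.  Empty sets use the zero convention.
    """

    n: int
    xbar: np.ndarray = field(repr=False)
    rbar: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        xbar = np.atleast_1d(np.asarray(self.xbar, dtype=float))
        rbar = np.atleast_2d(np.asarray(self.rbar, dtype=float))
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if rbar.shape != (xbar.shape[0], xbar.shape[0]):
            raise ValueError("rbar shape inconsistent with xbar")
        object.__setattr__(self, "xbar", xbar)
        object.__setattr__(self, "rbar", rbar)

    @property
    def dim(self) -> int:
        return self.xbar.shape[0]

    @classmethod
    def from_samples(cls, x: np.ndarray, d: int | None = None) -> "GroupStats":
        """Statistics of columns of ``x`` (shape ``d x n``); n may be 0."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if d is None:
            d = x.shape[0]
        n = x.shape[1]
        if n == 0:
            return cls(0, np.zeros(d), np.zeros((d, d)))
        xbar = x.mean(axis=1)
        centered = x - xbar[:, None]
        rbar = (centered @ centered.T) / n
        return cls(n, xbar, rbar)

    def restrict(self, idx: np.ndarray) -> "GroupStats":
        """Slice to the coordinate subset ``idx`` (rows/columns removal)."""
        idx = np.asarray(idx)
        return GroupStats(self.n, self.xbar[idx], self.rbar[np.ix_(idx, idx)])


def nw_posterior(prior: NWParams, stats: GroupStats) -> NWParams:
    """Conjugate Normal-Wishart update from group sufficient statistics.

    nu' = nu + n,  eta' = eta + n,
    mu' = (n xbar + eta mu) / (n + eta),
    Lam'^-1 = Lam^-1 + n rbar + n eta (mu - xbar)(mu - xbar)^t / (n + eta).
    """
    if stats.dim != prior.dim:
        raise ValueError(
            f"stats dimension {stats.dim} != prior dimension {prior.dim}"
        )
    n = stats.n
    if n == 0:
        return prior
    eta = prior.eta
    mu_pst = (n * stats.xbar + eta * prior.mu) / (n + eta)
    diff = prior.mu - stats.xbar
    lam_inv = (
        np.linalg.inv(prior.lam)
        + n * stats.rbar
        + (n * eta / (n + eta)) * np.outer(diff, diff)
    )
    lam_pst = np.linalg.inv(lam_inv)
    lam_pst = 0.5 * (lam_pst + lam_pst.T)
    return NWParams(prior.nu + n, eta + n, mu_pst, lam_pst)


def log_knw(params: NWParams, d: int | None = None) -> float:
    """Log normalizing constant of the Normal-Wishart density.

    log KNW = (d/2) log 2pi + (nu d/2) log 2 - (d/2) log eta
              + (nu/2) log det Lam + log gamma_d(nu/2).

    A zero-dimensional parameter set contributes log KNW = 0 (empty
    protein subset convention).
    """
    if d is None:
        d = params.dim
    elif d != params.dim:
        raise ValueError(f"params have dimension {params.dim}, not {d}")
    if d == 0:
        return 0.0
    return (
        0.5 * d * _LOG_2PI
        + 0.5 * params.nu * d * _LOG_2
        - 0.5 * d * np.log(params.eta)
        + 0.5 * params.nu * chol_logdet(params.lam)
        + multigammaln(0.5 * params.nu, d)
    )


def log_kw(params: WishartParams, d: int | None = None) -> float:
    """Log normalizing constant of the Wishart density.

    log KW = (nu d/2) log 2 + (nu/2) log det Lam + log gamma_d(nu/2).
    """
    if d is None:
        d = params.dim
    elif d != params.dim:
        raise ValueError(f"params have dimension {params.dim}, not {d}")
    if d == 0:
        return 0.0
    return (
        0.5 * params.nu_eps * d * _LOG_2
        + 0.5 * params.nu_eps * chol_logdet(params.lam_eps)
        + multigammaln(0.5 * params.nu_eps, d)
    )


def log_beta_bernoulli(prior: BetaPrior, n_path: int, n_healthy: int) -> float:
    """Log marginal probability of status counts under a Beta prior.

    Integrates p^n_path (1-p)^n_healthy against Beta(a, b):
    log [B(a + n_path, b + n_healthy) / B(a, b)].
    """
    if n_path < 0 or n_healthy < 0:
        raise ValueError("counts must be >= 0")
    return float(
        betaln(prior.a + n_path, prior.b + n_healthy) - betaln(prior.a, prior.b)
    )
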