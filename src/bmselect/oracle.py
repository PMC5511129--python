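"""Brute-force Monte-Carlo marginalization of the evidence.

Independent validation route for the closed-form evidences: draw the
model parameters from their priors and average the exact conditional
likelihood of the observed data.  For the noisy model the latent true
concentrations are integrated analytically per draw (y_n given the
parameters is Gaussian with covariance blkdiag(G_g^-1, G_C^-1) + G_eps^-1),
so only (p, m_x, G_x, G_eps) are sampled.

Deliberately simple and slow; intended for small instances (P <= 3,
N <= 10).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import wishart

from .conjugate import GroupStats, NWParams
from .data import Dataset, Partition, group_stats
from .evidence import ModelPriors

__all__ = ["mc_evidence_oracle"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _sample_nw(nw: NWParams, size: int, rng) -> tuple:
    """Draws (G, m) from the Normal-Wishart prior, shapes (S,d,d), (S,d)."""
    d = nw.dim
    gammas = wishart.rvs(df=nw.nu, scale=nw.lam, size=size, random_state=rng)
    gammas = np.asarray(gammas, dtype=float).reshape(size, d, d)
    # m | G ~ N(mu, (eta G)^-1): with eta G = L L^t, m = mu + L^-t z.
    chols = np.linalg.cholesky(nw.eta * gammas)
    z = rng.standard_normal((size, d))
    ms = nw.mu + np.linalg.solve(np.transpose(chols, (0, 2, 1)), z[..., None])[..., 0]
    return gammas, ms


def _gauss_group_loglik(
    gammas: np.ndarray, ms: np.ndarray, stats: GroupStats
) -> np.ndarray:
    """Per-draw log prod_{n in set} N(x_n; m, G^-1) from sufficient
    statistics (precision parameterization)."""
    size, d = ms.shape
    if stats.n == 0 or d == 0:
        return np.zeros(size)
    _, logdets = np.linalg.slogdet(gammas)
    tr = np.einsum("sij,ji->s", gammas, stats.rbar)
    dm = stats.xbar - ms
    quad = np.einsum("si,sij,sj->s", dm, gammas, dm)
    return 0.5 * stats.n * (logdets - d * _LOG_2PI - tr - quad)


def _status_loglik(ps: np.ndarray, n_path: int, n_healthy: int) -> np.ndarray:
    out = np.zeros(ps.shape)
    if n_path:
        out += n_path * np.log(ps)
    if n_healthy:
        out += n_healthy * np.log1p(-ps)
    return out


def _logmeanexp_with_se(ll: np.ndarray) -> tuple:
    shift = ll.max() if ll.size else 0.0
    w = np.exp(ll - shift)
    mean_w = w.mean()
    est = shift + np.log(mean_w)
    if ll.size > 1:
        se = w.std(ddof=1) / (np.sqrt(ll.size) * mean_w)
    else:
        se = np.inf
    return float(est), float(se)


def mc_evidence_oracle(
    dataset: Dataset,
    partition: Partition,
    priors: ModelPriors,
    model: str = "noiseless",
    n_samples: int = 100_000,
    seed=None,
) -> tuple:
    """Monte-Carlo estimate of the log evidence with its standard error.

    Returns
    -------
    (log_evidence_estimate, mc_std_error)
        The standard error is the delta-method error of the log of the
        sample mean of likelihoods.
    """
    if model not in ("noiseless", "noisy"):
        raise ValueError("model must be 'noiseless' or 'noisy'")
    priors.check_partition(partition)
    rng = np.random.default_rng(seed)
    stats_p = group_stats(dataset, "pathological")
    stats_h = group_stats(dataset, "healthy")
    stats_c = group_stats(dataset, "all")
    plus = np.nonzero(partition.mask)[0]
    minus = np.nonzero(~partition.mask)[0]
    s = int(n_samples)

    ps = rng.beta(priors.beta.a, priors.beta.b, size=s)
    ll = _status_loglik(ps, stats_p.n, stats_h.n)

    if model == "noiseless":
        for nw, stats, idx in (
            (priors.nw_path, stats_p, plus),
            (priors.nw_healthy, stats_h, plus),
            (priors.nw_common, stats_c, minus),
        ):
            if idx.size == 0:
                continue
            gammas, ms = _sample_nw(nw, s, rng)
            ll += _gauss_group_loglik(gammas, ms, stats.restrict(idx))
        return _logmeanexp_with_se(ll)

    if priors.noise is None:
        raise ValueError("noisy model requires a noise Wishart prior")
    p = dataset.n_proteins
    noise = wishart.rvs(
        df=priors.noise.nu_eps, scale=priors.noise.lam_eps, size=s,
        random_state=rng,
    )
    noise_cov = np.linalg.inv(np.asarray(noise, dtype=float).reshape(s, p, p))

    cov_common = np.zeros((s, p, p))
    m_stack = {"path": np.zeros((s, p)), "healthy": np.zeros((s, p))}
    if minus.size:
        g_c, m_c = _sample_nw(priors.nw_common, s, rng)
        cov_common[np.ix_(range(s), minus, minus)] = np.linalg.inv(g_c)
        m_stack["path"][:, minus] = m_c
        m_stack["healthy"][:, minus] = m_c
    group_cov = {}
    for key, nw in (("path", priors.nw_path), ("healthy", priors.nw_healthy)):
        cov = cov_common.copy()
        if plus.size:
            g_g, m_g = _sample_nw(nw, s, rng)
            cov[np.ix_(range(s), plus, plus)] = np.linalg.inv(g_g)
            m_stack[key][:, plus] = m_g
        group_cov[key] = cov + noise_cov

    for key, stats in (("path", stats_p), ("healthy", stats_h)):
        if stats.n == 0:
            continue
        cov = group_cov[key]
        _, logdets = np.linalg.slogdet(cov)
        inv = np.linalg.inv(cov)
        tr = np.einsum("sij,ji->s", inv, stats.rbar)
        dm = stats.xbar - m_stack[key]
        quad = np.einsum("si,sij,sj->s", dm, inv, dm)
        ll += -0.5 * stats.n * (p * _LOG_2PI + logdets + tr + quad)
    return _logmeanexp_with_se(ll)
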