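"""Synthetic-cohort generator and the selection-error benchmark.

The generator reproduces the benchmark protocol of the study conditions:

* prevalence p ~ Beta(a, b) (default Beta(1, 1), i.e. uniform),
* statuses ~ Bernoulli(p),
* per-group (m, G) ~ Normal-Wishart, moment matched to
  E(m) = 1e3 * 1, V(m) = 1e4 * I, E(G) = 1e3 * I, V(G) = 1e4 * I,
* concentrations multivariate Gaussian (precision parameterization),
* optional additive zero-mean Gaussian noise whose precision is itself
  Wishart distributed, matched to E(G_eps) = 1e-2 * I, V(G_eps) = 1e-5 * I.

The benchmark draws ``n_reps`` cohorts per true partition, runs each
selector, and counts a decision as an error whenever the selected
partition differs from the true one as a whole vector.  The error rate is

    tau (%) = 100 * sum_i E_i / (n_reps * n_truths).

Baselines with a free parameter (t test alpha, lasso penalty,
Bhattacharyya threshold) are swept over a grid and the best (lowest)
error rate is reported, mirroring the benchmark's best-version-of-the-
competitor protocol.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conjugate import BetaPrior, NWParams, WishartParams
from .data import Dataset, Partition, all_partitions, partitions_with_m
from .evidence import EvidenceEngine
from .priors import (
    MomentSpec,
    PriorConfig,
    SIMULATION_MOMENTS,
    SIMULATION_NOISE_MOMENTS,
    moment_match_nw,
    moment_match_wishart,
)

__all__ = [
    "SimConfig",
    "BenchResult",
    "sample_wishart",
    "simulate_dataset",
    "run_benchmark",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_LAMBDA_GRID",
]

#: Type-I-error sweep for the t test (15 points, log spaced).
DEFAULT_ALPHA_GRID = tuple(np.geomspace(1e-4, 0.5, 15))
#: Lasso penalty sweep (20 points, log spaced).
DEFAULT_LAMBDA_GRID = tuple(np.geomspace(1e-4, 1.0, 20))


def sample_wishart(rng, nu: float, scale_chol: np.ndarray) -> np.ndarray:
    """One Wishart(nu, scale) draw via the Bartlett decomposition.

    ``scale_chol`` is the lower Cholesky factor of the scale matrix.
    Kept in-package because the benchmark draws millions of small
    matrices and per-call overhead dominates; cross-checked against
    scipy.stats.wishart in the test suite.
    """
    d = scale_chol.shape[0]
    a = np.zeros((d, d))
    idx = np.tril_indices(d, -1)
    a[idx] = rng.standard_normal(idx[0].size)
    a[np.diag_indices(d)] = np.sqrt(
        rng.chisquare(nu - np.arange(d))
    )
    la = scale_chol @ a
    return la @ la.T


def _sample_nw_params(rng, nw: NWParams) -> tuple:
    """One (m, G) draw from a Normal-Wishart prior; returns (m, chol(G))."""
    scale_chol = np.linalg.cholesky(nw.lam)
    gamma = sample_wishart(rng, nw.nu, scale_chol)
    chol_g = np.linalg.cholesky(gamma)
    z = rng.standard_normal(nw.dim)
    m = nw.mu + np.linalg.solve(chol_g.T, z) / np.sqrt(nw.eta)
    return m, chol_g


def _gaussian_from_precision_chol(rng, m, chol_g, n: int) -> np.ndarray:
    """n column draws from N(m, G^-1) given chol(G); shape (d, n)."""
    z = rng.standard_normal((chol_g.shape[0], n))
    return m[:, None] + np.linalg.solve(chol_g.T, z)


@dataclass(frozen=True)
class SimConfig:
    """Benchmark configuration.

    Parameters
    ----------
    n_proteins, n_individuals : int
        P and N of every generated cohort.
    n_reps : int
        Cohort realizations per true partition.
    moments : MomentSpec
        Concentration prior moments (generation and, matched, inference).
    noise_moments : MomentSpec or None
        When set, noisy cohorts y = x + eps are generated and the noisy
        selectors become available.
    fixed_m : int or None
        Restrict truths and candidates to partitions with exactly M
        discriminant proteins (C(P, M) models instead of 2^P).
    n_truths : int or None
        Subsample this many true partitions uniformly from the candidate
        set (the protocol is exchangeable over equal-size partitions, so
        per-truth error probabilities coincide in expectation).
    seed : int
        Master seed; one independent stream is spawned per
        (true partition, repetition).
    """

    n_proteins: int
    n_individuals: int
    n_reps: int = 1000
    moments: MomentSpec = SIMULATION_MOMENTS
    noise_moments: MomentSpec | None = None
    beta: BetaPrior = BetaPrior(1.0, 1.0)
    fixed_m: int | None = None
    n_truths: int | None = None
    seed: int = 0
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    bha_quantiles: tuple = tuple(np.linspace(0.05, 0.95, 15))
    bha_pilot_reps: int = 50

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_individuals < 1:
            raise ValueError("need n_proteins >= 1 and n_individuals >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.fixed_m is not None and not (0 <= self.fixed_m <= self.n_proteins):
            raise ValueError("need 0 <= fixed_m <= n_proteins")

    @property
    def prior_config(self) -> PriorConfig:
        return PriorConfig(self.moments, self.beta, self.noise_moments)

    def candidate_partitions(self) -> list:
        if self.fixed_m is None:
            return all_partitions(self.n_proteins)
        return partitions_with_m(self.n_proteins, self.fixed_m)


def simulate_dataset(
    true_partition: Partition,
    config: SimConfig,
    rng,
) -> tuple:
    """One synthetic cohort under ``true_partition``.

    Returns ``(dataset, noisy_dataset)``; ``noisy_dataset`` is None when
    no noise moments are configured.
    """
    p = config.n_proteins
    n = config.n_individuals
    if true_partition.n_proteins != p:
        raise ValueError("partition size != configured protein count")
    prevalence = rng.beta(config.beta.a, config.beta.b)
    is_path = rng.random(n) < prevalence
    statuses = np.where(is_path, "P", "H")
    x = np.empty((p, n))
    plus = np.nonzero(true_partition.mask)[0]
    minus = np.nonzero(~true_partition.mask)[0]
    if plus.size:
        nw = moment_match_nw(config.moments, plus.size)
        m_h, chol_h = _sample_nw_params(rng, nw)
        m_p, chol_p = _sample_nw_params(rng, nw)
        n_path = int(is_path.sum())
        x[np.ix_(plus, np.nonzero(is_path)[0])] = _gaussian_from_precision_chol(
            rng, m_p, chol_p, n_path
        )
        x[np.ix_(plus, np.nonzero(~is_path)[0])] = _gaussian_from_precision_chol(
            rng, m_h, chol_h, n - n_path
        )
    if minus.size:
        nw = moment_match_nw(config.moments, minus.size)
        m_c, chol_c = _sample_nw_params(rng, nw)
        x[minus] = _gaussian_from_precision_chol(rng, m_c, chol_c, n)
    dataset = Dataset(x, statuses)
    if config.noise_moments is None:
        return dataset, None
    wish = moment_match_wishart(config.noise_moments, p)
    gamma_eps = sample_wishart(
        rng, wish.nu_eps, np.linalg.cholesky(wish.lam_eps)
    )
    chol_eps = np.linalg.cholesky(gamma_eps)
    eps = np.linalg.solve(chol_eps.T, rng.standard_normal((p, n)))
    return dataset, Dataset(x + eps, statuses)


@dataclass
class BenchResult:
    """Benchmark outcome: error rate per method (best grid point for
    parametric baselines), per-truth error counts, and the full grids."""

    tau: dict
    errors_by_truth: dict
    n_reps: int
    n_truths: int
    n_candidates: int
    grids: dict = field(default_factory=dict)
    runtime_seconds: float = 0.0
    config: SimConfig | None = None

    @property
    def n_decisions(self) -> int:
        return self.n_reps * self.n_truths

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"method": m, "tau_percent": t, "n_decisions": self.n_decisions}
            for m, t in self.tau.items()
        ]
        return pd.DataFrame(rows)


def _registered_methods():
    # Imported lazily: selectors pulls in scikit-learn.
    from . import selectors as sel

    return {
        "bms_as_d": sel._bench_bms_d,
        "bms_as_n": sel._bench_bms_n,
        "ttest": sel._bench_ttest,
        "lasso": sel._bench_lasso,
        "bha": sel._bench_bha,
        "fohsic": sel._bench_fohsic,
    }


def run_benchmark(config: SimConfig, methods=("bms_as_d",)) -> BenchResult:
    """Monte-Carlo selection-error benchmark.

    For every true partition in the candidate set, ``config.n_reps``
    cohorts are generated; every requested selector picks a partition and
    an error is counted when the whole selected mask differs from the
    truth.  Returns per-method error rates tau (%).
    """
    registry = _registered_methods()
    unknown = [m for m in methods if m not in registry]
    if unknown:
        raise ValueError(
            f"unknown method(s) {unknown}; registered: {sorted(registry)}"
        )
    if "fohsic" in methods and config.fixed_m is None:
        raise ValueError("fohsic needs fixed_m (its biomarker count)")
    if "bms_as_n" in methods and config.noise_moments is None:
        raise ValueError("bms_as_n needs noise_moments in the configuration")

    t0 = time.perf_counter()
    candidates = config.candidate_partitions()
    master = np.random.SeedSequence(config.seed)
    truth_indices = np.arange(len(candidates))
    if config.n_truths is not None and config.n_truths < len(candidates):
        pick_rng = np.random.default_rng(master.spawn(1)[0])
        truth_indices = np.sort(
            pick_rng.choice(len(candidates), size=config.n_truths, replace=False)
        )
    truths = [candidates[i] for i in truth_indices]

    # Parametric baselines accumulate errors on their whole grid; the
    # best grid point is reported.
    grid_sizes = {
        "ttest": len(config.alpha_grid),
        "lasso": len(config.lambda_grid),
        "bha": len(config.bha_quantiles),
    }
    errors = {
        m: np.zeros((len(truths), grid_sizes.get(m, 1)), dtype=np.int64)
        for m in methods
    }

    bha_thresholds = None
    if "bha" in methods:
        bha_thresholds = _bha_threshold_grid(config, truths, master)

    state = {"config": config, "candidates": candidates}
    for ti, truth in enumerate(truths):
        streams = master.spawn(config.n_reps)
        for rep in range(config.n_reps):
            rng = np.random.default_rng(streams[rep])
            clean, noisy = simulate_dataset(truth, config, rng)
            observed = noisy if noisy is not None else clean
            state["clean"] = clean
            state["observed"] = observed
            state["engines"] = {}
            for m in methods:
                picked = registry[m](state, bha_thresholds=bha_thresholds)
                # picked: boolean mask (grid, P) or (P,)
                picked = np.atleast_2d(picked)
                errs = np.any(picked != truth.mask[None, :], axis=1)
                errors[m][ti] += errs

    n_dec = config.n_reps * len(truths)
    tau = {}
    grids = {}
    for m in methods:
        per_grid = errors[m].sum(axis=0) / n_dec * 100.0
        if m in grid_sizes:
            grid_vals = {
                "ttest": config.alpha_grid,
                "lasso": config.lambda_grid,
                "bha": tuple(bha_thresholds) if bha_thresholds is not None else (),
            }[m]
            grids[m] = pd.DataFrame(
                {"parameter": list(grid_vals), "tau_percent": per_grid}
            )
            tau[m] = float(per_grid.min())
        else:
            tau[m] = float(per_grid[0])
    return BenchResult(
        tau=tau,
        errors_by_truth={m: errors[m] for m in methods},
        n_reps=config.n_reps,
        n_truths=len(truths),
        n_candidates=len(candidates),
        grids=grids,
        runtime_seconds=time.perf_counter() - t0,
        config=config,
    )


def _bha_threshold_grid(config: SimConfig, truths, master) -> np.ndarray:
    """Threshold sweep for the Bhattacharyya selector: quantiles of the
    per-protein distances observed on a small pilot set of cohorts."""
    from .selectors import bhattacharyya_distances

    rng = np.random.default_rng(master.spawn(1)[0])
    pilot = min(config.bha_pilot_reps, config.n_reps * len(truths))
    dists = []
    for i in range(pilot):
        truth = truths[i % len(truths)]
        clean, noisy = simulate_dataset(truth, config, rng)
        ds = noisy if noisy is not None else clean
        if min(ds.n_pathological, ds.n_healthy) >= 2:
            dists.append(bhattacharyya_distances(ds))
    if not dists:
        return np.asarray([0.0])
    pooled = np.concatenate(dists)
    pooled = pooled[np.isfinite(pooled)]
    return np.unique(np.quantile(pooled, config.bha_quantiles))
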