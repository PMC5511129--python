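"""Feature (biomarker) selectors with a scikit-learn estimator surface.

:class:`BayesPartitionSelector` is the package's method: it enumerates
candidate discriminant/non-discriminant partitions, computes each
partition's marginal likelihood in closed form and keeps the MAP
partition.  The remaining selectors are the comparison baselines of the
benchmark (per-protein t test, linear lasso, per-protein Bhattacharyya
distance, forward HSIC selection).

All selectors implement ``fit(X, y)`` with ``X`` of shape
``(n_samples, n_features)`` and binary ``y`` (1 or "P" = pathological),
expose the selected mask through ``get_support()`` and subset columns
with ``transform``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .conjugate import BetaPrior
from .data import Dataset, Partition, all_partitions, partitions_with_m
from .evidence import EvidenceEngine, posterior_over_partitions
from .priors import MomentSpec, PriorConfig

__all__ = [
    "BayesPartitionSelector",
    "TTestSelector",
    "LassoSelector",
    "BhattacharyyaSelector",
    "ForwardHSICSelector",
    "ttest_select",
    "lasso_select",
    "bhattacharyya_select",
    "fohsic_select",
    "bhattacharyya_distances",
    "hsic_unbiased",
]


def _check_binary_y(y) -> np.ndarray:
    """Map y to a boolean pathological mask; accepts {0,1} or {H,P}."""
    y = np.asarray(y).ravel()
    if y.dtype.kind in "biuf":
        vals = set(np.unique(y).tolist())
        if not vals <= {0, 1, 0.0, 1.0}:
            raise ValueError(f"numeric y must be binary 0/1, got values {vals}")
        return y.astype(bool)
    vals = set(np.unique(y.astype(str)).tolist())
    if not vals <= {"H", "P"}:
        raise ValueError(f"string y must use labels 'H'/'P', got {vals}")
    return np.asarray(y).astype(str) == "P"


class _MaskSelector(SelectorMixin, BaseEstimator):
    """Shared plumbing: fitted boolean ``support_`` drives transform."""

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _validate_xy(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_2d=True)
        self.n_features_in_ = X.shape[1]
        return X, _check_binary_y(y)


class BayesPartitionSelector(_MaskSelector):
    """Exact Bayesian partition selection of discriminant proteins.

    Enumerates every candidate partition of the P features into a
    discriminant subset (whose Gaussian parameters depend on the status)
    and a non-discriminant subset (shared parameters), computes the
    marginal likelihood of each partition with all continuous parameters
    integrated out, and selects the a-posteriori most probable partition.
    Correlations between features are handled intrinsically because the
    decision is made on the feature set as a whole.

    Parameters
    ----------
    model : {"noiseless", "noisy"}
        Exact evidence for directly observed concentrations, or the
        Gaussian-approximated evidence for concentrations measured with
        additive noise of Wishart-distributed precision.
    mean_m, var_m, mean_gamma, var_gamma : float
        Expert orders of magnitude of the group mean and precision,
        moment matched into Normal-Wishart hyperparameters.  Defaults are
        the benchmark setting (concentrations of order 1e3 ug/ml).
    mean_gamma_eps, var_gamma_eps : float, optional
        Noise-precision moments (required for model="noisy").
    beta_a, beta_b : float
        Beta prior on the prevalence.
    n_biomarkers : int, optional
        Restrict candidates to partitions with exactly this many
        discriminant features (C(P, M) models instead of 2^P).
    partition_prior : array-like, optional
        Positive prior weights over the candidate partitions (hook for
        non-uniform priors, e.g. protein-protein-interaction knowledge).
    max_features_enumerated : int
        Guard on the enumeration size (2^P grows quickly); exceeding it
        raises with a suggestion to set ``n_biomarkers``.

    Attributes
    ----------
    support_ : bool array of shape (n_features,)
        MAP partition mask (ties broken towards the smallest bitmask).
    posterior_table_ : PosteriorTable
        Every candidate partition with log evidence and posterior
        probability (sums to one).
    map_posterior_ : float
        Posterior probability of the selected partition.
    """

    def __init__(
        self,
        model: str = "noiseless",
        mean_m: float = 1e3,
        var_m: float = 1e4,
        mean_gamma: float = 1e3,
        var_gamma: float = 1e4,
        mean_gamma_eps: float | None = None,
        var_gamma_eps: float | None = None,
        beta_a: float = 1.0,
        beta_b: float = 1.0,
        n_biomarkers: int | None = None,
        partition_prior=None,
        max_features_enumerated: int = 22,
    ):
        self.model = model
        self.mean_m = mean_m
        self.var_m = var_m
        self.mean_gamma = mean_gamma
        self.var_gamma = var_gamma
        self.mean_gamma_eps = mean_gamma_eps
        self.var_gamma_eps = var_gamma_eps
        self.beta_a = beta_a
        self.beta_b = beta_b
        self.n_biomarkers = n_biomarkers
        self.partition_prior = partition_prior
        self.max_features_enumerated = max_features_enumerated

    def _prior_config(self) -> PriorConfig:
        noise = None
        if self.model == "noisy":
            if self.mean_gamma_eps is None or self.var_gamma_eps is None:
                raise ValueError(
                    "model='noisy' requires mean_gamma_eps and var_gamma_eps"
                )
            noise = MomentSpec(
                mean_of_gamma=self.mean_gamma_eps,
                var_of_gamma=self.var_gamma_eps,
            )
        elif self.model != "noiseless":
            raise ValueError("model must be 'noiseless' or 'noisy'")
        moments = MomentSpec(
            mean_of_gamma=self.mean_gamma,
            var_of_gamma=self.var_gamma,
            mean_of_m=self.mean_m,
            var_of_m=self.var_m,
        )
        return PriorConfig(moments, BetaPrior(self.beta_a, self.beta_b), noise)

    def _candidates(self, p: int) -> list:
        if self.n_biomarkers is not None:
            return partitions_with_m(p, self.n_biomarkers)
        if p > self.max_features_enumerated:
            raise ValueError(
                f"enumerating 2^{p} partitions exceeds the cap of "
                f"2^{self.max_features_enumerated}; set n_biomarkers to "
                "restrict the candidate set (C(P, M) models)"
            )
        return all_partitions(p)

    def fit(self, X, y):
        X, is_path = self._validate_xy(X, y)
        dataset = Dataset.from_xy(X, is_path.astype(int))
        config = self._prior_config()
        candidates = self._candidates(dataset.n_proteins)
        table = posterior_over_partitions(
            dataset,
            candidates,
            config,
            partition_prior=self.partition_prior,
            model=self.model,
        )
        self.posterior_table_ = table
        self.partitions_ = table.partitions
        self.log_evidence_ = table.log_evidence
        self.posterior_probs_ = table.posterior
        idx = table.map_index
        self.support_ = table.partitions[idx].mask.copy()
        self.map_posterior_ = float(table.posterior[idx])
        return self


class TTestSelector(_MaskSelector):
    """Per-feature two-sided two-sample Student t test (pooled variance).

    A feature is selected when its p-value falls below ``alpha``.  No
    multiplicity correction is applied: in the benchmark ``alpha`` is
    swept and the best operating point reported.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X, is_path = self._validate_xy(X, y)
        pvals = ttest_pvalues(X, is_path)
        self.pvalues_ = pvals
        self.support_ = pvals < self.alpha
        return self


class LassoSelector(_MaskSelector):
    """Linear lasso regression of the 0/1 status on standardized
    concentrations; features with nonzero coefficients are selected."""

    def __init__(self, penalty: float = 0.01):
        self.penalty = penalty

    def fit(self, X, y):
        X, is_path = self._validate_xy(X, y)
        coefs = lasso_coefficients(X, is_path, [self.penalty])[0]
        self.coef_ = coefs
        self.support_ = coefs != 0.0
        return self


class BhattacharyyaSelector(_MaskSelector):
    """Per-feature Bhattacharyya distance between the two status groups
    (empirical Gaussian plug-in); selected when above ``threshold``."""

    def __init__(self, threshold: float = 0.5):
        self.threshold = threshold

    def fit(self, X, y):
        X, is_path = self._validate_xy(X, y)
        dataset = Dataset.from_xy(X, is_path.astype(int))
        self.distances_ = bhattacharyya_distances(dataset)
        self.support_ = self.distances_ > self.threshold
        return self


class ForwardHSICSelector(_MaskSelector):
    """Forward feature selection maximizing the unbiased HSIC estimate
    between the selected concentration block and the status vector.

    Gaussian kernel on concentrations with median-heuristic bandwidth,
    delta kernel on statuses.  The number of selected features is fixed a
    priori.  The kernel and bandwidth choices are this package's
    reconstruction of the forward-HSIC procedure.
    """

    def __init__(self, n_biomarkers: int = 1):
        self.n_biomarkers = n_biomarkers

    def fit(self, X, y):
        X, is_path = self._validate_xy(X, y)
        p = X.shape[1]
        if self.n_biomarkers > p:
            raise ValueError("n_biomarkers exceeds the number of features")
        self.support_ = _forward_hsic(X, is_path, self.n_biomarkers)
        return self


# ---------------------------------------------------------------------------
# Functional layer (thin wrappers + shared numerics)


def ttest_pvalues(X: np.ndarray, is_path: np.ndarray) -> np.ndarray:
    if is_path.all() or (~is_path).all():
        raise ValueError("t test requires both status groups to be non-empty")
    res = sps.ttest_ind(X[is_path], X[~is_path], axis=0, equal_var=True)
    return np.atleast_1d(np.asarray(res.pvalue))


def lasso_coefficients(X, is_path, penalties) -> np.ndarray:
    """Lasso coefficient vectors (len(penalties), P) on standardized X.

    The selection mask is read on the original feature ordering; a
    penalty of exactly zero falls back to ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(is_path, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0.0] = 1.0
    Xs = (X - mean) / std
    out = np.empty((len(penalties), X.shape[1]))
    for i, lam in enumerate(penalties):
        if lam == 0.0:
            model = LinearRegression().fit(Xs, y)
        else:
            model = Lasso(alpha=lam, max_iter=5000, tol=1e-6).fit(Xs, y)
        out[i] = model.coef_
    return out


def bhattacharyya_distances(dataset: Dataset) -> np.ndarray:
    """Univariate Bhattacharyya distance per protein:

        D_b = (mu1 - mu2)^2 / (8 sbar^2) + 0.5 log(sbar^2 / (s1 s2)),
        sbar^2 = (s1^2 + s2^2) / 2,

    with unbiased empirical means/variances.  When both group variances
    vanish, D_b is 0 for equal means and +inf otherwise.
    """
    is_path = dataset.pathological_mask
    if dataset.n_pathological < 2 or dataset.n_healthy < 2:
        raise ValueError("both groups need >= 2 individuals")
    x1 = dataset.concentrations[:, is_path]
    x2 = dataset.concentrations[:, ~is_path]
    mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    vbar = 0.5 * (v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mu1 - mu2) ** 2 / (8.0 * vbar) + 0.5 * np.log(
            vbar / np.sqrt(v1 * v2)
        )
    degenerate = vbar == 0.0
    if degenerate.any():
        d[degenerate] = np.where(
            np.isclose(mu1[degenerate], mu2[degenerate]), 0.0, np.inf
        )
    return d


def hsic_unbiased(K: np.ndarray, L: np.ndarray) -> float:
    """Unbiased HSIC estimator from two kernel matrices (n >= 4):

        HSIC = [tr(K~ L~) + 1'K~1 1'L~1 / ((n-1)(n-2)) - 2 1'K~L~1 / (n-2)]
               / (n (n-3))

    where K~, L~ are the kernel matrices with zeroed diagonals.
    """
    n = K.shape[0]
    if n < 4:
        raise ValueError("unbiased HSIC needs n >= 4")
    Kt = K - np.diag(np.diag(K))
    Lt = L - np.diag(np.diag(L))
    term1 = float(np.sum(Kt * Lt))
    term2 = float(Kt.sum() * Lt.sum()) / ((n - 1) * (n - 2))
    term3 = 2.0 * float(Kt.sum(axis=0) @ Lt.sum(axis=1)) / (n - 2)
    return (term1 + term2 - term3) / (n * (n - 3))


def _gaussian_kernel(X: np.ndarray) -> np.ndarray:
    """Gaussian kernel with median-heuristic bandwidth on rows of X."""
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    off = d2[np.triu_indices_from(d2, 1)]
    positive = off[off > 0]
    sigma2 = np.median(positive) if positive.size else 1.0
    return np.exp(-d2 / (2.0 * sigma2))


def _forward_hsic(X: np.ndarray, is_path: np.ndarray, m: int) -> np.ndarray:
    n, p = X.shape
    L = (is_path[:, None] == is_path[None, :]).astype(float)
    selected: list = []
    remaining = list(range(p))
    for _ in range(m):
        scores = []
        for j in remaining:
            K = _gaussian_kernel(X[:, selected + [j]])
            scores.append(hsic_unbiased(K, L))
        best = int(np.argmax(scores))  # ties -> smallest feature index
        selected.append(remaining.pop(best))
    mask = np.zeros(p, dtype=bool)
    mask[selected] = True
    return mask


def ttest_select(dataset: Dataset, alpha: float) -> Partition:
    """Per-protein pooled-variance t test; discriminant iff p < alpha."""
    is_path = dataset.pathological_mask
    return Partition(ttest_pvalues(dataset.concentrations.T, is_path) < alpha)


def lasso_select(dataset: Dataset, penalty: float) -> Partition:
    """Linear lasso of status on concentrations; nonzero-coefficient mask."""
    is_path = dataset.pathological_mask
    coefs = lasso_coefficients(dataset.concentrations.T, is_path, [penalty])[0]
    return Partition(coefs != 0.0)


def bhattacharyya_select(dataset: Dataset, threshold: float) -> Partition:
    """Univariate Bhattacharyya distance thresholding."""
    return Partition(bhattacharyya_distances(dataset) > threshold)


def fohsic_select(dataset: Dataset, n_biomarkers: int) -> Partition:
    """Greedy forward HSIC selection of a fixed number of biomarkers."""
    if n_biomarkers > dataset.n_proteins:
        raise ValueError("n_biomarkers exceeds the number of proteins")
    return Partition(
        _forward_hsic(
            dataset.concentrations.T, dataset.pathological_mask, n_biomarkers
        )
    )


# ---------------------------------------------------------------------------
# Benchmark hooks (called by simulate.run_benchmark).  Each returns either a
# (P,) mask or a (grid, P) stack of masks for parameter sweeps.


def _bench_engine(state, noisy: bool):
    key = "noisy" if noisy else "noiseless"
    if key not in state["engines"]:
        state["engines"][key] = EvidenceEngine(
            state["observed"], state["config"].prior_config, noisy=noisy
        )
    return state["engines"][key]


def _bench_bms_d(state, **kw):
    engine = _bench_engine(state, noisy=False)
    idx = engine.map_index(state["candidates"])
    return state["candidates"][idx].mask


def _bench_bms_n(state, **kw):
    engine = _bench_engine(state, noisy=True)
    idx = engine.map_index(state["candidates"])
    return state["candidates"][idx].mask


def _bench_ttest(state, **kw):
    ds = state["observed"]
    is_path = ds.pathological_mask
    if is_path.all() or (~is_path).all():
        # A single-status cohort carries no contrast; nothing is selected.
        p = ds.n_proteins
        return np.zeros((len(state["config"].alpha_grid), p), dtype=bool)
    pvals = ttest_pvalues(ds.concentrations.T, is_path)
    grid = np.asarray(state["config"].alpha_grid)
    return pvals[None, :] < grid[:, None]


def _bench_lasso(state, **kw):
    ds = state["observed"]
    coefs = lasso_coefficients(
        ds.concentrations.T, ds.pathological_mask, state["config"].lambda_grid
    )
    return coefs != 0.0


def _bench_bha(state, bha_thresholds=None, **kw):
    ds = state["observed"]
    grid = np.asarray(bha_thresholds)
    if min(ds.n_pathological, ds.n_healthy) < 2:
        return np.zeros((grid.size, ds.n_proteins), dtype=bool)
    d = bhattacharyya_distances(ds)
    return d[None, :] > grid[:, None]


def _bench_fohsic(state, **kw):
    ds = state["observed"]
    return _forward_hsic(
        ds.concentrations.T,
        ds.pathological_mask,
        state["config"].fixed_m,
    )
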