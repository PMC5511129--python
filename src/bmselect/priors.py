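"""Moment-matched hyperparameter elicitation.

Experts state orders of magnitude for the group mean vector ``m`` and
precision matrix ``G`` — E(m), V(m), E(G), V(G) — and these are inverted
into Normal-Wishart hyperparameters (nu, eta, mu, Lam) using the prior
moments

    E(G) = nu Lam,          E(m) = mu,
    V(m) = Lam^-1 / [eta (nu - d - 1)],
    cov(G_ij, G_kl) = nu (Lam_il Lam_jk + Lam_ik Lam_jl),

so that for isotropic targets (scalars g = E(G_ii), v = Var(G_ii),
vm = V(m_ii)):

    lam = v / (2 g),   nu = 2 g^2 / v,   eta = 1 / [lam * vm * (nu - d - 1)].

``nu`` and ``lam`` are dimension independent but ``eta`` is not, so
Normal-Wishart parameters are re-derived for every protein-subset
dimension encountered during partition enumeration.  The Wishart noise
prior is matched the same way without the mean equations.

Only isotropic (scalar-per-moment) specifications are supported: the
moment system is over-determined for general matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Real

import numpy as np
import yaml

from .conjugate import BetaPrior, NWParams, WishartParams

__all__ = [
    "MomentSpec",
    "moment_match_nw",
    "moment_match_wishart",
    "PriorConfig",
    "SIMULATION_MOMENTS",
    "SIMULATION_NOISE_MOMENTS",
]


def _scalar(value, name: str) -> float:
    if not isinstance(value, Real):
        raise ValueError(
            f"{name} must be a scalar: only isotropic moment specifications "
            "are supported (the moment system is over-determined otherwise)"
        )
    return float(value)


@dataclass(frozen=True)
class MomentSpec:
    """Isotropic prior moments for one group's (m, G) pair.

    ``mean_of_m`` may be omitted (None) for a pure precision spec such as
    the measurement-noise prior, where only E(G) and Var(G_ii) matter.
    """

    mean_of_gamma: float
    var_of_gamma: float
    mean_of_m: float | None = None
    var_of_m: float | None = None

    def __post_init__(self) -> None:
        g = _scalar(self.mean_of_gamma, "mean_of_gamma")
        v = _scalar(self.var_of_gamma, "var_of_gamma")
        if g <= 0:
            raise ValueError("mean_of_gamma must be > 0")
        if v <= 0:
            raise ValueError("var_of_gamma must be > 0")
        object.__setattr__(self, "mean_of_gamma", g)
        object.__setattr__(self, "var_of_gamma", v)
        if self.mean_of_m is not None:
            object.__setattr__(self, "mean_of_m", _scalar(self.mean_of_m, "mean_of_m"))
        if self.var_of_m is not None:
            vm = _scalar(self.var_of_m, "var_of_m")
            if vm <= 0:
                raise ValueError("var_of_m must be > 0")
            object.__setattr__(self, "var_of_m", vm)


#: The simulation-benchmark moment settings:
#: E(m) = 1e3, V(m) = 1e4, E(G) = 1e3 I, V(G) = 1e4 I.
SIMULATION_MOMENTS = MomentSpec(
    mean_of_gamma=1e3, var_of_gamma=1e4, mean_of_m=1e3, var_of_m=1e4
)

#: Reference noise-precision moments: E(G_eps) = 1e-2 I, V(G_eps) = 1e-5 I.
SIMULATION_NOISE_MOMENTS = MomentSpec(mean_of_gamma=1e-2, var_of_gamma=1e-5)


def moment_match_nw(spec: MomentSpec, dim: int) -> NWParams:
    """Normal-Wishart hyperparameters matching an isotropic moment spec
    at protein-subset dimension ``dim``."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if spec.mean_of_m is None or spec.var_of_m is None:
        raise ValueError("Normal-Wishart matching needs mean_of_m and var_of_m")
    g, v = spec.mean_of_gamma, spec.var_of_gamma
    lam = v / (2.0 * g)
    nu = g / lam  # = 2 g^2 / v
    if nu <= dim + 1:
        raise ValueError(
            f"matched nu = 2 E(G)^2 / V(G) = {nu:.4g} must exceed dim + 1 = "
            f"{dim + 1} for V(m) to be finite; decrease var_of_gamma or dim"
        )
    eta = 1.0 / (lam * spec.var_of_m * (nu - dim - 1.0))
    mu = np.full(dim, spec.mean_of_m)
    return NWParams(nu, eta, mu, lam * np.eye(dim))


def moment_match_wishart(spec: MomentSpec, dim: int) -> WishartParams:
    """Wishart noise-precision hyperparameters matching E(G_eps) and
    Var(G_eps_ii); requires nu_eps + 1 - dim > 0 for the downstream
    matrix-t -> Gaussian approximation."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    g, v = spec.mean_of_gamma, spec.var_of_gamma
    lam = v / (2.0 * g)
    nu = g / lam
    if nu + 1.0 - dim <= 0:
        raise ValueError(
            f"matched nu_eps = {nu:.4g} violates nu_eps + 1 - P > 0 for "
            f"P = {dim}; the Gaussian approximation of the noise marginal "
            "is invalid — use a smaller var_of_gamma (larger nu_eps)"
        )
    return WishartParams(nu, lam * np.eye(dim))


@dataclass(frozen=True)
class PriorConfig:
    """Complete prior specification: per-group moments, prevalence Beta
    prior and (optionally) noise-precision moments.

    The three concentration groups (pathological, healthy, common) share a
    single moment spec by default, as in the benchmark protocol.
    """

    moments: MomentSpec = SIMULATION_MOMENTS
    beta: BetaPrior = BetaPrior(1.0, 1.0)
    noise_moments: MomentSpec | None = None

    @classmethod
    def from_yaml(cls, path) -> "PriorConfig":
        """Load keys mean_m, var_m, mean_gamma, var_gamma
        [, mean_gamma_eps, var_gamma_eps, beta_a, beta_b]."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PriorConfig":
        required = ("mean_m", "var_m", "mean_gamma", "var_gamma")
        missing = [k for k in required if k not in raw]
        if missing:
            raise KeyError(
                f"prior configuration is missing required key(s): {missing}"
            )
        moments = MomentSpec(
            mean_of_gamma=raw["mean_gamma"],
            var_of_gamma=raw["var_gamma"],
            mean_of_m=raw["mean_m"],
            var_of_m=raw["var_m"],
        )
        noise = None
        if "mean_gamma_eps" in raw or "var_gamma_eps" in raw:
            if not ("mean_gamma_eps" in raw and "var_gamma_eps" in raw):
                raise KeyError(
                    "noise prior needs both mean_gamma_eps and var_gamma_eps"
                )
            noise = MomentSpec(
                mean_of_gamma=raw["mean_gamma_eps"],
                var_of_gamma=raw["var_gamma_eps"],
            )
        beta = BetaPrior(float(raw.get("beta_a", 1.0)), float(raw.get("beta_b", 1.0)))
        return cls(moments, beta, noise)

    def nw(self, dim: int) -> NWParams:
        return moment_match_nw(self.moments, dim)

    def noise_wishart(self, dim: int) -> WishartParams:
        if self.noise_moments is None:
            raise ValueError("no noise moments configured")
        return moment_match_wishart(self.noise_moments, dim)
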