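"""Pure likelihood components of the abundance-mediated interaction model.

These are the reference (readable, scipy-backed) forms of every density the
sampler uses: the Royle–Nichols site-level detection probability
``p = 1 - (1 - r)^N``, binomial/Bernoulli observation densities, Poisson
abundance and Bernoulli occupancy state densities, and linear predictors
with interaction terms ``gamma0*N + gamma1*N*x``.  The MCMC kernel has its
own compiled implementations; tests hold the two routes together.

Probabilities inside log-densities are clamped to [1e-12, 1 - 1e-12],
except the structural zeros (detection with N = 0 or z = 0), which are an
exact ``-inf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .config import ModelGraph

__all__ = [
    "SiteState",
    "Coefficients",
    "rn_detection_prob",
    "binomial_obs_loglik",
    "bernoulli_obs_loglik",
    "linear_predictor",
    "site_joint_loglik",
]

_EPS = 1e-12


@dataclass
class SiteState:
    """Latent state at one site: abundances N (per abundance-state species)
    and presences z (per occupancy-state species)."""

    N: dict = field(default_factory=dict)
    z: dict = field(default_factory=dict)

    def value_of(self, species: str) -> float:
        if species in self.N:
            n = self.N[species]
            if n < 0:
                raise ValueError(f"N[{species!r}] must be >= 0")
            return float(n)
        zv = self.z[species]
        if zv not in (0, 1):
            raise ValueError(f"z[{species!r}] must be binary")
        return float(zv)


@dataclass
class Coefficients:
    """Named regression/interaction coefficients on their link scales."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get(self, name: str, default: float = 0.0) -> float:
        return self.values.get(name, default)


def _clamp(p):
    return np.clip(p, _EPS, 1.0 - _EPS)


def rn_detection_prob(r: float, N: int) -> float:
    """Royle–Nichols site-level detection: 1 - (1 - r)^N.

    Probability that at least one of N independent individuals, each
    detected with probability r, is detected.  Zero when N = 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("individual detection probability r must be in [0, 1]")
    N = np.asarray(N)
    if np.any(N < 0):
        raise ValueError("abundance N must be >= 0")
    out = -np.expm1(np.log1p(-np.minimum(r, 1 - _EPS)) * N)
    out = np.where((r >= 1) & (N > 0), 1.0, out)
    return out if out.ndim else float(out)


def binomial_obs_loglik(y: int, K: int, p: float) -> float:
    """log Binomial(y | K, p) with exact -inf when p = 0 and y > 0."""
    if y < 0 or y > K:
        raise ValueError(f"count y={y} outside [0, K={K}]")
    if p == 0.0:
        return 0.0 if y == 0 else -np.inf
    if p == 1.0:
        return 0.0 if y == K else -np.inf
    return float(stats.binom.logpmf(y, K, _clamp(p)))


def bernoulli_obs_loglik(y: int, p: float, z: int) -> float:
    """log Bernoulli(y | p*z): detection conditional on presence; a
    detection at an unoccupied site (z = 0, y = 1) is impossible."""
    if y not in (0, 1) or z not in (0, 1):
        raise ValueError("y and z must be binary")
    if z == 0:
        return 0.0 if y == 0 else -np.inf
    p = float(_clamp(p))
    return float(np.log(p) if y == 1 else np.log1p(-p))


def interaction_contribution(term, coefs: Coefficients, row_covariates: dict,
                             upstream_states: SiteState, source_is_occupancy: bool) -> float:
    """gamma0 * f(N) + gamma1 * f(N) * x_mod, with f = identity for
    abundance-mediated edges and f = 1{.>0} for occupancy-mediated ones."""
    val = upstream_states.value_of(term.source_species)
    if term.occupancy_mediated or source_is_occupancy:
        val = 1.0 if val > 0 else 0.0
    g = coefs[term.gamma0_name]
    if term.modifier_covariate is not None:
        if term.modifier_covariate not in row_covariates:
            raise KeyError(f"missing modifier covariate {term.modifier_covariate!r}")
        g = g + coefs[term.gamma1_name] * row_covariates[term.modifier_covariate]
    return g * val


def linear_predictor(row_covariates: dict, coefs: Coefficients, params,
                     interactions=(), upstream_states: SiteState | None = None,
                     source_kinds: dict | None = None) -> float:
    """eta = beta0 + sum beta*x + sum over edges of (gamma0 + gamma1*x)*f(N).

    ``params`` is the ParamSpec list of one submodel (in index order);
    gamma entries are resolved through ``interactions``/``upstream_states``.
    """
    eta = 0.0
    for p in params:
        if p.kind == "intercept":
            eta += coefs[p.name]
        elif p.kind in ("covariate", "year"):
            if p.covariate not in row_covariates:
                raise KeyError(f"missing covariate {p.covariate!r}")
            eta += coefs[p.name] * row_covariates[p.covariate]
    for term in interactions:
        if upstream_states is None:
            raise KeyError("interaction terms need upstream states")
        occ_src = bool(source_kinds and source_kinds.get(term.source_species) == "occupancy")
        eta += interaction_contribution(term, coefs, row_covariates, upstream_states, occ_src)
    return float(eta)


def _bind_terms(graph: ModelGraph, sp, submodel: str):
    """Interaction terms of one submodel with their parameter names bound
    from the graph's parameter index."""
    from dataclasses import replace

    out = []
    for t in sp.incoming_interactions:
        if t.target_submodel != submodel:
            continue
        g0 = graph.interaction_param(t.source_species, sp.name, submodel, 0)
        g1 = (
            graph.interaction_param(t.source_species, sp.name, submodel, 1)
            if t.modifier_covariate is not None
            else None
        )
        out.append(replace(t, gamma0_name=g0, gamma1_name=g1))
    return out


def species_site_loglik(graph: ModelGraph, data, site: int, species: str,
                        states: SiteState, coefs: Coefficients) -> float:
    """State density plus all occasion-level observation terms for one
    species at one site (masked occasions contribute nothing)."""
    sp = graph.species_model(species)
    row = data.covariate_row(site)
    kinds = {s.name: s.state_variable for s in graph.species}
    eta_s = linear_predictor(
        row, coefs, graph.params_for(species, "state"),
        _bind_terms(graph, sp, "state"), states, kinds,
    )
    eta_d = linear_predictor(
        row, coefs, graph.params_for(species, "detection"),
        _bind_terms(graph, sp, "detection"), states, kinds,
    )
    mask = data.design.observed_mask[site]
    y_row = data.y[species][site]
    total = 0.0
    if sp.state_variable == "abundance":
        N = int(states.N[species])
        lam = float(np.exp(eta_s))
        total += float(stats.poisson.logpmf(N, lam))
        r = float(expit(eta_d))
        p_site = rn_detection_prob(r, N)
        K = data.design.n_subsamples
        for j in range(data.design.n_occasions):
            if not mask[j]:
                continue
            total += binomial_obs_loglik(int(y_row[j]), K, p_site)
    else:
        zv = int(states.z[species])
        psi = float(_clamp(expit(eta_s)))
        total += float(np.log(psi) if zv == 1 else np.log1p(-psi))
        p = float(expit(eta_d))
        for j in range(data.design.n_occasions):
            if not mask[j]:
                continue
            total += bernoulli_obs_loglik(min(int(y_row[j]), 1), p, zv)
    return total


def site_joint_loglik(site: int, states: SiteState, coefs: Coefficients,
                      data, graph: ModelGraph) -> float:
    """Joint log-density of all latent states and observations at one site:
    the product over species (topological order) of state and observation
    terms."""
    return float(
        sum(
            species_site_loglik(graph, data, site, s.name, states, coefs)
            for s in graph.species
        )
    )
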