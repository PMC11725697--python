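"""MCMC engine: model compilation, chain management, and fitting.

The sampler is Metropolis-within-Gibbs.  Latent abundances N (and
occupancy states z) are drawn from their exact full conditionals by
categorical draws over a truncated support; coefficients take adaptive
random-walk Metropolis steps with independent Normal(0, 2.5) priors on
the link scale.  Proposal scales adapt toward a 0.44 acceptance rate by
Robbins-Monro updates during burn-in only, so the post-burn-in kernel is
a fixed, valid MCMC kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .config import ConfigurationError, ModelGraph
from .data import DetectionData

__all__ = ["SamplerError", "McmcConfig", "CompiledModel", "compile_model",
           "run_chain", "fit", "gibbs_latent_draws"]

DEFAULT_PRIOR_SD = 2.5


class SamplerError(RuntimeError):
    pass


@dataclass(frozen=True)
class McmcConfig:
    """Chain lengths, truncation and adaptation settings.

    Defaults are the desk-scale preset (3 chains x 6,000 iterations,
    burn-in 1,000, thin 5 -> 3,000 retained draws); :meth:`paper` gives the
    long-run preset used for full replication.
    """

    n_chains: int = 3
    n_iterations: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    N_max: int = 30
    adapt_interval: int = 50
    target_accept: float = 0.44
    prior_sd: float = DEFAULT_PRIOR_SD

    def __post_init__(self):
        if self.n_chains < 1 or self.n_iterations < 1 or self.thin < 1:
            raise ConfigurationError("chains, iterations and thin must be positive")
        if self.burn_in < 0 or self.burn_in >= self.n_iterations:
            raise ConfigurationError("burn_in must be in [0, n_iterations)")
        if (self.n_iterations - self.burn_in) // self.thin < 100:
            raise ConfigurationError("need at least 100 retained draws per chain")
        if self.N_max < 1:
            raise ConfigurationError("N_max must be >= 1")

    @classmethod
    def paper(cls, seed: int = 0) -> "McmcConfig":
        """Three chains of 50,000 iterations, 20,000 burn-in, thin 18
        (about 5,000 retained draws in total)."""
        return cls(n_chains=3, n_iterations=50000, burn_in=20000, thin=18, seed=seed)

    @property
    def n_kept_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class CompiledModel:
    """ModelGraph + DetectionData lowered to the flat arrays the kernel uses."""

    graph: ModelGraph
    data: DetectionData
    parameter_names: list
    state_kind: np.ndarray
    Xs: np.ndarray
    nP: np.ndarray
    spar: np.ndarray
    Xd: np.ndarray
    nQ: np.ndarray
    dpar: np.ndarray
    e_src: np.ndarray
    e_tgt: np.ndarray
    e_sub: np.ndarray
    e_g0: np.ndarray
    e_g1: np.ndarray
    e_ind: np.ndarray
    e_mod: np.ndarray
    ins_ptr: np.ndarray
    ins_idx: np.ndarray
    ind_ptr: np.ndarray
    ind_idx: np.ndarray
    out_ptr: np.ndarray
    out_idx: np.ndarray
    Y: np.ndarray
    T: np.ndarray
    anydet: np.ndarray
    role_sp: np.ndarray
    role_sub: np.ndarray
    prior_sd: np.ndarray
    dcls: np.ndarray = None  # per-site data-equivalence class
    n_dcls: int = 0
    fast_ok: bool = False  # structure allows site-collapsed updates
    pair_a: np.ndarray = None  # joint ridge-move pairs: submodel intercept
    pair_b: np.ndarray = None  # ... and the edge's gamma0
    pair_sp: np.ndarray = None
    pair_sub: np.ndarray = None

    @property
    def n_par(self) -> int:
        return len(self.parameter_names)

    def kernel_args(self):
        return (
            self.state_kind, self.Xs, self.nP, self.spar, self.Xd, self.nQ, self.dpar,
            self.e_src, self.e_tgt, self.e_sub, self.e_g0, self.e_g1, self.e_ind, self.e_mod,
            self.ins_ptr, self.ins_idx, self.ind_ptr, self.ind_idx, self.out_ptr, self.out_idx,
            self.Y, self.T, self.anydet,
        )


def _csr(groups, S, E):
    ptr = np.zeros(S + 1, dtype=np.int64)
    for g in groups:
        ptr[g + 1] += 1
    ptr = np.cumsum(ptr)
    idx = np.empty(E, dtype=np.int64)
    fill = ptr[:-1].copy()
    for e, g in enumerate(groups):
        idx[fill[g]] = e
        fill[g] += 1
    return ptr.astype(np.int64), idx


def compile_model(graph: ModelGraph, data: DetectionData,
                  prior_sd: float | dict = DEFAULT_PRIOR_SD) -> CompiledModel:
    S = len(graph.species)
    I = data.design.n_sites
    names = graph.parameter_names
    pidx = {n: k for k, n in enumerate(names)}
    sp_index = {s.name: k for k, s in enumerate(graph.species)}

    state_kind = np.array(
        [0 if s.state_variable == "abundance" else 1 for s in graph.species],
        dtype=np.int64,
    )
    plain = {"intercept", "year", "covariate"}
    Xs_list, spar_list, Xd_list, dpar_list = [], [], [], []
    for s in graph.species:
        for sub, xl, pl in (("state", Xs_list, spar_list), ("detection", Xd_list, dpar_list)):
            ps = [p for p in graph.params_for(s.name, sub) if p.kind in plain]
            xl.append(data.design_matrix(ps))
            pl.append(np.array([pidx[p.name] for p in ps], dtype=np.int64))
    Pmax = max(x.shape[1] for x in Xs_list)
    Qmax = max(x.shape[1] for x in Xd_list)
    Xs = np.zeros((S, I, max(Pmax, 1)))
    Xd = np.zeros((S, I, max(Qmax, 1)))
    spar = np.zeros((S, max(Pmax, 1)), dtype=np.int64)
    dpar = np.zeros((S, max(Qmax, 1)), dtype=np.int64)
    nP = np.array([x.shape[1] for x in Xs_list], dtype=np.int64)
    nQ = np.array([x.shape[1] for x in Xd_list], dtype=np.int64)
    for k in range(S):
        Xs[k, :, : nP[k]] = Xs_list[k]
        spar[k, : nP[k]] = spar_list[k]
        Xd[k, :, : nQ[k]] = Xd_list[k]
        dpar[k, : nQ[k]] = dpar_list[k]

    e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod = [], [], [], [], [], [], []
    for s in graph.species:
        for t in s.incoming_interactions:
            src = graph.species_model(t.source_species)
            e_src.append(sp_index[src.name])
            e_tgt.append(sp_index[s.name])
            e_sub.append(0 if t.target_submodel == "state" else 1)
            e_g0.append(pidx[graph.interaction_param(src.name, s.name, t.target_submodel, 0)])
            if t.modifier_covariate is not None:
                e_g1.append(pidx[graph.interaction_param(src.name, s.name, t.target_submodel, 1)])
                if t.modifier_covariate not in data.covariates.columns:
                    raise ConfigurationError(
                        f"missing modifier covariate {t.modifier_covariate!r}"
                    )
                e_mod.append(data.covariates[t.modifier_covariate].to_numpy(float))
            else:
                e_g1.append(-1)
                e_mod.append(np.zeros(I))
            e_ind.append(1 if (t.occupancy_mediated or src.state_variable == "occupancy") else 0)
    E = len(e_src)
    e_src = np.array(e_src, dtype=np.int64)
    e_tgt = np.array(e_tgt, dtype=np.int64)
    e_sub_a = np.array(e_sub, dtype=np.int64)
    e_g0 = np.array(e_g0, dtype=np.int64)
    e_g1 = np.array(e_g1, dtype=np.int64)
    e_ind = np.array(e_ind, dtype=np.uint8)
    e_mod = np.vstack(e_mod) if E else np.zeros((0, I))

    ins_groups = [e_tgt[e] for e in range(E) if e_sub_a[e] == 0]
    ins_ptr, ins_idx0 = _csr(ins_groups, S, len(ins_groups))
    ins_idx = np.array(
        [e for e in range(E) if e_sub_a[e] == 0], dtype=np.int64
    )[ins_idx0] if len(ins_groups) else np.zeros(0, dtype=np.int64)
    ind_groups = [e_tgt[e] for e in range(E) if e_sub_a[e] == 1]
    ind_ptr, ind_idx0 = _csr(ind_groups, S, len(ind_groups))
    ind_idx = np.array(
        [e for e in range(E) if e_sub_a[e] == 1], dtype=np.int64
    )[ind_idx0] if len(ind_groups) else np.zeros(0, dtype=np.int64)
    out_ptr, out_idx = _csr(list(e_src), S, E)

    Y = np.zeros((S, I))
    T = np.zeros((S, I))
    anydet = np.zeros((S, I), dtype=np.uint8)
    for k, s in enumerate(graph.species):
        ysum, trials = data.sufficient_stats(s.name, binary=(state_kind[k] == 1))
        Y[k] = ysum
        T[k] = trials
        anydet[k] = (ysum > 0).astype(np.uint8)

    role_sp = np.zeros(len(names), dtype=np.int64)
    role_sub = np.zeros(len(names), dtype=np.int64)
    for k, p in enumerate(graph.parameter_index):
        role_sp[k] = sp_index[p.species]
        role_sub[k] = 0 if p.submodel == "state" else 1
    if isinstance(prior_sd, dict):
        psd = np.array([float(prior_sd.get(n, DEFAULT_PRIOR_SD)) for n in names])
    else:
        psd = np.full(len(names), float(prior_sd))

    # One joint ridge move per edge: the target-submodel intercept and the
    # edge's gamma0 are near-collinear when the source is present at most
    # sites; proposing them in opposite directions restores mixing there.
    pair_a, pair_b, pair_sp, pair_sub = [], [], [], []
    for e in range(E):
        t = e_tgt[e]
        par_row = spar if e_sub_a[e] == 0 else dpar
        pair_a.append(par_row[t, 0])  # intercept is always the first column
        pair_b.append(e_g0[e])
        pair_sp.append(t)
        pair_sub.append(e_sub_a[e])
    pair_a = np.array(pair_a, dtype=np.int64)
    pair_b = np.array(pair_b, dtype=np.int64)
    pair_sp = np.array(pair_sp, dtype=np.int64)
    pair_sub = np.array(pair_sub, dtype=np.int64)

    # Site-collapsed updates are exact when sites are exchangeable given
    # their sufficient statistics: intercept-only submodels, no modifiers.
    fast_ok = bool(np.all(nP == 1) and np.all(nQ == 1) and np.all(e_g1 < 0))
    stacked = np.vstack([Y, T]).T
    _, dcls = np.unique(stacked, axis=0, return_inverse=True)
    dcls = dcls.astype(np.int64)
    n_dcls = int(dcls.max()) + 1 if I else 0

    return CompiledModel(
        graph=graph, data=data, parameter_names=list(names),
        state_kind=state_kind, Xs=Xs, nP=nP, spar=spar, Xd=Xd, nQ=nQ, dpar=dpar,
        e_src=e_src, e_tgt=e_tgt, e_sub=e_sub_a, e_g0=e_g0, e_g1=e_g1,
        e_ind=e_ind, e_mod=e_mod,
        ins_ptr=ins_ptr, ins_idx=ins_idx, ind_ptr=ind_ptr, ind_idx=ind_idx,
        out_ptr=out_ptr, out_idx=out_idx,
        Y=Y, T=T, anydet=anydet, role_sp=role_sp, role_sub=role_sub, prior_sd=psd,
        dcls=dcls, n_dcls=n_dcls, fast_ok=fast_ok,
        pair_a=pair_a, pair_b=pair_b, pair_sp=pair_sp, pair_sub=pair_sub,
    )


def choose_n_max(compiled: CompiledModel, default: int = 30) -> int:
    """Truncation bound: the configured default, or 10 * ceil(lambda-hat)
    from a naive occupancy-based abundance guess if that is larger."""
    best = default
    for k, s in enumerate(compiled.graph.species):
        if compiled.state_kind[k] != 0:
            continue
        phat = min(float(compiled.anydet[k].mean()), 0.95)
        lam_hat = -math.log(1.0 - phat) if phat > 0 else 0.0
        best = max(best, 10 * math.ceil(lam_hat))
    return best


def _initial_state(compiled: CompiledModel, rng: np.random.Generator):
    S, I = compiled.anydet.shape
    lat = np.zeros((S, I), dtype=np.int64)
    for k in range(S):
        if compiled.state_kind[k] == 0:
            lat[k] = compiled.anydet[k].astype(np.int64) + rng.poisson(1.0, size=I)
        else:
            lat[k] = compiled.anydet[k].astype(np.int64)
    theta = rng.normal(0.0, 1.0, size=compiled.n_par)
    return theta, lat


@dataclass
class ChainResult:
    chain_id: int
    draws: np.ndarray  # (n_kept, n_par)
    latent_draws: np.ndarray | None  # (n_kept, S, I) int16 or None
    acceptance: np.ndarray
    trunc_hits: int
    status: int
    err_info: np.ndarray

    @property
    def ok(self) -> bool:
        return self.status == 0


def run_chain(compiled: CompiledModel, mcmc: McmcConfig, chain_id: int = 0,
              record_latent: bool = True, n_max: int | None = None,
              collapse_sites: bool | None = None) -> ChainResult:
    """One chain, reproducible given (mcmc.seed, chain_id).

    ``collapse_sites`` forces the site-collapsed fast path on/off; by
    default it is used whenever the model structure permits and the
    equivalence-class tables stay small.  The two paths produce identical
    chains for a given seed.
    """
    seed = int((mcmc.seed + chain_id) % (2**31 - 1))
    rng = np.random.default_rng(seed)
    theta, lat = _initial_state(compiled, rng)
    scales = np.full(compiled.n_par, 0.3)
    nmax = n_max if n_max is not None else choose_n_max(compiled, mcmc.N_max)
    lat = np.minimum(lat, nmax)
    S = len(compiled.graph.species)
    use_fast = compiled.fast_ok and compiled.n_dcls * (nmax + 1) ** S <= 4_000_000
    if collapse_sites is not None:
        use_fast = collapse_sites and compiled.fast_ok
    draws, lat_draws, acc, trunc, status, err = _kernel.run_chain_kernel(
        seed, mcmc.n_iterations, mcmc.burn_in, mcmc.thin, record_latent,
        theta, lat, scales, mcmc.adapt_interval, mcmc.target_accept,
        *compiled.kernel_args(),
        compiled.prior_sd, compiled.role_sp, compiled.role_sub, nmax,
        use_fast, compiled.dcls, compiled.n_dcls,
        compiled.pair_a, compiled.pair_b, compiled.pair_sp, compiled.pair_sub,
    )
    return ChainResult(
        chain_id=chain_id,
        draws=draws,
        latent_draws=lat_draws if record_latent else None,
        acceptance=acc / mcmc.n_iterations,
        trunc_hits=int(trunc),
        status=int(status),
        err_info=err,
    )


def fit(graph: ModelGraph, data: DetectionData, mcmc: McmcConfig | None = None,
        record_latent: bool = True, prior_sd: float | dict = DEFAULT_PRIOR_SD):
    """Run n_chains chains and assemble a PosteriorResult with summaries
    and convergence diagnostics.  A failed chain flags the result unusable
    instead of raising."""
    from .diagnostics import build_result

    mcmc = mcmc or McmcConfig()
    compiled = compile_model(graph, data, prior_sd=prior_sd)
    nmax = choose_n_max(compiled, mcmc.N_max)
    chains, errors, warnings = [], [], []
    for c in range(mcmc.n_chains):
        res = run_chain(compiled, mcmc, chain_id=c, record_latent=record_latent, n_max=nmax)
        if not res.ok:
            it, s, i = res.err_info
            errors.append(
                f"chain {c}: latent full conditional underflowed at iteration {it}, "
                f"species {compiled.graph.species[s].name!r}, site {i}"
            )
        chains.append(res)
        if res.trunc_hits > 0:
            warnings.append(
                f"chain {c}: N_max={nmax} truncation mass exceeded 1e-6 in "
                f"{res.trunc_hits} updates"
            )
    return build_result(compiled, mcmc, chains, errors, warnings)


def gibbs_latent_draws(graph: ModelGraph, data: DetectionData, coefs: dict,
                       n_draws: int, seed: int = 0, n_max: int = 30,
                       lat0: np.ndarray | None = None) -> np.ndarray:
    """Latent-only Gibbs sampling at fixed coefficients.

    Returns an (n_draws, S, I) array of latent states; species axis follows
    the graph's topological order.  This is the object the full-conditional
    oracle tests compare against brute-force enumeration.
    """
    compiled = compile_model(graph, data)
    missing = [n for n in compiled.parameter_names if n not in coefs]
    if missing:
        raise ConfigurationError(f"missing coefficient values for {missing}")
    theta = np.array([float(coefs[n]) for n in compiled.parameter_names])
    if lat0 is None:
        _, lat = _initial_state(compiled, np.random.default_rng(seed))
    else:
        lat = np.asarray(lat0, dtype=np.int64).copy()
    return _kernel.gibbs_latent_kernel(
        int(seed % (2**31 - 1)), n_draws, theta, lat,
        *compiled.kernel_args(), n_max,
    )
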