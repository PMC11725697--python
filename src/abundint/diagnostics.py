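"""Convergence diagnostics, posterior summaries, posterior predictive checks.

Point summaries follow the convention of reporting the posterior mode
(midpoint of the highest bin of a fixed 512-bin histogram — deterministic
and testable) alongside the mean and equal-tailed 95% credible interval.
Convergence uses the classic Gelman–Rubin potential scale reduction factor
with its Brooks–Gelman 97.5% upper bound; a fit counts as converged only
if every parameter's upper bound is below 1.1.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "gelman_rubin",
    "posterior_mode",
    "equal_tailed_cri",
    "effective_sample_size",
    "PosteriorResult",
    "build_result",
    "ppc_pearson",
]


def gelman_rubin(draws: np.ndarray) -> dict:
    """Classic potential scale reduction factor with 97.5% upper bound.

    ``draws`` is (chains, iterations) for one parameter.  Returns
    ``{"point": ..., "upper": ...}``; with a single chain both are NaN
    (unavailable).  The degrees-of-freedom correction and the F-quantile
    upper bound follow Brooks & Gelman's formulation.
    """
    x = np.atleast_2d(np.asarray(draws, dtype=float))
    m, n = x.shape
    if m < 2:
        return {"point": float("nan"), "upper": float("nan")}
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    means = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    W = s2.mean()
    B = n * means.var(ddof=1)
    muhat = means.mean()
    if W <= 0:
        pt = 1.0 if B <= 0 else np.inf
        return {"point": pt, "upper": pt}
    var_w = s2.var(ddof=1) / m
    var_b = 2.0 * B * B / (m - 1)
    cov_wb = (n / m) * (
        np.cov(s2, means**2, ddof=1)[0, 1] - 2.0 * muhat * np.cov(s2, means, ddof=1)[0, 1]
    )
    V = (n - 1) * W / n + (1.0 + 1.0 / m) * B / n
    var_V = ((n - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * var_b
             + 2 * (n - 1) * (1 + 1 / m) * cov_wb) / n**2
    df_V = 2.0 * V**2 / var_V if var_V > 0 else np.inf
    df_adj = (df_V + 3.0) / (df_V + 1.0)
    W_df = 2.0 * W**2 / var_w if var_w > 0 else np.inf
    r2_fixed = (n - 1.0) / n
    r2_random = (1.0 + 1.0 / m) * B / (n * W)
    point = float(np.sqrt(df_adj * (r2_fixed + r2_random)))
    upper = float(np.sqrt(df_adj * (r2_fixed + stats.f.ppf(0.975, m - 1, W_df) * r2_random)))
    return {"point": point, "upper": upper}


def posterior_mode(draws: np.ndarray, bins: int = 512) -> float:
    """Midpoint of the highest-count bin of a fixed-width histogram
    spanning the draw range (first such bin on ties)."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("no draws")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(x, bins=bins, range=(lo, hi))
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def equal_tailed_cri(draws: np.ndarray, level: float = 0.95):
    """Equal-tailed credible interval: empirical central quantiles."""
    x = np.asarray(draws, dtype=float).ravel()
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [a, 1.0 - a])
    return float(lo), float(hi)


def effective_sample_size(draws: np.ndarray) -> float:
    """Bulk effective sample size of (chains, iterations) draws (arviz)."""
    import arviz as az

    x = np.atleast_2d(np.asarray(draws, dtype=float))
    return float(az.ess(x))


@dataclass
class PosteriorResult:
    """Multi-chain posterior draws with summaries and diagnostics."""

    draws: np.ndarray  # (chains, kept, params)
    parameter_names: list
    summaries: pd.DataFrame
    rhat: np.ndarray
    rhat_upper: np.ndarray
    ess: np.ndarray
    latent_draws: np.ndarray | None = None  # (chains, kept, S, I) int16
    species_names: list = field(default_factory=list)
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    ppc_pvalues: dict = field(default_factory=dict)
    mcmc: object = None
    compiled: object = None
    runtime_s: float = 0.0

    @property
    def usable(self) -> bool:
        return not self.errors

    @property
    def converged(self):
        """True iff every parameter's R-hat upper CI is < 1.1; None when
        R-hat is unavailable (single chain)."""
        if self.draws.shape[0] < 2:
            return None
        if not self.usable:
            return False
        return bool(np.all(self.rhat_upper < 1.1))

    def param_draws(self, name: str) -> np.ndarray:
        j = self.parameter_names.index(name)
        return self.draws[:, :, j]

    def mode(self, name: str) -> float:
        return posterior_mode(self.param_draws(name))

    def cri(self, name: str, level: float = 0.95):
        return equal_tailed_cri(self.param_draws(name), level)

    def to_frame(self) -> pd.DataFrame:
        """Tidy draws: chain, iteration, parameter, value."""
        C, D, P = self.draws.shape
        ch, it, pj = np.meshgrid(np.arange(C), np.arange(D), np.arange(P), indexing="ij")
        return pd.DataFrame(
            {
                "chain": ch.ravel(),
                "iteration": it.ravel(),
                "parameter": np.asarray(self.parameter_names)[pj.ravel()],
                "value": self.draws.ravel(),
            }
        )

    def save(self, out_dir, manifest_extra: dict | None = None) -> None:
        """Write chains.csv (tidy), summary.csv, and a JSON run manifest."""
        import abundint

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "chains.csv", index=False)
        self.summaries.to_csv(out / "summary.csv", index=False)
        manifest = {
            "package_version": abundint.__version__,
            "numpy_version": np.__version__,
            "mcmc": None if self.mcmc is None else vars(self.mcmc) | {},
            "parameters": self.parameter_names,
            "n_chains": int(self.draws.shape[0]),
            "converged": self.converged,
            "errors": self.errors,
            "runtime_s": self.runtime_s,
        }
        if manifest_extra:
            manifest.update(manifest_extra)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)


def summarize_chains(draws: np.ndarray, names) -> pd.DataFrame:
    C, D, P = draws.shape
    rows = []
    for j, name in enumerate(names):
        x = draws[:, :, j]
        gr = gelman_rubin(x)
        lo, hi = equal_tailed_cri(x)
        rows.append(
            {
                "parameter": name,
                "mode": posterior_mode(x),
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)),
                "lo95": lo,
                "hi95": hi,
                "rhat": gr["point"],
                "rhat_upper": gr["upper"],
                "ess": effective_sample_size(x),
            }
        )
    return pd.DataFrame(rows)


def build_result(compiled, mcmc, chains, errors, warnings=()) -> PosteriorResult:
    """Assemble a PosteriorResult from per-chain kernel output."""
    t0 = time.time()
    n_kept = min(c.draws.shape[0] for c in chains)
    draws = np.stack([c.draws[:n_kept] for c in chains])
    lat = None
    if all(c.latent_draws is not None for c in chains):
        lat = np.stack([c.latent_draws[:n_kept] for c in chains])
    names = compiled.parameter_names
    summaries = summarize_chains(draws, names)
    return PosteriorResult(
        draws=draws,
        parameter_names=list(names),
        summaries=summaries,
        rhat=summaries["rhat"].to_numpy(),
        rhat_upper=summaries["rhat_upper"].to_numpy(),
        ess=summaries["ess"].to_numpy(),
        latent_draws=lat,
        species_names=[s.name for s in compiled.graph.species],
        errors=list(errors),
        warnings=list(warnings),
        mcmc=mcmc,
        compiled=compiled,
        runtime_s=time.time() - t0,
    )


def _detection_prob_for_draw(compiled, k, theta, lat_si):
    """Site-level success probability of the observation model of species k
    at one posterior draw, conditional on the latent states of that draw."""
    eta_d = compiled.Xd[k, :, : compiled.nQ[k]] @ theta[compiled.dpar[k, : compiled.nQ[k]]]
    for q in range(compiled.ind_ptr[k], compiled.ind_ptr[k + 1]):
        e = compiled.ind_idx[q]
        f = lat_si[compiled.e_src[e]].astype(float)
        if compiled.e_ind[e] == 1:
            f = (f > 0).astype(float)
        g = theta[compiled.e_g0[e]]
        if compiled.e_g1[e] >= 0:
            g = g + theta[compiled.e_g1[e]] * compiled.e_mod[e]
        eta_d = eta_d + g * f
    p_ind = expit(eta_d)
    if compiled.state_kind[k] == 0:
        N = lat_si[k].astype(float)
        return -np.expm1(np.log1p(-np.clip(p_ind, 0, 1 - 1e-12)) * N)
    return p_ind * (lat_si[k] > 0)


def ppc_pearson(result: PosteriorResult, species: str, n_rep: int = 200,
                seed: int = 0) -> float:
    """Bayesian p-value from a Pearson chi-square discrepancy.

    For each of n_rep posterior draws: T(y, theta) sums
    (y_ij - E[y_ij|theta])^2 / (Var[y_ij|theta] + 0.5) over sampled cells,
    with moments conditional on that draw's latent states; replicate data
    are simulated from the same draw and p is the proportion of draws with
    T(y_rep) >= T(y_obs).
    """
    compiled = result.compiled
    if result.latent_draws is None:
        raise ValueError("posterior predictive checks need recorded latent draws")
    k = result.species_names.index(species)
    data = compiled.data
    mask = data.design.observed_mask
    y = data.y[species]
    binary = compiled.state_kind[k] == 1
    K = 1 if binary else data.design.n_subsamples
    y_obs = np.minimum(y, 1) if binary else y
    rng = np.random.default_rng(seed)
    C, D, P = result.draws.shape
    flat = rng.choice(C * D, size=min(n_rep, C * D), replace=False)
    count = 0
    for idx in flat:
        c, d = divmod(idx, D)
        theta = result.draws[c, d]
        lat_si = result.latent_draws[c, d]
        p_site = _detection_prob_for_draw(compiled, k, theta, lat_si)
        E = K * p_site[:, None] * mask
        V = K * (p_site * (1 - p_site))[:, None] * mask
        t_obs = float((((np.where(mask, y_obs, 0) - E) ** 2) / (V + 0.5))[mask].sum())
        y_rep = rng.binomial(K, np.broadcast_to(p_site[:, None], mask.shape))
        t_rep = float((((np.where(mask, y_rep, 0) - E) ** 2) / (V + 0.5))[mask].sum())
        if t_rep >= t_obs:
            count += 1
    return count / len(flat)
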