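"""Batch simulate-fit-evaluate harness.

Replicates the evaluation protocol of the simulation studies: simulate
``n_reps`` datasets from a scenario, fit the abundance-mediated model
(and/or its occupancy-mediated comparison variant), keep only converged
fits (every parameter's Gelman-Rubin upper CI < 1.1), and evaluate
posterior-mode point estimates by relative bias (absolute bias for true
zeros), 95% credible-interval coverage, and Type S / Type M error
classification.

Both the signed mean relative bias and the mean of |RB| are reported; the
magnitude |mean RB| is the quantity tables compare against, and a Monte
Carlo standard error accompanies it so that reduced replicate counts can
be compared with full-scale results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import as_occupancy_mediated
from .samplers import McmcConfig, fit
from .simulate import SimulationScenario, simulate_dataset

__all__ = [
    "relative_bias",
    "absolute_bias",
    "coverage",
    "classify_error",
    "EvaluationSummary",
    "run_study",
    "VARIANTS",
]

VARIANTS = ("abundance_mediated", "occupancy_mediated")
BIAS_THRESHOLD = 0.05


def relative_bias(estimate: float, truth: float) -> float:
    """(theta_hat - theta) / theta; callers must use absolute_bias when
    the true value is zero."""
    if truth == 0:
        raise ZeroDivisionError("relative bias undefined at truth 0; use absolute_bias")
    return (estimate - truth) / truth


def absolute_bias(estimate: float, truth: float) -> float:
    """theta_hat - theta (used for true values of zero)."""
    return estimate - truth


def coverage(cri_list, truth: float) -> float:
    """Fraction of intervals with lo <= truth <= hi (boundary covered)."""
    cris = list(cri_list)
    if not cris:
        raise ValueError("need at least one interval")
    hits = sum(1 for lo, hi in cris if lo <= truth <= hi)
    return hits / len(cris)


def classify_error(mean_rb: float, truth_sign: int, estimates_sign: int,
                   threshold: float = BIAS_THRESHOLD) -> str:
    """'type_S' when the estimated direction opposes the truth; otherwise
    'type_M' when |mean bias| exceeds the threshold; otherwise 'unbiased'."""
    if estimates_sign != 0 and estimates_sign != truth_sign:
        return "type_S"
    if abs(mean_rb) > threshold:
        return "type_M"
    return "unbiased"


@dataclass
class EvaluationSummary:
    scenario: str
    variant: str
    n_total: int
    n_converged: int
    table: pd.DataFrame  # one row per parameter

    def row(self, parameter: str) -> pd.Series:
        t = self.table[self.table["parameter"] == parameter]
        if t.empty:
            raise KeyError(parameter)
        return t.iloc[0]


def _variant_graph(graph, variant: str):
    if variant == "abundance_mediated":
        return graph
    if variant == "occupancy_mediated":
        return as_occupancy_mediated(graph)
    raise ValueError(f"unknown variant {variant!r}")


def _summarize_variant(scenario, variant, records: pd.DataFrame, truths: dict):
    conv = records[records["converged"]]
    n_total = records["rep"].nunique()
    n_conv = conv["rep"].nunique()
    rows = []
    for pname, truth in truths.items():
        sub = conv[conv["parameter"] == pname]
        est = sub["mode"].to_numpy(float)
        if len(est) == 0:
            rows.append({"parameter": pname, "true_value": truth, "n_converged": 0,
                         "n_total": n_total})
            continue
        if truth != 0:
            rb = np.array([relative_bias(e, truth) for e in est])
            metric = "relative"
        else:
            rb = np.array([absolute_bias(e, truth) for e in est])
            metric = "absolute"
        cov = coverage(list(zip(sub["lo95"], sub["hi95"])), truth)
        sign_t = int(np.sign(truth))
        sign_e = int(np.sign(est.mean()))
        type_s_rate = float(np.mean(np.sign(est) != sign_t)) if truth != 0 else np.nan
        mean_rb = float(rb.mean())
        rows.append(
            {
                "parameter": pname,
                "true_value": truth,
                "bias_metric": metric,
                "mean_rb": mean_rb,
                "abs_mean_rb": abs(mean_rb),
                "mean_abs_rb": float(np.abs(rb).mean()),
                "mc_se_rb": float(rb.std(ddof=1) / np.sqrt(len(rb))) if len(rb) > 1 else np.nan,
                "coverage": cov,
                "type_s_rate": type_s_rate,
                "classification": classify_error(mean_rb, sign_t if sign_t else 1, sign_e),
                "n_converged": len(est),
                "n_total": n_total,
            }
        )
    return EvaluationSummary(
        scenario=scenario.name, variant=variant, n_total=n_total,
        n_converged=n_conv, table=pd.DataFrame(rows),
    )


def run_study(scenario: SimulationScenario, n_reps: int = 25,
              variants=("abundance_mediated",), mcmc: McmcConfig | None = None,
              base_seed: int = 1, parameters=None, out_dir=None,
              progress: bool = False):
    """Simulate n_reps datasets (seeds base_seed + k), fit each requested
    variant, filter non-converged fits, and evaluate point estimates.

    Returns (summaries, results): a dict variant -> EvaluationSummary and
    the tidy per-fit results table.  A failed fit is logged in the results
    with converged=False; it stays in n_total.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    mcmc = mcmc or McmcConfig()
    track = list(parameters) if parameters else list(scenario.graph.parameter_names)
    recs = []
    for k in range(n_reps):
        data, truth = simulate_dataset(scenario, seed=base_seed + k)
        for variant in variants:
            g = _variant_graph(scenario.graph, variant)
            m = replace(mcmc, seed=int((base_seed + 104729 * (k + 1)) % (2**31 - 1)))
            res = fit(g, data, m, record_latent=False)
            conv = bool(res.converged) and res.usable
            for pname in track:
                lo, hi = res.cri(pname)
                recs.append(
                    {
                        "scenario": scenario.name,
                        "variant": variant,
                        "rep": k,
                        "parameter": pname,
                        "mode": res.mode(pname),
                        "mean": float(res.param_draws(pname).mean()),
                        "lo95": lo,
                        "hi95": hi,
                        "converged": conv,
                    }
                )
        if progress:
            print(f"  rep {k + 1}/{n_reps} done", flush=True)
    results = pd.DataFrame(recs)
    truths = {p: float(scenario.true_values[p]) for p in track}
    summaries = {
        v: _summarize_variant(scenario, v, results[results["variant"] == v], truths)
        for v in variants
    }
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "study_results.csv", index=False)
        pd.concat(
            [s.table.assign(scenario=s.scenario, variant=s.variant) for s in summaries.values()]
        ).to_csv(out / "study_summary.csv", index=False)
    return summaries, results
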