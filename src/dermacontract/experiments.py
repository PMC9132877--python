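"""Scenario orchestration: sensitivity sweeps, backend comparison, Monte Carlo.

The sweep varies one mechanical parameter at a time on the deterministic
fixed-cell scenario and reports the scar-area series with its extremal times.
The comparison runs the stochastic biology once, records the per-step
traction history, and replays it through both mechanics backends so that the
two relative-area curves answer only for the mechanical formalism.  The Monte
Carlo study draws mechanical and cellular rate parameters from the stated
input distributions, runs the full stochastic model per sample, and
summarizes the scar outputs with Monte Carlo error estimates, pairwise
correlations and a normality check of the final area.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .observables import mc_error, t_end_of, t_min_of
from .scenarios import Scenario
from .simulation import ForceHistory, Simulation

__all__ = [
    "run_sensitivity_sweep",
    "run_comparison",
    "MCInputSpec",
    "run_monte_carlo",
]

SWEEP_RANGES = {"E_s": (20.0, 200.0), "eta": (0.6, 3.0),
                "alpha": (0.0, 1.0), "nu": (0.118, 0.495)}


def run_sensitivity_sweep(param: str, values, scenario: Scenario) -> pd.DataFrame:
    """One-at-a-time sweep of a mechanical parameter on the fixed-cell scenario.

    Returns one row per value with t_min, t_end, the minimal and final
    relative areas, and the full r(t) series attached in the ``series``
    column.  Solver failures are recorded and the sweep continues.
    """
    if param not in SWEEP_RANGES:
        raise ValueError(f"sweep parameter must be one of {sorted(SWEEP_RANGES)}")
    lo, hi = SWEEP_RANGES[param]
    rows = []
    for val in values:
        if not lo <= val <= hi:
            raise ValueError(f"{param} = {val} outside the sweep range [{lo}, {hi}]")
        sc = scenario.with_overrides(**{param: float(val)})
        try:
            sim = Simulation(sc)
            sim.run()
            summ = sim.summary()
            rows.append({"param": param, "value": float(val), "failed": False,
                         "series": sim.series, **summ})
        except Exception as exc:  # noqa: BLE001 - record and continue per contract
            rows.append({"param": param, "value": float(val), "failed": True,
                         "error": str(exc)})
    return pd.DataFrame(rows)


def run_comparison(scenario: Scenario) -> dict:
    """Run both backends on identical force histories with a shared seed.

    The stochastic layer is driven once by the morphoelastic backend while the
    per-step traction loads and myofibroblast occupancy are recorded; the
    phenomenological backend then replays that history.  Returns the paired
    series and, in the non-permanent mode (Q = 0 and alpha = 0), the maximal
    pointwise discrepancy of the relative-area curves.
    """
    sc_m = replace(scenario, stop_after_equilibrium=False)
    sim_m = Simulation(sc_m, backend="morpho", record=True)
    sim_m.run()
    # replay needs only mechanics: the biology fields are fixed by the history
    sc_p = replace(sc_m, enable_chemistry=False, enable_fibers=False,
                   enable_cell_dynamics=False)
    sim_p = Simulation(sc_p, backend="phenom", replay=sim_m.history)
    sim_p.run()
    r_m = sim_m.series.r
    r_p = sim_p.series.r
    n = min(len(r_m), len(r_p))
    out = {
        "series_morpho": sim_m.series,
        "series_phenom": sim_p.series,
        "r_final_morpho": float(r_m[n - 1]),
        "r_final_phenom": float(r_p[n - 1]),
        "max_abs_diff": float(np.max(np.abs(r_m[:n] - r_p[:n]))),
    }
    return out


@dataclass
class MCInputSpec:
    """Input sampling distributions for the Monte Carlo study.

    Defaults are the stated distributions: substrate stiffness
    LogNormal(log 50, 0.1), fibroblast division coefficient Uniform(1.5, 2.5),
    myofibroblast apoptosis rate Normal(10, 0.1), macrophage influx rate
    LogNormal(log 0.04, 1e-5).  Per-sample seeds derive deterministically
    from the base seed and the sample index.
    """

    n_samples: int = 10
    base_seed: int = 0
    E_s_mu: float = float(np.log(50.0))
    E_s_sigma: float = 0.1
    lambda_d_lo: float = 1.5
    lambda_d_hi: float = 2.5
    lambda_a_mean: float = 10.0
    lambda_a_sd: float = 0.1
    lambda_imm_mu: float = float(np.log(0.04))
    lambda_imm_sigma: float = 1e-5

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        return {
            "E_s": float(rng.lognormal(self.E_s_mu, self.E_s_sigma)),
            "lambda_d": float(rng.uniform(self.lambda_d_lo, self.lambda_d_hi)),
            "lambda_a": float(rng.normal(self.lambda_a_mean, self.lambda_a_sd)),
            "lambda_immune_random": float(
                rng.lognormal(self.lambda_imm_mu, self.lambda_imm_sigma)),
        }


MC_OUTPUTS = [
    "n", "n_min", "n_rho_0.5", "n_rho_0.8",
    "Area_final", "Area_min", "Area_4d", "Area_rho_0.5", "Area_rho_0.8",
    "rho_c_hat_final", "rho_c_hat_min", "rho_c_hat_4d",
]

CORRELATION_PAIRS = [
    ("Area_min", "Area_final"),
    ("Area_4d", "Area_final"),
    ("E_s", "Area_final"),
    ("E_s", "rho_c_hat_final"),
    ("rho_c_hat_final", "Area_final"),
    ("rho_c_hat_4d", "Area_4d"),
]


def _extract_outputs(summary: dict) -> dict[str, float]:
    return {
        "n": summary["t_end"],
        "n_min": summary["t_min"],
        "n_rho_0.5": summary.get("t_rho_0.5", float("nan")),
        "n_rho_0.8": summary.get("t_rho_0.8", float("nan")),
        "Area_final": summary["area_final"],
        "Area_min": summary["area_min"],
        "Area_4d": summary["area_checkpoint"],
        "Area_rho_0.5": summary.get("area_rho_0.5", float("nan")),
        "Area_rho_0.8": summary.get("area_rho_0.8", float("nan")),
        "rho_c_hat_final": summary.get("rho_hat_final", float("nan")),
        "rho_c_hat_min": summary.get("rho_hat_min", float("nan")),
        "rho_c_hat_4d": summary.get("rho_hat_checkpoint", float("nan")),
    }


def run_monte_carlo(spec: MCInputSpec, scenario: Scenario) -> dict:
    """Monte Carlo over the input distributions on the full stochastic model.

    Returns the per-sample table, the per-output summary (mean, SD, Monte
    Carlo error, relative error), the pairwise Pearson correlations, and a
    normality test of the final area.  Failed samples are logged and excluded.
    """
    if spec.n_samples < 2:
        raise ValueError("need at least two Monte Carlo samples")
    records, failures = [], []
    for i in range(spec.n_samples):
        rng_in = np.random.default_rng([spec.base_seed, i])
        draw = rng_in.integers(0, 2**31 - 1)
        inputs = spec.draw(rng_in)
        sc = scenario.with_overrides(
            E_s=inputs["E_s"],
            seed=int(draw),
            rates=replace(scenario.rates,
                          lambda_d=inputs["lambda_d"],
                          lambda_a=inputs["lambda_a"],
                          lambda_immune_random=inputs["lambda_immune_random"]),
        )
        try:
            sim = Simulation(sc)
            sim.run()
            records.append({"sample": i, **inputs, **_extract_outputs(sim.summary())})
        except Exception as exc:  # noqa: BLE001
            failures.append({"sample": i, "error": str(exc)})
    samples = pd.DataFrame(records)
    summary_rows = []
    for name in MC_OUTPUTS:
        col = samples[name].dropna() if name in samples else pd.Series(dtype=float)
        if len(col) >= 2:
            mu, sd = float(col.mean()), float(col.std(ddof=1))
            err, rel = mc_error(mu, sd, len(col))
        else:
            mu = sd = err = rel = float("nan")
        summary_rows.append({"output": name, "mean": mu, "sd": sd,
                             "n": len(col), "mc_error": err, "rel_error": rel})
    corr_rows = []
    for a, b in CORRELATION_PAIRS:
        if a in samples and b in samples:
            sub = samples[[a, b]].dropna()
            if len(sub) >= 3 and sub[a].std() > 0 and sub[b].std() > 0:
                rho, p = stats.pearsonr(sub[a], sub[b])
                corr_rows.append({"x": a, "y": b, "pearson_r": float(rho),
                                  "p_value": float(p), "n": len(sub)})
    area = samples["Area_final"].dropna() if "Area_final" in samples else pd.Series(dtype=float)
    normality = None
    if len(area) >= 3 and area.std() > 0:
        stat, p = stats.shapiro(area)
        normality = {"statistic": float(stat), "p_value": float(p)}
    return {
        "samples": samples,
        "summary": pd.DataFrame(summary_rows),
        "correlations": pd.DataFrame(corr_rows),
        "normality_area_final": normality,
        "failures": failures,
    }
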