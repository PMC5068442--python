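"""Parameter-recovery experiments: simulate with known truth, fit, compare.

This is the calibration harness for the mixed-model fitters: datasets are
generated by :mod:`divescaling.synthetic_data` under the exact model the
fitters assume, then fitted with REML and/or Gibbs, and the estimates are
compared with the generating values — bias per coefficient and 95%-interval
coverage, replicate by replicate and in aggregate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace

import numpy as np

from .inference import build_design, fit_gibbs, fit_reml
from .synthetic_data import (
    DEFAULT_MASS_RANGE,
    DEFAULT_TEMP_RANGE,
    SimTruth,
    simulate_dataset,
)

__all__ = ["replicate_seeds", "run_recovery"]


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` per-replicate seeds (< 2^31) deterministically."""
    rng = np.random.default_rng(np.random.SeedSequence(int(master_seed)))
    return rng.integers(0, 2**31 - 1, size=n)


def run_recovery(
    truth: SimTruth,
    n_replicates: int = 20,
    methods: tuple = ("reml", "gibbs"),
    master_seed: int = 1,
    mass_range=DEFAULT_MASS_RANGE,
    temp_range=DEFAULT_TEMP_RANGE,
    which_response: str = "median",
    gibbs_options: dict | None = None,
) -> dict:
    """Run the simulate→fit→compare loop and return a JSON-serializable report.

    Each replicate regenerates the tree and data with its own derived seed,
    fits every requested method with temperature included, and records the
    estimated coefficients, bias against truth, and whether each true value
    fell inside the 95% interval.  Replicate failures are recorded and the
    run continues.
    """
    if gibbs_options is None:
        gibbs_options = {}
    true_by_name = {
        "intercept": truth.beta0,
        "ln_mass": truth.beta_mass,
        "temp_C": truth.beta_temp,
    }
    seeds = replicate_seeds(master_seed, n_replicates)
    replicates = []
    for rep, seed in enumerate(seeds):
        rep_truth = replace(truth, seed=int(seed))
        entry: dict = {"replicate": rep, "seed": int(seed), "fits": {}}
        try:
            sim = simulate_dataset(rep_truth, mass_range, temp_range)
            design = build_design(
                sim.dataset, which_response=which_response,
                include_temperature=True, tree=sim.tree,
            )
        except Exception as e:  # noqa: BLE001 - recorded, run continues
            entry["error"] = f"{type(e).__name__}: {e}"
            replicates.append(entry)
            continue
        for method in methods:
            try:
                if method == "reml":
                    fit = fit_reml(design)
                elif method == "gibbs":
                    fit = fit_gibbs(design, seed=int(seed), **gibbs_options)
                else:
                    raise ValueError(f"unknown method {method!r}")
            except Exception as e:  # noqa: BLE001
                entry["fits"][method] = {"error": f"{type(e).__name__}: {e}"}
                continue
            coefs = {}
            for c in fit.coefficients:
                truth_val = true_by_name[c.name]
                coefs[c.name] = {
                    "true": truth_val,
                    "estimate": c.estimate,
                    "bias": c.estimate - truth_val,
                    "lower95": c.lower95,
                    "upper95": c.upper95,
                    "covered": bool(c.lower95 <= truth_val <= c.upper95),
                }
            entry["fits"][method] = {
                "coefficients": coefs,
                "varcomp": asdict(fit.varcomp),
                "conditional_r2": fit.conditional_r2,
            }
        replicates.append(entry)

    summary: dict = {}
    for method in methods:
        per_coef: dict = {}
        for name in true_by_name:
            ests = [
                r["fits"][method]["coefficients"][name]["estimate"]
                for r in replicates
                if method in r["fits"] and "coefficients" in r["fits"][method]
            ]
            cov = [
                r["fits"][method]["coefficients"][name]["covered"]
                for r in replicates
                if method in r["fits"] and "coefficients" in r["fits"][method]
            ]
            if not ests:
                per_coef[name] = {"n_fits": 0}
                continue
            mean_est = float(np.mean(ests))
            per_coef[name] = {
                "true": true_by_name[name],
                "mean_estimate": mean_est,
                "mean_bias": mean_est - true_by_name[name],
                "coverage": float(np.mean(cov)),
                "n_fits": len(ests),
            }
        summary[method] = per_coef

    n_failed = sum(
        1 for r in replicates
        if "error" in r or any("error" in f for f in r["fits"].values())
    )
    return {
        "truth": asdict(truth),
        "master_seed": int(master_seed),
        "n_replicates": n_replicates,
        "methods": list(methods),
        "n_failed": n_failed,
        "summary": summary,
        "replicates": replicates,
    }
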