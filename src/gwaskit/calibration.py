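"""Calibration suites: statistical sanity checks with known ground truth.

These routines run the toolkit end-to-end on simulated data and summarise
how well it recovers the truth: colocalisation posteriors on shared /
distinct / null two-trait regions, IVW and Egger parameter recovery on
summary-level instrument draws, and the type-I error of the simulated
marginal association test. They back both the test suite and the
reproducibility script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coloc import ColocPriors, coloc_abf, compute_labf
from .mr import InstrumentSet, ivw_mr, mr_egger
from .simulate import SimulationConfig, make_scenario, simulate_genotypes, simulate_sumstats
from .variants import VariantKey

__all__ = [
    "coloc_scenario_posteriors",
    "mr_recovery",
    "egger_pleiotropy_recovery",
    "marginal_type1_error",
]


def coloc_scenario_posteriors(
    label: str,
    n_regions: int,
    seed: int,
    n_samples: int = 20_000,
    n_variants: int = 200,
    effect: float = 0.5,
    analytic: bool = True,
) -> pd.DataFrame:
    """Posterior probabilities over replicated two-trait regions.

    Each region is an independent scenario draw; the coloc posterior is
    computed from Wakefield ABFs at default priors. Returns one row per
    region with columns pp0..pp4.
    """
    rows = []
    for rep in range(n_regions):
        config = SimulationConfig(
            n_samples=n_samples,
            n_variants=n_variants,
            causal_effects=((effect,),),
            seed=seed + rep,
        )
        sc = make_scenario(label, config, analytic=analytic)
        res = coloc_abf(
            compute_labf(sc.tables[0]), compute_labf(sc.tables[1]), ColocPriors()
        )
        rows.append({"pp0": res.pp0, "pp1": res.pp1, "pp2": res.pp2,
                     "pp3": res.pp3, "pp4": res.pp4})
    return pd.DataFrame(rows)


def _draw_instruments(
    rng: np.random.Generator,
    J: int,
    true_beta: float,
    pleiotropy: float = 0.0,
    sx: float = 0.01,
    sy: float = 0.02,
) -> InstrumentSet:
    # strong-instrument regime: smallest F = (0.15/0.01)^2 = 225
    bx_true = rng.uniform(0.15, 0.5, J)
    bx = bx_true + rng.normal(0, sx, J)
    by = true_beta * bx_true + pleiotropy + rng.normal(0, sy, J)
    keys = [VariantKey("1", 1_000 + 1_000 * j, "A", "G") for j in range(J)]
    return InstrumentSet(
        keys=keys, bx=bx, sx=np.full(J, sx), by=by, sy=np.full(J, sy)
    )


def mr_recovery(
    J: int,
    true_beta: float,
    n_reps: int,
    seed: int,
    weighting: str = "delta",
) -> dict:
    """IVW parameter recovery over replicated strong-instrument draws.

    Returns the mean bias of the point estimate and the count of replicates
    whose 95% CI covers the true effect.
    """
    rng = np.random.default_rng(seed)
    estimates, covered = [], 0
    for _ in range(n_reps):
        est = ivw_mr(_draw_instruments(rng, J, true_beta), weighting)
        estimates.append(est.beta)
        covered += est.ci_low <= true_beta <= est.ci_high
    return {
        "J": J,
        "true_beta": true_beta,
        "n_reps": n_reps,
        "bias": float(np.mean(estimates) - true_beta),
        "coverage": int(covered),
    }


def egger_pleiotropy_recovery(
    J: int,
    true_beta: float,
    pleiotropy: float,
    n_reps: int,
    seed: int,
) -> dict:
    """MR-Egger recovery of an injected constant directional pleiotropy."""
    rng = np.random.default_rng(seed)
    intercepts, covered, slope_covered = [], 0, 0
    for _ in range(n_reps):
        est = mr_egger(_draw_instruments(rng, J, true_beta, pleiotropy=pleiotropy))
        intercepts.append(est.intercept)
        lo = est.intercept - 1.959964 * est.intercept_se
        hi = est.intercept + 1.959964 * est.intercept_se
        covered += lo <= pleiotropy <= hi
        slope_covered += est.ci_low <= true_beta <= est.ci_high
    return {
        "J": J,
        "pleiotropy": pleiotropy,
        "n_reps": n_reps,
        "mean_intercept": float(np.mean(intercepts)),
        "intercept_coverage": int(covered),
        "slope_coverage": int(slope_covered),
    }


def marginal_type1_error(
    n_reps: int = 50,
    n_variants: int = 500,
    n_samples: int = 1_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the marginal test on independent null variants.

    Variants are simulated without LD (ld_decay = 0) so the per-variant
    rejections are independent and the nominal binomial bounds apply.
    """
    rejections, total = 0, 0
    for rep in range(n_reps):
        config = SimulationConfig(
            n_samples=n_samples,
            n_variants=n_variants,
            ld_decay=0.0,
            causal_index_sets=((),),
            seed=seed + rep,
        )
        g, ld = simulate_genotypes(config)
        table = simulate_sumstats(
            g, np.zeros(n_variants), noise_sd=1.0, seed=seed + 10_000 + rep,
            variants=ld.variants,
        )
        rejections += int((table.df["p"] < alpha).sum())
        total += len(table)
    return {"rate": rejections / total, "n_tests": total, "alpha": alpha}
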