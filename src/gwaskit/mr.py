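"""Mendelian randomisation: instrument selection and causal-effect estimation.

Instrument selection is a greedy LD prune over candidate lead variants with
MAF > 1%: (A) move the smallest-p candidate into the instrument set,
(B) remove from the candidate pool every variant whose r^2 with it is at or
above the pruning threshold (default 0.01), (C) repeat until the pool is
empty. The retained instruments therefore satisfy pairwise r^2 < threshold,
which is asserted at construction rather than assumed. cis selection first
restricts candidates to a window (default +/- 200 kb) around the target gene
body and to p < 5e-8.

Estimation combines per-instrument Wald ratios theta_j = by_j / bx_j, with
either first-order variances (sy^2/bx^2) or delta-method variances that also
propagate the exposure uncertainty (sy^2/bx^2 + by^2 sx^2 / bx^4).
The headline estimator is multiplicative random-effects inverse-variance
weighted MR: the fixed-effect IVW point estimate with its standard error
inflated by the residual over-dispersion sqrt(Q / (J - 1)), floored at 1.
MR-Egger adds an intercept capturing average directional pleiotropy, with
instruments oriented so bx > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .ld import LDMatrix
from .sumstats import SummaryStatsTable, harmonize, panel_from_table
from .variants import VariantKey

__all__ = [
    "NoInstrumentsError",
    "InsufficientInstrumentsError",
    "InstrumentSet",
    "MREstimate",
    "select_instruments_genomewide",
    "select_instruments_cis",
    "build_instrument_set",
    "wald_ratio",
    "ivw_mr",
    "mr_egger",
    "fdr_adjust",
]

_Z95 = float(ndtri(0.975))


class NoInstrumentsError(ValueError):
    """No instruments could be selected; the analysis is untestable."""


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator requires."""


def _two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    return 2.0 * ndtr(-np.abs(z))


def _greedy_prune(
    candidates: list[tuple[VariantKey, float]],
    ld: LDMatrix,
    r2_thresh: float,
) -> list[VariantKey]:
    """Steps A-C of the greedy prune; candidates are (key, p) pairs."""
    for key, _ in candidates:
        ld.index_of(key)
    pool = sorted(candidates, key=lambda c: (c[1], str(c[0])))
    selected: list[VariantKey] = []
    while pool:
        lead, _ = pool[0]
        selected.append(lead)
        pool = [
            (k, p) for k, p in pool[1:]
            if ld.r2_between(lead, k) < r2_thresh
        ]
    _certify(selected, ld, r2_thresh)
    return selected


def _certify(keys: Sequence[VariantKey], ld: LDMatrix, r2_thresh: float) -> None:
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            r2 = ld.r2_between(keys[i], keys[j])
            if r2 >= r2_thresh:
                raise AssertionError(
                    f"pruning failed certification: r2({keys[i]}, {keys[j]}) = {r2:.4g}"
                )


def select_instruments_genomewide(
    leads: Sequence[tuple[VariantKey, float, float]],
    ld: LDMatrix,
    r2_thresh: float = 0.01,
    maf_min: float = 0.01,
) -> list[VariantKey]:
    """Greedy LD pruning of (key, p, maf) lead variants with MAF > maf_min."""
    candidates = [(k, p) for k, p, maf in leads if maf > maf_min]
    return _greedy_prune(candidates, ld, r2_thresh)


def select_instruments_cis(
    exposure: SummaryStatsTable,
    gene: tuple[str, int, int],
    ld: LDMatrix,
    window: int = 200_000,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.01,
    maf_min: float = 0.01,
) -> list[VariantKey]:
    """cis instrument selection around a gene body.

    Candidates are variants within [start - window, end + window] on the
    gene's chromosome with MAF > maf_min and p < p_thresh; the same greedy
    prune then enforces pairwise r^2 < r2_thresh. An empty candidate set
    raises :class:`NoInstrumentsError` so callers can report the region as
    untestable.
    """
    chrom, start, end = gene
    if start > end:
        raise ValueError("gene interval start > end")
    df = exposure.df
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    keep = (
        df["chrom"].eq(str(chrom))
        & (df["pos"] >= start - window)
        & (df["pos"] <= end + window)
        & (maf > maf_min)
        & (df["p"] < p_thresh)
    )
    sub = df[keep]
    if sub.empty:
        raise NoInstrumentsError(
            f"no candidate instruments in {chrom}:{start}-{end} +/- {window}"
        )
    candidates = [
        (VariantKey(r.chrom, int(r.pos), r.ref, r.alt), float(r.p))
        for r in sub.itertuples(index=False)
    ]
    return _greedy_prune(candidates, ld, r2_thresh)


@dataclass
class InstrumentSet:
    """Paired exposure/outcome associations at LD-pruned instruments."""

    keys: list[VariantKey]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    selection_mode: str = "genomewide"
    region: Optional[tuple[str, int, int]] = None
    r2_thresh: Optional[float] = None
    n_dropped_unmatched: int = 0

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, dtype=float)
        self.sx = np.asarray(self.sx, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        J = len(self.keys)
        for arr, name in ((self.bx, "bx"), (self.sx, "sx"), (self.by, "by"), (self.sy, "sy")):
            if arr.shape != (J,):
                raise ValueError(f"{name} length must match instrument count")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite {name}")
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.keys)


def build_instrument_set(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    keys: Sequence[VariantKey],
    ld: Optional[LDMatrix] = None,
    r2_thresh: Optional[float] = None,
    selection_mode: str = "genomewide",
    region: Optional[tuple[str, int, int]] = None,
) -> InstrumentSet:
    """Pair exposure and outcome associations at the selected instruments.

    The outcome table is harmonised to the exposure's allele orientation
    first; instruments missing from the outcome are dropped and counted.
    When an LD panel and threshold are given, pairwise r^2 < threshold is
    certified on the final set.
    """
    out_h = harmonize(outcome, panel_from_table(exposure))
    exp_ix = {k: i for i, k in enumerate(exposure.keys())}
    out_ix = {k: i for i, k in enumerate(out_h.keys())}
    kept, dropped = [], 0
    for k in keys:
        if k in exp_ix and k in out_ix:
            kept.append(k)
        else:
            dropped += 1
    if not kept:
        raise NoInstrumentsError("no instruments present in both exposure and outcome")
    ex = exposure.df.iloc[[exp_ix[k] for k in kept]]
    ou = out_h.df.iloc[[out_ix[k] for k in kept]]
    inst = InstrumentSet(
        keys=list(kept),
        bx=ex["beta"].to_numpy(),
        sx=ex["se"].to_numpy(),
        by=ou["beta"].to_numpy(),
        sy=ou["se"].to_numpy(),
        selection_mode=selection_mode,
        region=region,
        r2_thresh=r2_thresh,
        n_dropped_unmatched=dropped,
    )
    if ld is not None and r2_thresh is not None:
        _certify(kept, ld, r2_thresh)
    return inst


def wald_ratio(
    bx: float, sx: float, by: float, sy: float, weighting: str = "delta"
) -> tuple[float, float]:
    """Single-instrument causal-effect ratio and its standard error.

    first_order: se^2 = sy^2 / bx^2; delta adds the exposure-uncertainty
    term by^2 sx^2 / bx^4.
    """
    if bx == 0:
        raise ValueError("exposure effect bx must be non-zero")
    theta = by / bx
    var = sy**2 / bx**2
    if weighting == "delta":
        var += by**2 * sx**2 / bx**4
    elif weighting != "first_order":
        raise ValueError(f"unknown weighting {weighting!r}")
    return theta, float(np.sqrt(var))


@dataclass
class MREstimate:
    """A causal-effect estimate with uncertainty and heterogeneity diagnostics."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    Q: float
    Q_df: int
    Q_p: float
    n_instruments: int
    weighting: str = "delta"
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    single_instrument: bool = False

    def summary(self) -> str:
        lines = [
            f"Mendelian randomisation ({self.method}, {self.weighting} weights)",
            "=" * 64,
            f"instruments: {self.n_instruments}"
            + ("  [single-instrument Wald ratio]" if self.single_instrument else ""),
            f"causal estimate: {self.beta:+.4f}  (se {self.se:.4f})",
            f"95% CI: [{self.ci_low:+.4f}, {self.ci_high:+.4f}]   p = {self.p:.3g}",
        ]
        if self.intercept is not None:
            lines.append(
                f"Egger intercept: {self.intercept:+.4f} (se {self.intercept_se:.4f}, "
                f"p = {self.intercept_p:.3g})"
            )
        if self.Q_df > 0:
            lines.append(
                f"heterogeneity: Q = {self.Q:.2f} on {self.Q_df} df (p = {self.Q_p:.3g})"
            )
        return "\n".join(lines)


def _ratio_arrays(inst: InstrumentSet, weighting: str) -> tuple[np.ndarray, np.ndarray]:
    if np.any(inst.bx == 0):
        raise ValueError("zero exposure effect among instruments")
    theta = inst.by / inst.bx
    var = inst.sy**2 / inst.bx**2
    if weighting == "delta":
        var = var + inst.by**2 * inst.sx**2 / inst.bx**4
    elif weighting != "first_order":
        raise ValueError(f"unknown weighting {weighting!r}")
    return theta, var


def ivw_mr(inst: InstrumentSet, weighting: str = "delta") -> MREstimate:
    """Multiplicative random-effects inverse-variance-weighted MR.

    Fixed-effect point estimate; the standard error is inflated by
    max(1, sqrt(Q / (J - 1))). With a single instrument this degrades to the
    Wald ratio, flagged via ``single_instrument``.
    """
    J = len(inst)
    if J < 1:
        raise NoInstrumentsError("no instruments")
    theta, var = _ratio_arrays(inst, weighting)
    if J == 1:
        b, s = float(theta[0]), float(np.sqrt(var[0]))
        p = float(_two_sided_p(b / s))
        return MREstimate(
            method="ivw_mre", beta=b, se=s, ci_low=b - _Z95 * s, ci_high=b + _Z95 * s,
            p=p, Q=0.0, Q_df=0, Q_p=float("nan"), n_instruments=1,
            weighting=weighting, single_instrument=True,
        )
    w = 1.0 / var
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    Q = float(np.sum(w * (theta - beta) ** 2))
    Q_df = J - 1
    scale = max(1.0, np.sqrt(Q / Q_df))
    se = se_fixed * scale
    p = float(_two_sided_p(beta / se))
    return MREstimate(
        method="ivw_mre", beta=beta, se=se,
        ci_low=beta - _Z95 * se, ci_high=beta + _Z95 * se, p=p,
        Q=Q, Q_df=Q_df, Q_p=float(chi2.sf(Q, Q_df)), n_instruments=J,
        weighting=weighting,
    )


def mr_egger(inst: InstrumentSet, weighting: str = "first_order") -> MREstimate:
    """MR-Egger regression: weighted fit of by on bx with an intercept.

    Instruments are oriented so bx > 0 (flipping bx and by jointly); the
    intercept estimates average directional pleiotropy. Weights are 1/sy^2
    (first_order) or the delta-derived 1/(sy^2 + by^2 sx^2 / bx^2). The
    standard errors carry the same multiplicative random-effects floor as
    IVW, with J - 2 degrees of freedom.
    """
    J = len(inst)
    if J < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 instruments")
    flip = np.sign(inst.bx)
    if np.any(flip == 0):
        raise ValueError("zero exposure effect among instruments")
    bx = inst.bx * flip
    by = inst.by * flip
    if weighting == "first_order":
        w = 1.0 / inst.sy**2
    elif weighting == "delta":
        w = 1.0 / (inst.sy**2 + inst.by**2 * inst.sx**2 / inst.bx**2)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    X = np.column_stack([np.ones(J), bx])
    XtW = X.T * w
    cov_unit = np.linalg.inv(XtW @ X)
    coef = cov_unit @ (XtW @ by)
    resid = by - X @ coef
    Q = float(np.sum(w * resid**2))
    Q_df = J - 2
    scale2 = max(1.0, Q / Q_df)
    cov = cov_unit * scale2
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return MREstimate(
        method="egger", beta=slope, se=se_slope,
        ci_low=slope - _Z95 * se_slope, ci_high=slope + _Z95 * se_slope,
        p=float(_two_sided_p(slope / se_slope)),
        Q=Q, Q_df=Q_df, Q_p=float(chi2.sf(Q, Q_df)), n_instruments=J,
        weighting=weighting,
        intercept=intercept, intercept_se=se_int,
        intercept_p=float(_two_sided_p(intercept / se_int)),
    )


def fdr_adjust(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR rate q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    flags, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
    return flags
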