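"""Synthetic LD-structured genotypes, traits and marginal summary statistics.

Every downstream stage of the toolkit (clumping, colocalisation, MR) is
tested against data with known ground truth generated here. Genotypes come
from a latent-Gaussian threshold model: each haplotype is a stationary AR(1)
Gaussian process over variants (autocorrelation ``ld_decay ** |i-j|``),
thresholded at the per-variant allele frequency quantile, and two haplotypes
sum to a dosage in {0, 1, 2}. This induces the first-order LD structure the
algorithms consume; it is a stand-in for population genotype data, not a
population-genetics model.

Marginal summary statistics are per-variant simple linear regressions of a
quantitative trait y = G @ effects + noise, emulating step-2 single-variant
association testing. For fast calibration runs, :func:`simulate_sumstats_analytic`
draws the marginal z-scores directly from their asymptotic distribution
z ~ MVN(sqrt(n) * R b / sigma_y, R) without materialising genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .ld import LDMatrix
from .sumstats import LoadReport, SummaryStatsTable, _normal_p
from .variants import VariantKey

import pandas as pd

__all__ = [
    "SimulationConfig",
    "TwoTraitScenario",
    "simulate_genotypes",
    "simulate_sumstats",
    "simulate_sumstats_analytic",
    "make_scenario",
    "inverse_normal_transform",
    "default_variant_grid",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated region.

    Defaults describe the standard test regime: a biobank-scale cohort
    (n = 20,000) typed at 500 variants on a 1-kb grid with strong local LD
    (ld_decay = 0.9, giving adjacent-variant latent correlation 0.9) and a
    single strong causal variant of 0.5 trait-SD per allele copy.
    """

    n_samples: int = 20_000
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.9
    # None = one causal variant at the centre of the grid
    causal_index_sets: Optional[tuple[tuple[int, ...], ...]] = None
    causal_effects: tuple[tuple[float, ...], ...] = ((0.5,),)
    noise_sd: float = 1.0
    seed: int = 0
    spacing: int = 1_000
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for idx_set in self.causal_index_sets or ():
            for i in idx_set:
                if not (0 <= i < self.n_variants):
                    raise ValueError(f"causal index {i} out of range")

    def resolved_causal_sets(self) -> tuple[tuple[int, ...], ...]:
        if self.causal_index_sets is None:
            return ((self.n_variants // 2,),)
        return self.causal_index_sets


@dataclass
class TwoTraitScenario:
    """A simulated trait pair with recorded ground truth.

    labels: shared (same causal variant), distinct (separated causal
    variants in one region) or null (trait 2 has no causal variant).
    """

    label: str
    tables: tuple[SummaryStatsTable, SummaryStatsTable]
    ld: LDMatrix
    truth: tuple[tuple[int, ...], tuple[int, ...]]


def default_variant_grid(
    n_variants: int, spacing: int = 1_000, chrom: str = "1", start: int = 1_000
) -> list[VariantKey]:
    """Synthetic variant keys on a uniform position grid, alleles A/G."""
    return [
        VariantKey(chrom=chrom, pos=start + j * spacing, ref="A", alt="G")
        for j in range(n_variants)
    ]


def _ar1_latent(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """n x m stationary AR(1) Gaussian field along the variant axis."""
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if m > 1:
        innov = rng.standard_normal((n, m - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return z


def simulate_genotypes(config: SimulationConfig) -> tuple[np.ndarray, LDMatrix]:
    """Draw an n_samples x n_variants dosage matrix and its empirical LD.

    Two independent latent AR(1) haplotypes per sample are thresholded at the
    allele-frequency quantile and summed, so each dosage is marginally
    Binomial(2, maf). Deterministic given ``config.seed``.
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    cut = ndtri(mafs)
    g = np.zeros((config.n_samples, m), dtype=np.float64)
    for _ in range(2):
        g += _ar1_latent(rng, config.n_samples, m, config.ld_decay) < cut

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(g, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    variants = default_variant_grid(m, spacing=config.spacing, chrom=config.chrom)
    return g, LDMatrix(variants=variants, r=r)


def simulate_sumstats(
    genotypes: np.ndarray,
    effects: Sequence[float],
    noise_sd: float,
    seed: int,
    variants: Optional[Sequence[VariantKey]] = None,
    trait_id: str = "trait",
) -> SummaryStatsTable:
    """Marginal OLS summary statistics for y = G @ effects + Normal(0, noise_sd^2).

    For each variant the returned beta/se/p are the simple-regression slope
    of y on that variant's dosage, its standard error, and the two-sided
    normal p-value. Constant dosage columns are dropped and counted in the
    load report.
    """
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (m,):
        raise ValueError("effects length must match variant count")
    rng = np.random.default_rng(seed)
    y = g @ effects + rng.normal(0.0, noise_sd, size=n)

    gm = g.mean(axis=0)
    gc = g - gm
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    keep = sxx > 0
    report = LoadReport(n_input=m, dropped=int((~keep).sum()))
    sxy = yc @ gc
    syy = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
    p, truncated = _normal_p(np.where(keep, beta / np.where(se > 0, se, 1.0), 0.0))

    if variants is None:
        variants = default_variant_grid(m)
    df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "effect_allele": [v.alt for v in variants],
            "beta": beta,
            "se": se,
            "p": p,
            "eaf": gm / 2.0,
            "n": n,
            "info": np.nan,
            "p_truncated": truncated,
        }
    )
    df = df[keep & (df["eaf"] > 0) & (df["eaf"] < 1)]
    report.n_kept = len(df)
    return SummaryStatsTable(df=df, trait_id=trait_id, load_report=report)


def ar1_correlation(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_sumstats_analytic(
    ld: LDMatrix,
    joint_effects: Sequence[float],
    n: int,
    seed: int,
    maf: float = 0.3,
    noise_sd: float = 1.0,
    trait_id: str = "trait",
) -> SummaryStatsTable:
    """Draw marginal summary statistics from their asymptotic distribution.

    On the standardised-genotype scale the marginal z-scores are
    z ~ MVN(sqrt(n) * R b / sigma_y, R) with sigma_y^2 = b' R b + noise_sd^2;
    per-allele effects in ``joint_effects`` are converted with
    sd(g) = sqrt(2 maf (1 - maf)). Avoids the O(n) cost of genotype-level
    simulation in calibration runs.
    """
    r = ld.r
    m = len(ld)
    sd_g = np.sqrt(2.0 * maf * (1.0 - maf))
    b = np.asarray(joint_effects, dtype=float) * sd_g
    if b.shape != (m,):
        raise ValueError("joint_effects length must match LD panel")
    sigma_y = float(np.sqrt(b @ r @ b + noise_sd**2))
    mean_z = np.sqrt(n) * (r @ b) / sigma_y
    # small jitter keeps the Cholesky stable for near-singular empirical panels
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))
    rng = np.random.default_rng(seed)
    z = mean_z + chol @ rng.standard_normal(m)
    se = sigma_y / (np.sqrt(n) * sd_g)
    beta = z * se
    p, truncated = _normal_p(z)
    df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in ld.variants],
            "pos": [v.pos for v in ld.variants],
            "ref": [v.ref for v in ld.variants],
            "alt": [v.alt for v in ld.variants],
            "effect_allele": [v.alt for v in ld.variants],
            "beta": beta,
            "se": se,
            "p": p,
            "eaf": maf,
            "n": n,
            "info": np.nan,
            "p_truncated": truncated,
        }
    )
    return SummaryStatsTable(df=df, trait_id=trait_id)


_DISTINCT_SEPARATION = 50


def make_scenario(
    label: str, config: SimulationConfig, analytic: bool = False
) -> TwoTraitScenario:
    """Build a two-trait scenario for colocalisation testing.

    shared: both traits share one causal variant; distinct: causal variants
    at least 50 grid positions apart in the same region; null: trait 2 has
    no causal variant. Ground-truth causal indices are recorded.
    """
    if label not in ("shared", "distinct", "null"):
        raise ValueError(f"unknown scenario label {label!r}")
    m = config.n_variants
    center = m // 2
    effect = config.causal_effects[0][0] if config.causal_effects and config.causal_effects[0] else 0.5
    if label == "shared":
        truth = ((center,), (center,))
    elif label == "distinct":
        half = _DISTINCT_SEPARATION // 2
        if center - half < 0 or center + half >= m:
            raise ValueError("region too small for distinct-variant separation")
        truth = ((center - half,), (center + half,))
    else:
        truth = ((center,), ())

    effects = []
    for idx_set in truth:
        e = np.zeros(m)
        for i in idx_set:
            e[i] = effect
        effects.append(e)

    if analytic:
        ld = LDMatrix(
            variants=default_variant_grid(m, spacing=config.spacing, chrom=config.chrom),
            r=ar1_correlation(m, config.ld_decay),
        )
        tables = tuple(
            simulate_sumstats_analytic(
                ld,
                effects[t],
                n=config.n_samples,
                seed=config.seed * 2 + t,
                noise_sd=config.noise_sd,
                trait_id=f"trait{t + 1}",
            )
            for t in range(2)
        )
    else:
        g, ld = simulate_genotypes(config)
        tables = tuple(
            simulate_sumstats(
                g,
                effects[t],
                noise_sd=config.noise_sd,
                seed=config.seed * 2 + t + 1,
                variants=ld.variants,
                trait_id=f"trait{t + 1}",
            )
            for t in range(2)
        )
    return TwoTraitScenario(label=label, tables=tables, ld=ld, truth=truth)


def inverse_normal_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    output_i = Phi^-1((rank_i - 3/8) / (n + 1/4)), average ranks for ties.
    Monotone in the input ranks; requires at least two distinct values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    if np.all(x == x[0]):
        raise ValueError("all values identical; transform undefined")
    ranks = rankdata(x, method="average")
    return ndtri((ranks - 0.375) / (x.size + 0.25))
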