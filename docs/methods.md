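# Methods

This note records the statistical models the toolkit implements, the
conventions and tunable parameters, what the simulator does and does not
emulate, and the numerical choices made where the design was open.

## Summary-statistics model and conventions

A record is a marginal single-variant association: effect `beta` (trait SD
per effect-allele copy), its standard error `se > 0`, two-sided p-value,
effect-allele frequency `eaf ∈ (0,1)`, sample size `n`, and optional
imputation INFO. The minor allele count is `MAC = 2·n·min(eaf, 1−eaf)`.
Positions are 1-based and all windows are **closed** intervals: a ±1 Mb
region includes variants exactly 1 Mb from the centre. This choice is a
convention — the boundary-inclusive reading of "± window" prose — and is
applied uniformly (region extraction, locus width, cis windows).

Threshold conventions follow the wording they come from: p-value cuts are
strict (`p < 5×10⁻⁸`), MAC/INFO cuts inclusive (`≥ 20`, `≥ 0.6`). A missing
INFO passes the INFO filter, since meta-analysed columns often lack it.
Harmonisation matches variants by position and allele set, flips beta and
eaf when the effect allele is oriented the other way, and drops (with a
count) anything unmatched. Palindromic A/T and C/G variants are matched by
allele identity only; no frequency-based strand inference is attempted —
the simplest auditable rule, with palindromic counts surfaced in the load
report. p-values that underflow the smallest positive normal double are
stored at that minimum and flagged `p_truncated`; the z/p consistency check
(two-sided normal, tolerance 10⁻⁶) is waived for flagged rows.

## Fixed-effect IVW meta-analysis

Weights are inverse variances, `w_i = 1/se_i²`; the combined estimate,
standard error and p-value are `Σw_iβ_i/Σw_i`, `(Σw_i)^(−1/2)` and the
two-sided normal tail of their ratio (z-based rather than an equivalent
chi-square). Variants observed in a single cohort are reported with
`k_studies = 1` rather than dropped, because panels with very unequal
variant coverage are the normal case. No heterogeneity filtering happens at
this stage; Cochran's Q lives in the MR module where it informs the
random-effects scale. Conflicting effect alleles for a shared key are an
error: harmonisation is the caller's explicit step, and silent flipping
would hide upstream mistakes.

## Locus definition and lead clustering

Clumping is greedy: among unassigned genome-wide-significant variants, the
smallest p leads a locus and claims everything within ± half the locus
width (default 2 Mb total) on its chromosome; repeat until none remain.
Loci whose leads are in LD (`r² ≥ 0.05`) are then merged. Merging is
implemented as transitive single-linkage over the *original* locus leads —
the only order-independent reading — so the result is already a fixed
point: the merged locus keeps the smallest-p original lead, and no two
surviving leads can exceed the threshold. Cross-trait clustering is plain
single-linkage (union-find) at `r² ≥ 0.8` with the smallest-p member as the
cluster lead. Everywhere, p-value ties break on the canonical variant
string for full determinism, cross-chromosome r² is 0 by convention, and a
significant variant absent from the LD panel raises rather than silently
assuming independence — panel mismatches should surface, not vanish.

## Colocalisation

Per-variant evidence is the Wakefield log approximate Bayes factor
`labf = ½[ln(V/(V+W)) + z²·W/(V+W)]` with `V = se²`, `z = β/se` and prior
effect-size SD `√W = 0.15` (the quantitative-trait convention; binary-
outcome GWAS are treated identically through their beta/se, and the prior
SD is configurable). With per-variant priors `p1 = p2 = 10⁻⁴`,
`p12 = 10⁻⁶` over Q shared variants, the five-hypothesis evidence terms are

    ℓ0 = 0                      ℓ1 = ln p1 + L1         ℓ2 = ln p2 + L2
    ℓ3 = ln p1 + ln p2 + logdiffexp(L1+L2, L12)         ℓ4 = ln p12 + L12

with `L1, L2, L12` the log-sum-exp of `labf_a`, `labf_b`, `labf_a+labf_b`.
All arithmetic stays in log space; `logdiffexp` clamps to −∞ when the
difference underflows, which is the legitimate outcome at Q = 1 (pp3 = 0)
and under extreme concentration, not an error. Variant intersection is by
exact key after harmonisation; no positional fuzzy matching. The batched
all-pairs engine chunks `L12` row-wise to bound memory; its contract —
checked in the tests — is agreement with the scalar per-pair path to 10⁻⁸
at any batch size. An optional acceleration backend could sit behind the
same contract; the vectorised CPU path is the reference implementation.

## Mendelian randomisation

Greedy pruning retains instruments with pairwise `r² < 0.01` (MAF > 1%):
take the smallest-p candidate, discard everything correlated with it at or
above the threshold, repeat. Retention, not discarding, is the side that
satisfies `r² < 0.01`; the final set is certified by exhaustive pairwise
check rather than assumed. cis selection first restricts to
`[gene start − 200 kb, gene end + 200 kb]` and `p < 5×10⁻⁸`; an empty
candidate set raises a typed error so pipelines can count untestable genes.
Gene intervals are caller-supplied — no annotation database dependency.
Instruments missing from the outcome are dropped and counted; no proxy
search is attempted.

Per-instrument ratios use first-order (`sy²/bx²`) or delta
(`sy²/bx² + by²sx²/bx⁴`) variances; delta weights are recomputed from the
observed estimates at each use, with no iterative reweighting by the causal
estimate. IVW is multiplicative random effects: fixed-effect point
estimate, SE inflated by `max(1, √(Q/(J−1)))`, 95% CI at the normal
quantile. MR-Egger orients instruments to `bx > 0` (the standard
convention; flipping bx and by jointly), fits weighted least squares with
an intercept (weights `1/sy²` by default; a delta variant
`1/(sy² + by²sx²/bx²)` is available since the weighting for Egger is
genuinely open), and applies the same over-dispersion floor with J−2
degrees of freedom. FDR summarisation is Benjamini–Hochberg step-up.

## The simulator: what it emulates and what it does not

Genotypes come from a latent-Gaussian threshold model: per haplotype, a
stationary AR(1) process over variants (autocorrelation `ld_decay^|i−j|`,
default 0.9) thresholded at the allele-frequency quantile; two haplotypes
sum to a Binomial(2, maf) dosage. This induces realistic-looking local LD
decay — note that thresholding attenuates the dosage correlation below the
latent value, more strongly at low MAF — and is exactly what the clumping,
pruning and coloc code consume. It is **not** a population-genetics model:
no recombination maps, no allele-frequency spectrum, no relatedness, no
binary traits. Passing tests demonstrate algorithmic correctness under
first-order LD, not robustness to the full complexity of biobank data.

Traits are `y = G·effects + Normal(0, noise_sd²)` and summary statistics
are per-variant simple OLS with normal p-values. The default regime —
n = 20,000, 500 variants on a 1-kb grid, MAF ∈ (0.05, 0.5), one causal
variant of 0.5 SD per allele, unit noise — gives the causal variant
z ≈ 40: the strong-signal regime in which colocalisation and MR are
normally attempted. The rank-based inverse normal transform uses the Blom
offset, `Φ⁻¹((rank−3/8)/(n+¼))`, with average ranks for ties; the offset
and tie rule are conventions, chosen once.

For calibration runs the marginal statistics can instead be drawn from
their asymptotic distribution, `z ~ MVN(√n·Rb/σ_y, R)` on the standardised-
genotype scale (σ_y² = b'Rb + noise_sd²), skipping the O(n·m) genotype
cost. A 10⁻¹⁰ diagonal jitter keeps the Cholesky stable for near-singular
panels. The two-trait scenarios place the causal variant(s) at the grid
centre: shared uses one variant for both traits, distinct separates the two
causal variants by 50 grid positions (latent correlation 0.9⁵⁰ ≈ 5×10⁻³,
effectively independent), and null leaves trait 2 with no causal variant —
so the expected coloc verdicts are H4, H3, and "no colocalisation"
(posterior mass on H0/H1, since trait 1 keeps its signal) respectively.

## Problem sizes and numerical choices in the evaluation suites

The calibration suites use 100 regions per scenario at n = 20,000 and 200
variants via the analytic draw; MR recovery uses 100 replicates per cell of
J ∈ {10, 50} × β ∈ {0, 0.5} with minimum instrument F ≈ 225; the type-I
check uses 50 replicates of 500 LD-free variants at n = 1,000, where
per-variant rejections are independent and binomial bounds apply. These
sizes give Monte-Carlo error comfortably inside the asserted margins while
keeping the whole suite fast.

## Known limitations

- No VCF parsing, liftover, or multi-allelic decomposition; input is the
  toolkit's own TSV/Parquet schema.
- Colocalisation assumes at most one causal variant per trait per region
  (the single-variant ABF assumption); multi-signal data enter only as
  externally fine-mapped per-signal Bayes-factor rows.
- No random-effects meta-analysis, sample-overlap correction, Steiger
  filtering, bidirectional MR, or proxy-instrument search.
- The simulator's LD is first-order autoregressive; long-range LD,
  structural variation and population structure are out of scope.
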