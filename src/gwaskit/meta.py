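"""Fixed-effect inverse-variance-weighted meta-analysis across cohorts.

Per variant, each contributing cohort i enters with weight w_i = 1/se_i^2:

    beta_meta = sum(w_i beta_i) / sum(w_i),   se_meta = sum(w_i)^(-1/2)

and the meta p-value is the two-sided normal tail of beta_meta/se_meta.
Variants present in only a subset of cohorts are meta-analysed over the
cohorts that observe them (k_studies records how many contributed); cohorts
with unequal variant coverage are the norm. Tables must already share a
common allele orientation — a shared key with conflicting effect alleles is
an error, not silently flipped.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import SummaryStatsTable, _normal_p

__all__ = ["ivw_fixed_meta"]

_KEY = ["chrom", "pos", "ref", "alt"]


def ivw_fixed_meta(
    tables: Sequence[SummaryStatsTable], trait_id: str = ""
) -> SummaryStatsTable:
    """Fixed-effect IVW meta-analysis of harmonised cohort tables.

    Returns a :class:`SummaryStatsTable` whose beta/se/p are the meta-analysed
    values, with ``n`` the summed sample size over contributing cohorts, an
    ``eaf`` that is the sample-size-weighted mean frequency, and an extra
    ``k_studies`` column. Raises ValueError when a shared variant key carries
    conflicting effect alleles across cohorts.
    """
    if not tables:
        raise ValueError("need at least one cohort table")
    frames = [t.df.assign(_cohort=i) for i, t in enumerate(tables)]
    all_df = pd.concat(frames, ignore_index=True)

    ea_counts = all_df.groupby(_KEY)["effect_allele"].nunique()
    conflicts = ea_counts[ea_counts > 1]
    if len(conflicts):
        chrom, pos, ref, alt = conflicts.index[0]
        raise ValueError(
            f"conflicting effect alleles for variant {chrom}-{pos}-{ref}-{alt}; "
            "harmonise cohorts to a common orientation first"
        )

    w = 1.0 / all_df["se"].to_numpy() ** 2
    all_df = all_df.assign(_w=w, _wb=w * all_df["beta"].to_numpy(), _nf=all_df["n"].astype(float))
    all_df = all_df.assign(_nf_eaf=all_df["_nf"] * all_df["eaf"])

    grouped = all_df.groupby(_KEY, sort=False).agg(
        effect_allele=("effect_allele", "first"),
        _w=("_w", "sum"),
        _wb=("_wb", "sum"),
        n=("n", "sum"),
        _nf=("_nf", "sum"),
        _nf_eaf=("_nf_eaf", "sum"),
        k_studies=("_cohort", "nunique"),
    )
    beta = (grouped["_wb"] / grouped["_w"]).to_numpy()
    se = 1.0 / np.sqrt(grouped["_w"].to_numpy())
    p, truncated = _normal_p(beta / se)

    out = grouped.reset_index()[_KEY + ["effect_allele", "n", "k_studies"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["p_truncated"] = truncated
    out["eaf"] = (grouped["_nf_eaf"] / grouped["_nf"]).to_numpy()
    out["info"] = np.nan
    return SummaryStatsTable(df=out, trait_id=trait_id)
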