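"""GWAS summary-statistics tables: data model, I/O, harmonisation, filtering.

The central container is :class:`SummaryStatsTable`, a thin wrapper around a
pandas DataFrame with one row per variant and the columns

    chrom, pos, ref, alt, effect_allele, beta, se, p, eaf, n, info

``beta`` is the marginal per-effect-allele-copy effect in trait SD units,
``se`` its standard error, ``p`` the two-sided association p-value, ``eaf``
the effect-allele frequency, ``n`` the sample size and ``info`` the
imputation quality (may be missing). Tables are kept sorted by
(chrom, pos, ref, alt) with unique variant keys.

p-values smaller than the smallest positive normal double are stored as that
minimum and flagged in the boolean ``p_truncated`` column; the z/p
consistency check is waived for flagged rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .variants import VariantKey, chrom_rank

__all__ = [
    "COLUMNS",
    "LoadReport",
    "SummaryStatsTable",
    "SumstatsFormatError",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "extract_region",
    "significance_filter",
    "panel_from_table",
]

COLUMNS = ["chrom", "pos", "ref", "alt", "effect_allele", "beta", "se", "p", "eaf", "n", "info"]
_REQUIRED = [c for c in COLUMNS if c != "info"]
_NUMERIC = ["pos", "beta", "se", "p", "eaf", "n"]

P_MIN = float(np.finfo(np.float64).tiny)


class SumstatsFormatError(ValueError):
    """Raised for malformed summary-statistics input (missing columns, duplicates)."""


@dataclass
class LoadReport:
    """Row accounting for a read or harmonisation pass."""

    n_input: int = 0
    n_kept: int = 0
    dropped: int = 0
    dropped_unparseable: int = 0
    dropped_invalid: int = 0
    dropped_unmatched: int = 0
    n_palindromic: int = 0
    n_truncated_p: int = 0


def _normal_p(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided normal p-value with underflow truncation flag."""
    p = 2.0 * ndtr(-np.abs(np.asarray(z, dtype=float)))
    truncated = p < P_MIN
    return np.where(truncated, P_MIN, p), truncated


@dataclass
class SummaryStatsTable:
    """One trait's per-variant marginal association records."""

    df: pd.DataFrame
    trait_id: str = ""
    genome_build: str = "GRCh38"
    load_report: Optional[LoadReport] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise SumstatsFormatError(f"missing required column(s): {', '.join(missing)}")
        if "info" not in df.columns:
            df["info"] = np.nan
        if "p_truncated" not in df.columns:
            df["p_truncated"] = False
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        for c in ("beta", "se", "p", "eaf", "info"):
            df[c] = df[c].astype(float)
        df["n"] = df["n"].astype(np.int64)
        df = _sort(df)
        dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            key = f"{first.chrom}-{first.pos}-{first.ref}-{first.alt}"
            raise SumstatsFormatError(f"duplicate variant key: {key}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
            for r in self.df.itertuples(index=False)
        ]

    @property
    def mac(self) -> np.ndarray:
        """Minor allele count 2*n*min(eaf, 1-eaf) per variant."""
        eaf = self.df["eaf"].to_numpy()
        return 2.0 * self.df["n"].to_numpy() * np.minimum(eaf, 1.0 - eaf)

    def validate(self, z_p_tol: float = 1e-6) -> None:
        """Check record invariants; raise ValueError on the first violation."""
        df = self.df
        if (df["se"] <= 0).any():
            raise ValueError("non-positive standard error")
        if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
            raise ValueError("effect-allele frequency outside (0, 1)")
        if ((df["p"] <= 0) | (df["p"] > 1)).any():
            raise ValueError("p-value outside (0, 1]")
        bad_ea = ~(df["effect_allele"].eq(df["ref"]) | df["effect_allele"].eq(df["alt"]))
        if bad_ea.any():
            raise ValueError("effect_allele must equal ref or alt")
        ok = df["p_truncated"].to_numpy(dtype=bool)
        expected, _ = _normal_p(df["beta"].to_numpy() / df["se"].to_numpy())
        mismatch = (~ok) & (np.abs(expected - df["p"].to_numpy()) > z_p_tol)
        if mismatch.any():
            i = int(np.argmax(mismatch))
            raise ValueError(f"p inconsistent with beta/se at row {i}")

    def with_df(self, df: pd.DataFrame, report: Optional[LoadReport] = None) -> "SummaryStatsTable":
        return SummaryStatsTable(
            df=df, trait_id=self.trait_id, genome_build=self.genome_build, load_report=report
        )


def _sort(df: pd.DataFrame) -> pd.DataFrame:
    rank = df["chrom"].map(chrom_rank)
    order = np.lexsort((df["alt"], df["ref"], df["pos"], rank))
    return df.iloc[order]


def read_sumstats(
    path: Union[str, Path],
    format: Optional[str] = None,
    trait_id: str = "",
    genome_build: str = "GRCh38",
) -> SummaryStatsTable:
    """Read a summary-statistics table from TSV or Parquet.

    Rows with unparseable or invalid numeric fields are dropped and counted
    in ``table.load_report``. Missing ``info`` values are allowed; a missing
    required column or a duplicated variant key raises
    :class:`SumstatsFormatError`.
    """
    path = Path(path)
    fmt = format or ("parquet" if path.suffix == ".parquet" else "tsv")
    if fmt == "parquet":
        df = pd.read_parquet(path)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=[".", "NA"], keep_default_na=True)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"missing required column(s): {', '.join(missing)}")
    if "info" not in df.columns:
        df["info"] = np.nan

    report = LoadReport(n_input=len(df))
    for c in _NUMERIC:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["info"] = pd.to_numeric(df["info"], errors="coerce")
    parseable = df[_NUMERIC].notna().all(axis=1)
    report.dropped_unparseable = int((~parseable).sum())
    df = df[parseable]

    valid = (
        (df["se"] > 0)
        & (df["eaf"] > 0)
        & (df["eaf"] < 1)
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & (df["n"] > 0)
        & (df["effect_allele"].eq(df["ref"]) | df["effect_allele"].eq(df["alt"]))
    )
    report.dropped_invalid = int((~valid).sum())
    df = df[valid].copy()
    if "p_truncated" in df.columns:
        if df["p_truncated"].dtype == object:  # TSV: "True"/"False" strings
            df["p_truncated"] = df["p_truncated"].astype(str).str.lower().eq("true")
        else:
            df["p_truncated"] = df["p_truncated"].astype(bool)
    else:
        df["p_truncated"] = df["p"] <= P_MIN
    report.dropped = report.dropped_unparseable + report.dropped_invalid
    report.n_kept = len(df)
    report.n_truncated_p = int(df["p_truncated"].sum())
    pal = {frozenset(("A", "T")), frozenset(("C", "G"))}
    report.n_palindromic = int(
        df.apply(lambda r: frozenset((r["ref"], r["alt"])) in pal, axis=1).sum()
    ) if len(df) else 0
    return SummaryStatsTable(
        df=df, trait_id=trait_id, genome_build=genome_build, load_report=report
    )


def write_sumstats(table: SummaryStatsTable, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write a table to TSV (full decimal precision) or Parquet (lossless)."""
    path = Path(path)
    fmt = format or ("parquet" if path.suffix == ".parquet" else "tsv")
    out = table.df[COLUMNS + ["p_truncated"]]
    if fmt == "parquet":
        out.to_parquet(path, index=False)
    elif fmt == "tsv":
        out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def panel_from_table(table: SummaryStatsTable) -> pd.DataFrame:
    """Derive a harmonisation panel (chrom,pos,ref,alt,effect_allele) from a table."""
    return table.df[["chrom", "pos", "ref", "alt", "effect_allele"]].copy()


def _as_panel(panel) -> pd.DataFrame:
    if isinstance(panel, SummaryStatsTable):
        return panel_from_table(panel)
    if isinstance(panel, pd.DataFrame):
        need = {"chrom", "pos", "ref", "alt", "effect_allele"}
        missing = need - set(panel.columns)
        if missing:
            raise SumstatsFormatError(f"panel missing column(s): {', '.join(sorted(missing))}")
        return panel
    # iterable of (VariantKey, effect_allele)
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "effect_allele": ea}
        for k, ea in panel
    ]
    return pd.DataFrame(rows)


def harmonize(table: SummaryStatsTable, panel) -> SummaryStatsTable:
    """Orient effect alleles to a reference panel.

    Records are matched to the panel by position and allele set. Where the
    table's effect allele differs from the panel's, the orientation is
    flipped: beta := -beta, eaf := 1 - eaf. Records absent from the panel, or
    whose alleles do not match the panel's {ref, alt}, are dropped and
    counted in the returned table's ``load_report``. Palindromic (A/T, C/G)
    variants are matched by allele identity only — no strand inference.
    """
    pan = _as_panel(panel).rename(
        columns={"ref": "panel_ref", "alt": "panel_alt", "effect_allele": "panel_ea"}
    )
    pan = pan.copy()
    pan["chrom"] = pan["chrom"].astype(str)
    pan["pos"] = pan["pos"].astype(np.int64)
    if pan.duplicated(subset=["chrom", "pos", "panel_ref", "panel_alt"]).any():
        raise SumstatsFormatError("panel contains duplicate variant keys")

    df = table.df.merge(pan, on=["chrom", "pos"], how="left")
    same = df["ref"].eq(df["panel_ref"]) & df["alt"].eq(df["panel_alt"])
    swapped = df["ref"].eq(df["panel_alt"]) & df["alt"].eq(df["panel_ref"])
    matched = same | swapped
    report = LoadReport(n_input=len(table.df))
    report.dropped_unmatched = int((~matched).sum())
    report.dropped = report.dropped_unmatched
    df = df[matched].copy()

    # align key orientation to panel, then effect allele
    df["ref"] = df["panel_ref"]
    df["alt"] = df["panel_alt"]
    flip = ~df["effect_allele"].eq(df["panel_ea"])
    df.loc[flip, "beta"] = -df.loc[flip, "beta"]
    df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
    df["effect_allele"] = df["panel_ea"]
    df = df.drop(columns=["panel_ref", "panel_alt", "panel_ea"])
    report.n_kept = len(df)
    return table.with_df(df, report=report)


def extract_region(
    table: SummaryStatsTable, center: VariantKey, half_window: int
) -> SummaryStatsTable:
    """Records on center's chromosome within the closed interval
    [center.pos - half_window, center.pos + half_window]."""
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    df = table.df
    keep = df["chrom"].eq(center.chrom) & (df["pos"] - center.pos).abs().le(half_window)
    return table.with_df(df[keep])


def significance_filter(
    table: SummaryStatsTable,
    p_max: float = 5e-8,
    mac_min: float = 20.0,
    info_min: float = 0.6,
) -> SummaryStatsTable:
    """Keep records with p < p_max, MAC >= mac_min and INFO >= info_min.

    The p comparison is strict; MAC/INFO are inclusive; a missing INFO value
    passes the INFO filter (meta-analysed columns may lack it).
    """
    df = table.df
    info = df["info"]
    keep = (
        (df["p"] < p_max)
        & (table.mac >= mac_min)
        & (info.isna() | (info >= info_min))
    )
    return table.with_df(df[keep])
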