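"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from gwaskit import LDMatrix, SummaryStatsTable, default_variant_grid


def normal_p(z):
    return 2.0 * ndtr(-np.abs(np.asarray(z, dtype=float)))


def make_table(
    betas,
    ses,
    positions=None,
    chrom="1",
    eaf=0.3,
    n=10_000,
    info=None,
    trait_id="trait",
    effect_is_alt=True,
):
    """Build a valid SummaryStatsTable from effect estimates."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    m = betas.size
    if positions is None:
        positions = 1_000 + 1_000 * np.arange(m)
    eaf = np.broadcast_to(np.asarray(eaf, dtype=float), (m,))
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": "A",
            "alt": "G",
            "effect_allele": "G" if effect_is_alt else "A",
            "beta": betas,
            "se": ses,
            "p": normal_p(betas / ses),
            "eaf": eaf,
            "n": n,
            "info": np.nan if info is None else info,
        }
    )
    return SummaryStatsTable(df=df, trait_id=trait_id)


def random_ld(rng, m, n_latent=400):
    """A random valid LD matrix: empirical correlation of a Gaussian sample."""
    x = rng.standard_normal((n_latent, m))
    # mix columns to create correlation structure
    mix = rng.standard_normal((m, m)) * 0.3 + np.eye(m)
    r = np.corrcoef(x @ mix, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(variants=default_variant_grid(m), r=r)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
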