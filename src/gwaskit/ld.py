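"""Linkage-disequilibrium matrices of signed correlations r.

The toolkit consumes LD as a dense square matrix of signed dosage
correlations over an ordered variant panel; r-squared is derived on demand.
On-disk form is a square TSV with the canonical variant strings as both the
header row and the index column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .variants import VariantKey

__all__ = ["LDMatrix", "read_ld_tsv", "write_ld_tsv"]

PSD_TOL = 1e-8


class VariantNotInPanelError(KeyError):
    """A variant required by an algorithm is absent from the LD panel."""


@dataclass
class LDMatrix:
    """Signed pairwise correlation r over an ordered variant panel.

    Invariants (checked by :meth:`validate`): symmetric, unit diagonal,
    all |r| <= 1, positive semi-definite within a small tolerance.
    """

    variants: list[VariantKey]
    r: np.ndarray
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.variants), len(self.variants)):
            raise ValueError("r must be square with one row per variant")
        self._index = {v: i for i, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("duplicate variants in LD panel")

    def __len__(self) -> int:
        return len(self.variants)

    def validate(self, psd_tol: float = PSD_TOL) -> None:
        r = self.r
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("|r| > 1 in LD matrix")
        w = np.linalg.eigvalsh((r + r.T) / 2.0)
        if w.min() < -psd_tol:
            raise ValueError(f"LD matrix not PSD: min eigenvalue {w.min():.3g}")

    def index_of(self, key: VariantKey) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise VariantNotInPanelError(f"variant {key} not in LD panel") from None

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._index

    def r_between(self, a: VariantKey, b: VariantKey) -> float:
        """Signed r; cross-chromosome pairs are 0 by convention."""
        if a.chrom != b.chrom:
            return 0.0
        return float(self.r[self.index_of(a), self.index_of(b)])

    def r2_between(self, a: VariantKey, b: VariantKey) -> float:
        return self.r_between(a, b) ** 2

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def subset(self, keys: Sequence[VariantKey]) -> "LDMatrix":
        idx = [self.index_of(k) for k in keys]
        return LDMatrix(variants=list(keys), r=self.r[np.ix_(idx, idx)])


def write_ld_tsv(ld: LDMatrix, path: Union[str, Path]) -> None:
    labels = [str(v) for v in ld.variants]
    pd.DataFrame(ld.r, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_ld_tsv(path: Union[str, Path]) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("LD TSV header and index disagree")
    variants = [VariantKey.parse(s) for s in df.columns]
    return LDMatrix(variants=variants, r=df.to_numpy(dtype=float))
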