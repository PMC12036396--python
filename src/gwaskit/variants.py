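"""Variant identity: chromosome-position-ref-alt keys.

Variants are identified throughout the toolkit by the canonical string form
``chrom-pos-ref-alt`` (e.g. ``19-41414070-A-G``) on a single named genome
build. Positions are 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["VariantKey", "chrom_rank"]

_VALID_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X",)
_DNA_RE = re.compile(r"^[ACGT]+$")


def chrom_rank(chrom: str) -> int:
    """Sort rank for chromosome labels: 1..22 numerically, then X."""
    if chrom == "X":
        return 23
    try:
        return int(chrom)
    except ValueError:
        # unknown labels sort after X, alphabetically via a stable large rank
        return 24


@dataclass(frozen=True)
class VariantKey:
    """Immutable identifier for a bi-allelic variant.

    Parameters
    ----------
    chrom : str
        Chromosome label ("1".."22", "X").
    pos : int
        1-based base-pair position.
    ref, alt : str
        Reference and alternative alleles (non-empty DNA strings, ref != alt).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not _DNA_RE.match(allele):
                raise ValueError(f"invalid allele {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref}")

    def __str__(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse the canonical ``chrom-pos-ref-alt`` form."""
        parts = text.strip().split("-")
        if len(parts) != 4:
            raise ValueError(f"cannot parse variant key {text!r}")
        chrom, pos, ref, alt = parts
        return cls(chrom=chrom, pos=int(pos), ref=ref, alt=alt)

    @property
    def sort_key(self) -> tuple:
        return (chrom_rank(self.chrom), self.pos, self.ref, self.alt)

    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T or C/G variants."""
        pair = {self.ref, self.alt}
        return pair == {"A", "T"} or pair == {"C", "G"}
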