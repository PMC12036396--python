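"""Lead-variant / locus definition and cross-trait lead-variant clustering.

Locus definition is a greedy clump: iterate over genome-wide-significant
variants, take the unassigned one with the smallest p-value as a lead,
assign every unassigned significant variant within half the locus width on
the same chromosome to its locus, and repeat. Same-chromosome loci whose
leads are in LD (r^2 at or above the merge threshold) are then merged,
iterating to a fixed point; the merged lead is the smaller-p lead and the
span is the union of spans.

Cross-trait clustering joins lead variants (possibly from many traits) into
single-linkage connected components of the graph with edges r^2 >= threshold;
each cluster is represented by its smallest-p member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ld import LDMatrix
from .sumstats import SummaryStatsTable, significance_filter
from .variants import VariantKey

__all__ = ["Locus", "LeadCluster", "define_loci", "cluster_leads"]


@dataclass
class Locus:
    """A clumped association locus for one trait."""

    trait_id: str
    lead: VariantKey
    lead_p: float
    start: int
    end: int
    member_keys: list[VariantKey]

    def __len__(self) -> int:
        return len(self.member_keys)


@dataclass
class LeadCluster:
    """A cross-trait cluster of lead variants linked by LD."""

    members: list[tuple[str, VariantKey, float]]
    cluster_lead: tuple[str, VariantKey, float]


def _p_order_key(p: float, key: VariantKey) -> tuple:
    # deterministic: p ascending, ties broken by canonical variant string
    return (p, str(key))


def define_loci(
    table: SummaryStatsTable,
    ld: LDMatrix,
    p_thresh: float = 5e-8,
    locus_width: int = 2_000_000,
    merge_r2: float = 0.05,
) -> list[Locus]:
    """Greedy locus definition with LD-based merging.

    All significant variants must be present in the LD panel (an absent one
    raises, to surface panel mismatches rather than silently assuming r=0).
    ``locus_width`` is the full window; members fall within +/- width/2 of
    the lead (closed interval).
    """
    if locus_width % 2:
        raise ValueError("locus_width must be even")
    sig = significance_filter(table, p_max=p_thresh, mac_min=0.0, info_min=0.0)
    entries = [
        (VariantKey(r.chrom, int(r.pos), r.ref, r.alt), float(r.p))
        for r in sig.df.itertuples(index=False)
    ]
    for key, _ in entries:
        ld.index_of(key)  # raises VariantNotInPanelError if absent

    half = locus_width // 2
    unassigned = sorted(entries, key=lambda e: _p_order_key(e[1], e[0]))
    loci: list[Locus] = []
    while unassigned:
        lead, lead_p = unassigned[0]
        members = [
            (k, p)
            for k, p in unassigned
            if k.chrom == lead.chrom and abs(k.pos - lead.pos) <= half
        ]
        member_keys = [k for k, _ in members]
        loci.append(
            Locus(
                trait_id=table.trait_id,
                lead=lead,
                lead_p=lead_p,
                start=min(k.pos for k in member_keys),
                end=max(k.pos for k in member_keys),
                member_keys=member_keys,
            )
        )
        taken = set(member_keys)
        unassigned = [(k, p) for k, p in unassigned if k not in taken]

    return _merge_loci(loci, ld, merge_r2)


def _merge_loci(loci: list[Locus], ld: LDMatrix, merge_r2: float) -> list[Locus]:
    """Merge loci whose leads are linked by r^2 >= merge_r2.

    Transitive single-linkage over the original locus leads (same chromosome
    only), so the result is independent of merge order and already a fixed
    point: re-merging the output changes nothing, because each merged locus
    keeps the smallest-p original lead and links are defined on leads.
    """
    n = len(loci)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if loci[i].lead.chrom != loci[j].lead.chrom:
                continue
            if ld.r2_between(loci[i].lead, loci[j].lead) >= merge_r2:
                parent[find(j)] = find(i)

    groups: dict[int, list[Locus]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(loci[i])

    merged: list[Locus] = []
    for group in groups.values():
        best = min(group, key=lambda l: _p_order_key(l.lead_p, l.lead))
        merged.append(
            Locus(
                trait_id=best.trait_id,
                lead=best.lead,
                lead_p=best.lead_p,
                start=min(l.start for l in group),
                end=max(l.end for l in group),
                member_keys=[k for l in group for k in l.member_keys],
            )
        )
    merged.sort(key=lambda l: (l.lead.sort_key, l.lead_p))
    return merged


def cluster_leads(
    leads: Sequence[tuple[str, VariantKey, float]],
    ld: LDMatrix,
    r2_thresh: float = 0.8,
) -> list[LeadCluster]:
    """Single-linkage clustering of lead variants at an r^2 threshold.

    Connected components (union-find) of the graph whose edges join lead
    pairs with r^2 >= r2_thresh; cross-chromosome r^2 is 0 by convention.
    The cluster lead is the smallest-p member, ties broken by canonical
    variant-string order.
    """
    leads = list(leads)
    for _, key, _ in leads:
        ld.index_of(key)

    parent = list(range(len(leads)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(len(leads)):
        for j in range(i + 1, len(leads)):
            ki, kj = leads[i][1], leads[j][1]
            if ki.chrom != kj.chrom:
                continue
            if ld.r2_between(ki, kj) >= r2_thresh:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(leads)):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for idxs in groups.values():
        members = [leads[i] for i in idxs]
        lead = min(members, key=lambda m: _p_order_key(m[2], m[1]))
        clusters.append(LeadCluster(members=members, cluster_lead=lead))
    clusters.sort(key=lambda c: c.cluster_lead[1].sort_key)
    return clusters
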