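"""Shared/unique classification of TE insertion clusters across populations.

A Cla-element cluster is *unique* when it is detected in exactly one
population, *shared* when in more than one, and *shared by all* when
every surveyed population carries it.  Clusters from different
populations are unified when their intervals overlap (optionally within
a bp tolerance), and the unified clusters are tallied by genomic
compartment: centromere + flanks, chromosomal arms, short chromosomes
analysed whole, and unplaced scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .intervals import GenomeLayout, GenomicInterval, IntervalSet

__all__ = [
    "ClaCluster",
    "SharingTally",
    "merge_population_calls",
    "tally_sharing",
    "sharing_percentages",
]

SIZE_SPLIT_BP = 500  # boundary between small and large clusters


@dataclass(frozen=True)
class ClaCluster:
    """A TE insertion cluster with its population presence set."""

    interval: GenomicInterval
    populations_present: frozenset[str]
    n_populations_surveyed: int

    def __post_init__(self) -> None:
        if not self.populations_present:
            raise ValueError("populations_present must be non-empty")
        if len(self.populations_present) > self.n_populations_surveyed:
            raise ValueError("more populations present than surveyed")

    @property
    def length_bp(self) -> int:
        return self.interval.length

    @property
    def size_class(self) -> str:
        return "small" if self.length_bp < SIZE_SPLIT_BP else "large"

    @property
    def sharing(self) -> str:
        k = len(self.populations_present)
        if k == 1:
            return "unique"
        if k == self.n_populations_surveyed:
            return "shared_all"
        return "shared_partial"


def merge_population_calls(
    per_population: Mapping[str, IntervalSet],
    match_tolerance_bp: int = 0,
    n_populations: Optional[int] = None,
) -> list[ClaCluster]:
    """Unify per-population insertion calls into cross-population clusters.

    Calls whose intervals overlap — or whose gap is at most
    ``match_tolerance_bp`` when a positive tolerance is given — are merged
    into a single cluster spanning their union, carrying the union of
    population labels.  With the default 0 tolerance only genuine overlap
    (>= 1 shared bp) merges; half-open abutment does not.  Idempotent:
    merging the merged output again changes nothing.
    """
    if not per_population:
        raise ValueError("at least one population required")
    n_pops = n_populations if n_populations is not None else len(per_population)
    tagged: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for pop, ivset in per_population.items():
        for iv in ivset:
            tagged.setdefault(iv.chrom, []).append((iv, pop))
    clusters: list[ClaCluster] = []
    for chrom in sorted(tagged):
        items = sorted(tagged[chrom], key=lambda t: (t[0].start, t[0].end))
        cur_s = cur_e = None
        cur_pops: set[str] = set()
        for iv, pop in items:
            gap = None if cur_e is None else iv.start - cur_e
            merge = gap is not None and (
                gap < 0 or (match_tolerance_bp > 0 and gap <= match_tolerance_bp)
            )
            if merge:
                cur_e = max(cur_e, iv.end)
                cur_pops.add(pop)
            else:
                if cur_e is not None:
                    clusters.append(
                        ClaCluster(
                            GenomicInterval(chrom, cur_s, cur_e),
                            frozenset(cur_pops),
                            n_pops,
                        )
                    )
                cur_s, cur_e, cur_pops = iv.start, iv.end, {pop}
        if cur_e is not None:
            clusters.append(
                ClaCluster(
                    GenomicInterval(chrom, cur_s, cur_e), frozenset(cur_pops), n_pops
                )
            )
    return clusters


@dataclass
class SharingTally:
    """Cross-tabulation of clusters by sharing class and compartment."""

    by_class: dict[str, int]                       # unique/shared_partial/shared_all
    by_compartment: pd.DataFrame                   # compartment x {shared, unique}
    per_population: dict[str, int]                 # clusters present per population
    n_total: int

    @property
    def n_shared_any(self) -> int:
        return self.by_class["shared_partial"] + self.by_class["shared_all"]


def _compartment(
    cluster: ClaCluster, layout: GenomeLayout, flank: Mapping[str, int]
) -> str:
    chrom = cluster.interval.chrom
    if chrom not in layout.chrom_lengths:
        return "unplaced"
    cen = layout.centromeres.get(chrom)
    if cen is None:
        return "whole_chromosome"
    flank_bp = flank[chrom]
    cen_flanked = GenomicInterval(
        chrom,
        max(0, cen.start - flank_bp),
        min(layout.chrom_lengths[chrom], cen.end + flank_bp),
    )
    # centromere +- flank takes precedence over arm assignment
    if cluster.interval.overlaps(cen_flanked):
        return "centromere"
    return "arm"


def tally_sharing(
    clusters: Sequence[ClaCluster],
    layout: GenomeLayout,
    centromere_flank_fraction: float = 0.05,
) -> SharingTally:
    """Tally clusters by sharing class and genomic compartment.

    Each cluster lands in exactly one compartment: ``centromere``
    (overlapping the centromere widened by ``centromere_flank_fraction``
    of the chromosome length on each side), ``arm``, ``whole_chromosome``
    (chromosomes without a defined centromere), or ``unplaced`` (scaffolds
    absent from the layout).
    """
    flank = {
        chrom: int(round(centromere_flank_fraction * length))
        for chrom, length in layout.chrom_lengths.items()
    }
    by_class = {"unique": 0, "shared_partial": 0, "shared_all": 0}
    comp_rows: dict[str, dict[str, int]] = {}
    per_pop: dict[str, int] = {}
    for cl in clusters:
        by_class[cl.sharing] += 1
        comp = _compartment(cl, layout, flank)
        row = comp_rows.setdefault(comp, {"shared": 0, "unique": 0})
        row["shared" if cl.sharing != "unique" else "unique"] += 1
        for pop in cl.populations_present:
            per_pop[pop] = per_pop.get(pop, 0) + 1
    comp_df = (
        pd.DataFrame.from_dict(comp_rows, orient="index")
        .reindex(columns=["shared", "unique"])
        .fillna(0)
        .astype(int)
    )
    comp_df.index.name = "compartment"
    return SharingTally(
        by_class=by_class,
        by_compartment=comp_df,
        per_population=dict(sorted(per_pop.items())),
        n_total=len(clusters),
    )


def _pct(k: int, total: int) -> float:
    """Percentage rounded half-up to one decimal."""
    return float(
        (Decimal(k) * 100 / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def sharing_percentages(tally: SharingTally) -> dict[str, float]:
    """Percentages of each sharing class (one decimal, half-up rounding)."""
    if tally.n_total <= 0:
        raise ValueError("tally is empty")
    return {
        "shared_all": _pct(tally.by_class["shared_all"], tally.n_total),
        "shared_partial": _pct(tally.by_class["shared_partial"], tally.n_total),
        "unique": _pct(tally.by_class["unique"], tally.n_total),
        "shared_any": _pct(tally.n_shared_any, tally.n_total),
    }
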