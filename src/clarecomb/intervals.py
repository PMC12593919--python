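"""Genomic interval primitives: BED I/O, windowing and nearest-feature search.

All coordinates are 0-based half-open (BED convention) throughout the
package; VCF positions (1-based) are converted at the I/O boundary.  Every
downstream stage — recombination windows, haplotype blocks, TE clusters,
centromere ranges — is expressed in terms of :class:`GenomicInterval` and
:class:`IntervalSet`.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GenomeLayout",
    "ClosestHit",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "make_windows",
    "closest_distance",
]


class BedParseError(ValueError):
    """Raised for malformed BED records; message carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region [start, end) on one chromosome.

    ``extra`` carries any BED columns beyond the first three, opaque to all
    interval arithmetic but preserved on round trips.
    """

    chrom: str
    start: int
    end: int
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap in bp between nearest edges; 0 on overlap; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, other.start - self.end, self.start - other.end)

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Keeps a ``sorted`` flag; sorting is by (chrom, start, end).  Equality
    compares the interval sequences (including extra columns), so a BED
    round trip is an identity.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), sorted: bool = False):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.is_sorted = bool(sorted)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, sorted={self.is_sorted})"

    def sort(self) -> "IntervalSet":
        if not self.is_sorted:
            self.intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
            self.is_sorted = True
        return self

    def sorted_copy(self) -> "IntervalSet":
        return IntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
            sorted=True,
        )

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        for ivs in out.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
        return out

    def total_bp(self) -> int:
        """Total bp covered, counting overlapping regions once."""
        total = 0
        for ivs in self.by_chrom().values():
            cur_s, cur_e = None, None
            for iv in ivs:
                if cur_e is None or iv.start >= cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = iv.start, iv.end
                else:
                    cur_e = max(cur_e, iv.end)
            if cur_e is not None:
                total += cur_e - cur_s
        return total


@dataclass
class GenomeLayout:
    """Chromosome lengths plus optional predicted centromere ranges."""

    chrom_lengths: dict[str, int]
    centromeres: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, cen in self.centromeres.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"centromere on unknown chromosome {chrom!r}")
            if cen.chrom != chrom:
                raise ValueError("centromere interval chrom mismatch")
            if cen.end > self.chrom_lengths[chrom]:
                raise ValueError(
                    f"centromere {cen} exceeds length of {chrom} "
                    f"({self.chrom_lengths[chrom]})"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)


# ---------------------------------------------------------------------------
# BED / TSV I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Columns beyond chrom/start/end are preserved verbatim in
    ``GenomicInterval.extra``.  Track, browser and comment lines are
    skipped.  Malformed records raise :class:`BedParseError` naming the
    offending line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, s_raw, e_raw = fields[0], fields[1], fields[2]
            try:
                start, end = int(s_raw), int(e_raw)
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {s_raw!r}/{e_raw!r}"
                ) from None
            try:
                iv = GenomicInterval(chrom, start, end, tuple(fields[3:]))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return IntervalSet(out)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write BED3+; extra columns follow the coordinates unchanged."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), *iv.extra]
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[parts[0]] = int(parts[1])
    return sizes


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def make_windows(layout: GenomeLayout, width: int) -> IntervalSet:
    """Tile each chromosome with non-overlapping windows of ``width`` bp.

    Only complete windows are emitted: a trailing partial window is
    dropped, and chromosomes shorter than ``width`` contribute none.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    out: list[GenomicInterval] = []
    for chrom, length in layout.chrom_lengths.items():
        n_win = length // width
        for k in range(n_win):
            out.append(GenomicInterval(chrom, k * width, (k + 1) * width))
    return IntervalSet(out, sorted=True)


# ---------------------------------------------------------------------------
# Nearest-feature distance (bedtools-closest semantics)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClosestHit:
    """Nearest feature for one query; feature is None when the query's
    chromosome carries no feature at all."""

    query: GenomicInterval
    feature: Optional[GenomicInterval]
    distance: Optional[int]


def closest_distance(
    queries: IntervalSet, features: IntervalSet, chunk: int = 1024
) -> list[ClosestHit]:
    """For each query, the nearest same-chromosome feature and the gap in bp.

    Distance is 0 when the intervals share at least one bp, else the number
    of bp strictly between their nearest edges (half-open arithmetic, so
    book-ended intervals are at distance 0).  Ties between equidistant
    features go to the feature with the smaller start (then smaller end).
    Queries on chromosomes without features yield a ``None`` sentinel hit.
    """
    feats = features.by_chrom()
    hits: list[ClosestHit] = []
    # Pre-extract arrays per chromosome; features sorted by (start, end) so
    # np.argmin's first-occurrence rule implements the leftmost tie-break.
    arrays: dict[str, tuple[np.ndarray, np.ndarray, list[GenomicInterval]]] = {}
    for chrom, ivs in feats.items():
        arrays[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
            ivs,
        )

    by_chrom_queries: dict[str, list[GenomicInterval]] = {}
    for q in queries:
        by_chrom_queries.setdefault(q.chrom, []).append(q)

    result_map: dict[int, ClosestHit] = {}
    for chrom, qs in by_chrom_queries.items():
        if chrom not in arrays:
            for q in qs:
                result_map[id(q)] = ClosestHit(q, None, None)
            continue
        f_start, f_end, f_ivs = arrays[chrom]
        q_start = np.array([q.start for q in qs], dtype=np.int64)
        q_end = np.array([q.end for q in qs], dtype=np.int64)
        for lo in range(0, len(qs), chunk):
            hi = min(lo + chunk, len(qs))
            gap_right = f_start[None, :] - q_end[lo:hi, None]
            gap_left = q_start[lo:hi, None] - f_end[None, :]
            dist = np.maximum(np.maximum(gap_right, gap_left), 0)
            best = np.argmin(dist, axis=1)
            for k, qi in enumerate(range(lo, hi)):
                j = int(best[k])
                result_map[id(qs[qi])] = ClosestHit(
                    qs[qi], f_ivs[j], int(dist[k, j])
                )
    # Preserve input query order.
    for q in queries:
        hits.append(result_map[id(q)])
    return hits
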