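"""Inside/outside statistics of TE clusters versus haplotype blocks.

Implements the overlap classification, the exact binomial test, the
Wilcoxon rank-sum comparisons, and the constrained region-permutation
test (fixed chromosomes, fixed lengths, mutually non-overlapping
re-placement) used to ask whether Cla-element insertions fall outside
haplotype blocks more often than chance placement would predict.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomeLayout, GenomicInterval, IntervalSet

__all__ = [
    "OverlapClassification",
    "BinomialResult",
    "PermutationResult",
    "InfeasiblePlacementError",
    "classify_overlap",
    "binomial_test",
    "wilcoxon_rank_sum",
    "permutation_test",
]


class InfeasiblePlacementError(RuntimeError):
    """Random re-placement could not satisfy the no-overlap constraint."""


# ---------------------------------------------------------------------------
# Overlap classification
# ---------------------------------------------------------------------------

@dataclass
class OverlapClassification:
    """Per-cluster inside/outside flags against a reference block set.

    A cluster is *inside* iff it shares at least one bp with any block
    (containment is a special case of overlap).  Half-open abutment is
    zero shared bp, hence outside.
    """

    inside: np.ndarray          # bool per query, input order
    n_total: int
    n_inside: int
    n_outside: int
    block_has_cluster: np.ndarray  # bool per reference block, input order


class _RefIndex:
    """Per-chromosome feature arrays supporting O(log n) overlap queries.

    Features are sorted by start; ``end_cummax`` is the running maximum of
    ends, so any query [s, e) overlaps some feature iff among features
    with start < e the maximum end exceeds s.
    """

    def __init__(self, features: IntervalSet):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in features.by_chrom().items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self.by_chrom[chrom] = (starts, np.maximum.accumulate(ends))

    def overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized: does each [start, end) overlap any feature on chrom?"""
        if chrom not in self.by_chrom:
            return np.zeros(len(starts), dtype=bool)
        f_start, end_cummax = self.by_chrom[chrom]
        idx = np.searchsorted(f_start, ends, side="left")
        out = np.zeros(len(starts), dtype=bool)
        nz = idx > 0
        out[nz] = end_cummax[idx[nz] - 1] > starts[nz]
        return out


def classify_overlap(
    clusters: IntervalSet, blocks: IntervalSet
) -> OverlapClassification:
    """Flag each cluster as inside (>=1 shared bp with any block) or outside."""
    ref = _RefIndex(blocks)
    inside = np.zeros(len(clusters), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(clusters):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        s = np.array([clusters[i].start for i in idxs], dtype=np.int64)
        e = np.array([clusters[i].end for i in idxs], dtype=np.int64)
        hit = ref.overlaps(chrom, s, e)
        for k, i in enumerate(idxs):
            inside[i] = hit[k]
    # symmetric per-block flag
    qref = _RefIndex(clusters)
    has_cluster = np.zeros(len(blocks), dtype=bool)
    bby: dict[str, list[int]] = {}
    for i, iv in enumerate(blocks):
        bby.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in bby.items():
        s = np.array([blocks[i].start for i in idxs], dtype=np.int64)
        e = np.array([blocks[i].end for i in idxs], dtype=np.int64)
        hit = qref.overlaps(chrom, s, e)
        for k, i in enumerate(idxs):
            has_cluster[i] = hit[k]
    n_in = int(inside.sum())
    return OverlapClassification(
        inside=inside,
        n_total=len(clusters),
        n_inside=n_in,
        n_outside=len(clusters) - n_in,
        block_has_cluster=has_cluster,
    )


# ---------------------------------------------------------------------------
# Exact binomial test
# ---------------------------------------------------------------------------

@dataclass
class BinomialResult:
    k: int
    n: int
    point_estimate: float  # k / n
    p0: float
    p_value: float
    alternative: str

    @property
    def point_estimate_7dp(self) -> float:
        """Success probability rounded to 7 decimals, the reporting precision."""
        return round(self.point_estimate, 7)


def binomial_test(
    k: int, n: int, p0: float = 0.5, alternative: str = "two-sided"
) -> BinomialResult:
    """Exact binomial test of k successes in n trials against null p0."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid binomial arguments k={k}, n={n}")
    res = stats.binomtest(k, n, p0, alternative=alternative)
    return BinomialResult(
        k=k,
        n=n,
        point_estimate=k / n,
        p0=p0,
        p_value=float(res.pvalue),
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 50
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of ``x`` with midranks for
    ties.  Uses the exact null distribution for small tie-free samples
    (combined n <= ``exact_max_n``), otherwise the normal approximation
    with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size + y.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


# ---------------------------------------------------------------------------
# Constrained region-permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    statistic: str
    observed: float
    n_perm: int
    permuted: np.ndarray
    permuted_mean: float
    permuted_sd: float
    z_score: float          # NaN when permuted SD is zero
    p_value: float
    alternative: str        # tail actually reported
    degenerate: bool = False
    seed: Optional[int] = None

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "n_perm": self.n_perm,
            "permuted_mean": self.permuted_mean,
            "permuted_sd": self.permuted_sd,
            "z_score": self.z_score,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "degenerate": self.degenerate,
            "seed": self.seed,
        }


def _place_queries(
    rng: np.random.Generator,
    lengths: np.ndarray,
    chrom_length: int,
    max_attempts: int,
    chrom: str,
) -> np.ndarray:
    """Place intervals of the given lengths uniformly on [0, L) without
    mutual overlap; returns start positions (same order as lengths)."""
    highs = chrom_length - lengths  # start in [0, L - len] inclusive
    if np.any(highs < 0):
        raise InfeasiblePlacementError(
            f"query longer than chromosome {chrom} (length {chrom_length})"
        )
    starts = np.empty(len(lengths), dtype=np.int64)
    first_try = rng.integers(0, highs + 1)
    placed_starts: list[int] = []  # sorted
    placed_ends: list[int] = []    # parallel to placed_starts
    for i, L in enumerate(lengths):
        s = int(first_try[i])
        attempts = 0
        while True:
            e = s + int(L)
            j = bisect.bisect_right(placed_starts, s)
            ok = True
            if j > 0 and placed_ends[j - 1] > s:
                ok = False
            if ok and j < len(placed_starts) and placed_starts[j] < e:
                ok = False
            if ok:
                placed_starts.insert(j, s)
                placed_ends.insert(j, e)
                starts[i] = s
                break
            attempts += 1
            if attempts >= max_attempts:
                raise InfeasiblePlacementError(
                    f"could not place interval of length {L} on chromosome "
                    f"{chrom} after {max_attempts} attempts "
                    "(no-overlap constraint)"
                )
            s = int(rng.integers(0, highs[i] + 1))
    return starts


def permutation_test(
    queries: IntervalSet,
    references: IntervalSet,
    layout: GenomeLayout,
    statistic: str = "n_overlapping",
    n_perm: int = 5000,
    seed: Optional[int] = None,
    alternative: str = "auto",
    max_attempts: int = 10_000,
) -> PermutationResult:
    """Region-permutation test of query/reference overlap.

    Each permutation independently re-places every query uniformly at
    random on its original chromosome, preserving its length, redrawing
    any placement that would overlap an already-placed permuted query.
    References stay fixed.  ``statistic`` is ``n_overlapping`` (queries
    sharing >=1 bp with a reference) or ``n_outside`` (the complement).
    The permutation p-value uses the add-one rule
    p = (#{perm as-or-more extreme} + 1) / (n_perm + 1), so it is never 0.

    ``alternative``: "greater", "less", "two_sided", or "auto" (report the
    tail of the observed deviation from the permuted mean).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("n_overlapping", "n_outside"):
        raise ValueError(f"unknown statistic {statistic!r}")
    for q in queries:
        if q.chrom not in layout.chrom_lengths:
            raise ValueError(f"query chromosome {q.chrom!r} missing from layout")
        if q.length > layout.chrom_lengths[q.chrom]:
            raise InfeasiblePlacementError(
                f"query of length {q.length} exceeds chromosome {q.chrom}"
            )

    ref = _RefIndex(references)
    obs_cls = classify_overlap(queries, references)
    n_total = obs_cls.n_total
    observed = float(
        obs_cls.n_inside if statistic == "n_overlapping" else obs_cls.n_outside
    )

    lengths_by_chrom: dict[str, np.ndarray] = {}
    for chrom, ivs in queries.by_chrom().items():
        lengths_by_chrom[chrom] = np.array([iv.length for iv in ivs], dtype=np.int64)

    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm, dtype=np.int64)
    for p in range(n_perm):
        n_overlap = 0
        for chrom, lens in lengths_by_chrom.items():
            starts = _place_queries(
                rng, lens, layout.chrom_lengths[chrom], max_attempts, chrom
            )
            n_overlap += int(ref.overlaps(chrom, starts, starts + lens).sum())
        permuted[p] = n_overlap if statistic == "n_overlapping" else n_total - n_overlap

    mean = float(permuted.mean())
    sd = float(permuted.std(ddof=1)) if n_perm > 1 else 0.0
    degenerate = sd == 0.0
    z = float("nan") if degenerate else (observed - mean) / sd

    p_greater = (int((permuted >= observed).sum()) + 1) / (n_perm + 1)
    p_less = (int((permuted <= observed).sum()) + 1) / (n_perm + 1)
    if alternative == "auto":
        tail = "greater" if observed >= mean else "less"
    else:
        tail = alternative
    if degenerate and observed == mean:
        p_value, tail = 1.0, alternative if alternative != "auto" else "greater"
    elif tail == "greater":
        p_value = p_greater
    elif tail == "less":
        p_value = p_less
    elif tail == "two_sided":
        p_value = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    return PermutationResult(
        statistic=statistic,
        observed=observed,
        n_perm=n_perm,
        permuted=permuted,
        permuted_mean=mean,
        permuted_sd=sd,
        z_score=z,
        p_value=min(1.0, p_value),
        alternative=tail,
        degenerate=degenerate,
        seed=seed,
    )
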