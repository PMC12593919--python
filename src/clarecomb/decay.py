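"""Distance-decay analysis: rho versus distance to the nearest feature.

Pairs each recombination window with the gap to the nearest TE cluster
(split into <500 bp and >=500 bp size classes, or unique/shared classes)
or to the nearest haplotype block, computes Pearson or Spearman
correlations of rho with that distance, resamples bootstrap envelopes of
the binned mean curve, and assembles the long-format table behind the
correlation heatmaps.  A positive Pearson r means rho rises with
distance from the feature; the haplotype-block analysis conventionally
reports negative r (higher rho close to blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, closest_distance

__all__ = [
    "DecayDataset",
    "CorrelationResult",
    "BootstrapEnvelope",
    "split_by_size",
    "build_decay",
    "correlate_decay",
    "bootstrap_decay",
    "decay_heatmap_table",
    "significance_stars",
]

SIZE_SPLIT_BP = 500


@dataclass
class DecayDataset:
    """(distance, rho) pairs for one genomic part and feature class."""

    part: str                     # e.g. "chr1:arm1", "chr2:centromere", "chr4:whole"
    feature_class: str            # cla_small / cla_large / cla_unique / ...
    distances: np.ndarray         # bp, >= 0
    rho: np.ndarray               # >= 0
    window_width: int

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.int64)
        self.rho = np.asarray(self.rho, dtype=float)
        if len(self.distances) != len(self.rho):
            raise ValueError("distances and rho must align")
        if len(self.distances) and self.distances.min() < 0:
            raise ValueError("distances must be >= 0")

    @property
    def n(self) -> int:
        return len(self.distances)


def significance_stars(p: float) -> str:
    """Fig-style stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def split_by_size(
    features: IntervalSet, size_split_bp: int = SIZE_SPLIT_BP
) -> dict[str, IntervalSet]:
    """Partition features into small (< split) and large (>= split)."""
    small = [iv for iv in features if iv.length < size_split_bp]
    large = [iv for iv in features if iv.length >= size_split_bp]
    return {
        "cla_small": IntervalSet(small, sorted=features.is_sorted),
        "cla_large": IntervalSet(large, sorted=features.is_sorted),
    }


def build_decay(
    windows: pd.DataFrame,
    features: IntervalSet,
    part: Optional[GenomicInterval] = None,
    part_label: str = "whole",
    feature_class: str = "feature",
    window_width: Optional[int] = None,
) -> DecayDataset:
    """Pair windows with the distance to the nearest feature.

    ``windows`` needs chrom/start/end/rho columns (one rho per window,
    e.g. the population mean).  When ``part`` is given, windows are
    clipped to it (windows without overlap are dropped) and only features
    overlapping the part are considered.  Windows with missing rho, and
    windows on chromosomes without any feature of the class, are dropped.
    """
    wdf = windows.dropna(subset=["rho"])
    if part is not None:
        wdf = wdf[wdf["chrom"] == part.chrom]
        wdf = wdf[(wdf["end"] > part.start) & (wdf["start"] < part.end)]
        wdf = wdf.assign(
            start=wdf["start"].clip(lower=part.start),
            end=wdf["end"].clip(upper=part.end),
        )
        feats = IntervalSet([iv for iv in features if iv.overlaps(part)])
    else:
        feats = features
    label = f"{part.chrom}:{part_label}" if part is not None else part_label
    if window_width is None:
        window_width = (
            int((windows["end"] - windows["start"]).mode().iloc[0]) if len(windows) else 0
        )
    if len(wdf) == 0 or len(feats) == 0:
        return DecayDataset(label, feature_class, np.empty(0, np.int64),
                            np.empty(0, float), window_width)
    queries = IntervalSet(
        [
            GenomicInterval(str(r.chrom), int(r.start), int(r.end))
            for r in wdf.itertuples()
        ]
    )
    hits = closest_distance(queries, feats)
    dist, rho = [], []
    for hit, r in zip(hits, wdf["rho"].to_numpy()):
        if hit.feature is None:
            continue
        dist.append(hit.distance)
        rho.append(r)
    return DecayDataset(
        label, feature_class, np.array(dist, np.int64), np.array(rho, float),
        window_width,
    )


@dataclass
class CorrelationResult:
    method: str
    r: float
    p_value: float
    n: int
    stars: str
    defined: bool = True


def correlate_decay(ds: DecayDataset, method: str = "pearson") -> CorrelationResult:
    """Correlation of rho with distance on the raw, unbinned pairs.

    Pearson uses the t-distribution p-value; Spearman the rank method
    (exact for small n without ties, asymptotic otherwise, as in
    scipy).  Zero variance in either margin yields an undefined result
    flagged ``defined=False``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if ds.n < 3:
        return CorrelationResult(method, float("nan"), float("nan"), ds.n, "", False)
    x = ds.distances.astype(float)
    y = ds.rho
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(method, float("nan"), float("nan"), ds.n, "", False)
    if method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(method, r, p, ds.n, significance_stars(p))


@dataclass
class BootstrapEnvelope:
    """Per-replicate binned mean-rho curves from resampling the pairs."""

    bin_edges: np.ndarray         # distance-bin edges, len n_bins + 1
    curves: np.ndarray            # (n_reps, n_bins); NaN where a bin is empty
    n_reps: int
    seed: Optional[int]

    def mean_curve(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.curves, axis=0)


def bootstrap_decay(
    ds: DecayDataset,
    n_reps: int = 100,
    n_bins: int = 20,
    seed: Optional[int] = None,
) -> BootstrapEnvelope:
    """Bootstrap the binned mean-rho curve.

    Each replicate resamples the (distance, rho) pairs with replacement
    at the original n and averages rho within equal-count (quantile)
    distance bins fixed from the observed distances.  Deterministic under
    ``seed``; bins with no resampled points carry NaN.
    """
    if ds.n < 2:
        raise ValueError("need at least 2 pairs to bootstrap")
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(ds.distances, qs))
    if len(edges) < 2:
        edges = np.array([ds.distances.min(), ds.distances.max() + 1])
    nb = len(edges) - 1
    rng = np.random.default_rng(seed)
    curves = np.full((n_reps, nb), np.nan)
    for rep in range(n_reps):
        idx = rng.integers(0, ds.n, size=ds.n)
        d = ds.distances[idx]
        r = ds.rho[idx]
        which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, nb - 1)
        sums = np.zeros(nb)
        cnt = np.zeros(nb)
        np.add.at(sums, which, r)
        np.add.at(cnt, which, 1)
        with np.errstate(invalid="ignore"):
            curves[rep] = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
    return BootstrapEnvelope(bin_edges=edges, curves=curves, n_reps=n_reps, seed=seed)


def decay_heatmap_table(
    results: Mapping[tuple[str, str, str, str, str], CorrelationResult]
) -> pd.DataFrame:
    """Long-format heatmap table.

    Keys are (population, chromosome, part, feature_class, method); rows
    carry r, p, n and stars, with NA entries for undefined correlations.
    """
    rows = []
    for (pop, chrom, part, klass, method), res in results.items():
        rows.append(
            {
                "population": pop,
                "chromosome": chrom,
                "part": part,
                "feature_class": klass,
                "method": method,
                "r": res.r if res.defined else np.nan,
                "p_value": res.p_value if res.defined else np.nan,
                "n": res.n,
                "stars": res.stars,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "population", "chromosome", "part", "feature_class",
            "method", "r", "p_value", "n", "stars",
        ],
    )
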