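"""Recombination-landscape windowing, summaries, hotspots and arm splitting.

Consumes per-individual piecewise-constant population-scaled recombination
maps (rho tracks, one TSV per individual: chrom, start, end, rho) such as
an SMC-based mapper emits, aggregates them into fixed-width windows,
produces per-chromosome / per-population summary tables, classifies
hotspot windows (rho above the chromosome mean + 2 SD for at least one
individual), and splits chromosomes into arm / centromere parts for the
region-stratified analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, GenomicInterval, IntervalSet

__all__ = [
    "RhoTrack",
    "WindowedRho",
    "RhoSummary",
    "HotspotSet",
    "read_rho_track",
    "write_rho_track",
    "window_rho",
    "pool_windows",
    "summarize_rho",
    "classify_hotspots",
    "split_arms",
]


@dataclass
class RhoTrack:
    """Piecewise-constant rho map for one individual.

    ``segments`` maps chromosome -> (starts, ends, rho) arrays with
    non-overlapping, start-sorted segments and finite rho >= 0.
    """

    individual: str
    population: str
    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for chrom, (s, e, r) in self.segments.items():
            if not (np.all(np.isfinite(r)) and np.all(r >= 0)):
                raise ValueError(f"{self.individual}/{chrom}: rho must be finite, >= 0")
            if np.any(e <= s):
                raise ValueError(f"{self.individual}/{chrom}: empty segment")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{self.individual}/{chrom}: overlapping segments")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, individual: str, population: str) -> "RhoTrack":
        segs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            segs[str(chrom)] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["rho"].to_numpy(float),
            )
        return cls(individual, population, segs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (s, e, r) in self.segments.items():
            rows.append(
                pd.DataFrame({"chrom": chrom, "start": s, "end": e, "rho": r})
            )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "start", "end", "rho"]
        )


def read_rho_track(path: str | Path, individual: str, population: str) -> RhoTrack:
    """Read a chrom/start/end/rho TSV (gzip supported via pandas)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "start", "end", "rho"],
        dtype={"chrom": str},
        header=None,
    )
    # tolerate a header row
    if len(df) and str(df.iloc[0]["start"]).lstrip("-").isdigit() is False:
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["rho"] = df["rho"].astype(float)
    return RhoTrack.from_frame(df, individual, population)


def write_rho_track(track: RhoTrack, path: str | Path) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def window_rho(track: RhoTrack, layout: GenomeLayout, width: int) -> pd.DataFrame:
    """Coverage-weighted mean rho of one individual in complete windows.

    Segments straddling a window border contribute only their in-window
    bp; the trailing partial window of each chromosome is dropped.
    Windows with zero covered bp carry NaN (excluded from summaries).
    Returns columns chrom, start, end, rho, covered_bp.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    frames = []
    for chrom, length in layout.chrom_lengths.items():
        n_win = length // width
        if n_win == 0:
            continue
        span = n_win * width
        sums = np.zeros(n_win)
        cov = np.zeros(n_win, dtype=np.int64)
        if chrom in track.segments:
            s, e, r = track.segments[chrom]
            s = np.clip(s, 0, span)
            e = np.clip(e, 0, span)
            keep = e > s
            s, e, r = s[keep], e[keep], r[keep]
            # split segments at window borders, at most one border per pass
            while len(s):
                win = s // width
                piece_end = np.minimum(e, (win + 1) * width)
                piece_len = piece_end - s
                np.add.at(sums, win, r * piece_len)
                np.add.at(cov, win, piece_len)
                cont = piece_end < e
                s, e, r = piece_end[cont], e[cont], r[cont]
        with np.errstate(invalid="ignore"):
            mean = np.where(cov > 0, sums / np.maximum(cov, 1), np.nan)
        starts = np.arange(n_win, dtype=np.int64) * width
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + width,
                    "rho": mean,
                    "covered_bp": cov,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "rho", "covered_bp"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class WindowedRho:
    """Fixed-width window table across individuals.

    ``values`` is a wide DataFrame indexed by (chrom, start, end) with one
    rho column per individual; ``populations`` maps individual -> population.
    The population mean is the arithmetic mean over individuals with data.
    """

    width: int
    values: pd.DataFrame
    populations: dict[str, str]

    def population_mean(self, population: Optional[str] = None) -> pd.DataFrame:
        cols = [
            ind
            for ind in self.values.columns
            if population is None or self.populations[ind] == population
        ]
        out = self.values[cols].mean(axis=1, skipna=True).rename("rho").reset_index()
        return out

    def individuals(self) -> list[str]:
        return list(self.values.columns)


def pool_windows(
    tracks: Sequence[RhoTrack], layout: GenomeLayout, width: int
) -> WindowedRho:
    """Window every track and align them into one wide table."""
    if not tracks:
        raise ValueError("no tracks supplied")
    cols = {}
    pops = {}
    for t in tracks:
        df = window_rho(t, layout, width).set_index(["chrom", "start", "end"])
        cols[t.individual] = df["rho"]
        pops[t.individual] = t.population
    wide = pd.DataFrame(cols)
    return WindowedRho(width=width, values=wide, populations=pops)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class RhoSummary:
    scope: str
    n: int
    mean: float
    median: float
    se_low: float
    se_high: float


def _summary_row(scope: str, vals: np.ndarray) -> RhoSummary:
    vals = vals[~np.isnan(vals)]
    n = len(vals)
    mean = float(vals.mean())
    median = float(np.median(vals))
    if n < 2:
        warnings.warn(f"scope {scope!r} has a single value; SE undefined, set to 0")
        se = 0.0
    else:
        se = float(vals.std(ddof=1) / np.sqrt(n))
    return RhoSummary(scope, n, mean, median, mean - se, mean + se)


def summarize_rho(windows: WindowedRho, group_by: str = "chromosome") -> pd.DataFrame:
    """Mean / median / mean+-SE over all (window x individual) rho values.

    ``group_by``: "chromosome", "population", or "total".  N is the number
    of non-missing window-by-individual values in scope; SE is the sample
    SD divided by sqrt(N).  Empty scopes are omitted.
    """
    stacked = windows.values.stack(future_stack=True).rename("rho").reset_index()
    stacked.columns = ["chrom", "start", "end", "individual", "rho"]
    stacked = stacked.dropna(subset=["rho"])
    rows: list[RhoSummary] = []
    if group_by == "chromosome":
        for chrom, sub in stacked.groupby("chrom", sort=False):
            rows.append(_summary_row(str(chrom), sub["rho"].to_numpy()))
    elif group_by == "population":
        stacked["population"] = stacked["individual"].map(windows.populations)
        for pop, sub in stacked.groupby("population", sort=False):
            rows.append(_summary_row(str(pop), sub["rho"].to_numpy()))
    elif group_by == "total":
        if len(stacked):
            rows.append(_summary_row("total", stacked["rho"].to_numpy()))
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    return pd.DataFrame(
        [
            {
                "scope": r.scope,
                "n": r.n,
                "mean": r.mean,
                "median": r.median,
                "se_low": r.se_low,
                "se_high": r.se_high,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------

@dataclass
class HotspotSet:
    """Hotspot windows per chromosome: union over individuals of windows
    whose rho exceeds that individual's chromosome mean + 2 SD."""

    flags: pd.DataFrame          # chrom,start,end,individual rows (flagged only)
    union: IntervalSet
    thresholds: pd.DataFrame     # chrom,individual,mean,sd,threshold


def classify_hotspots(windows: WindowedRho, n_sd: float = 2.0) -> HotspotSet:
    """Flag windows with rho > per-individual chromosome mean + ``n_sd``*SD.

    Mean and sample SD are computed from each individual's windows on that
    chromosome; the reported hotspot set is the union across individuals.
    A zero SD yields no hotspots on that chromosome for that individual.
    """
    flag_rows = []
    thr_rows = []
    union: dict[tuple[str, int, int], GenomicInterval] = {}
    vals = windows.values
    chroms = vals.index.get_level_values("chrom")
    for chrom in pd.unique(chroms):
        sub = vals[chroms == chrom]
        for ind in vals.columns:
            v = sub[ind].to_numpy()
            ok = ~np.isnan(v)
            if ok.sum() < 2:
                continue
            m = float(v[ok].mean())
            sd = float(v[ok].std(ddof=1))
            thr = m + n_sd * sd
            thr_rows.append(
                {"chrom": chrom, "individual": ind, "mean": m, "sd": sd, "threshold": thr}
            )
            if sd == 0.0:
                continue
            hot = np.where(ok & (v > thr))[0]
            for i in hot:
                chrom_i, start_i, end_i = sub.index[i]
                flag_rows.append(
                    {"chrom": chrom_i, "start": start_i, "end": end_i, "individual": ind}
                )
                key = (chrom_i, start_i, end_i)
                union.setdefault(key, GenomicInterval(chrom_i, int(start_i), int(end_i)))
    flags = pd.DataFrame(flag_rows, columns=["chrom", "start", "end", "individual"])
    ivs = sorted(union.values(), key=lambda iv: (iv.chrom, iv.start))
    return HotspotSet(
        flags=flags,
        union=IntervalSet(ivs, sorted=True),
        thresholds=pd.DataFrame(
            thr_rows, columns=["chrom", "individual", "mean", "sd", "threshold"]
        ),
    )


# ---------------------------------------------------------------------------
# Arm / centromere splitting
# ---------------------------------------------------------------------------

def split_arms(layout: GenomeLayout, chrom: str) -> dict[str, GenomicInterval]:
    """Partition a chromosome into arm1 / centromere / arm2, or return the
    whole chromosome when no centromere range is defined (the
    short-chromosome mode).  A centromere touching a telomere leaves the
    corresponding arm out, with a warning."""
    length = layout.chrom_lengths[chrom]
    cen = layout.centromeres.get(chrom)
    if cen is None:
        return {"whole": GenomicInterval(chrom, 0, length)}
    parts: dict[str, GenomicInterval] = {}
    if cen.start > 0:
        parts["arm1"] = GenomicInterval(chrom, 0, cen.start)
    else:
        warnings.warn(f"{chrom}: centromere touches left telomere; arm1 empty")
    parts["centromere"] = GenomicInterval(chrom, cen.start, cen.end)
    if cen.end < length:
        parts["arm2"] = GenomicInterval(chrom, cen.end, length)
    else:
        warnings.warn(f"{chrom}: centromere touches right telomere; arm2 empty")
    return parts
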