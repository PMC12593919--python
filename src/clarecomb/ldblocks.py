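"""Haplotype-block detection with the confidence-interval (Gabriel) method.

Implements the classic Haploview/PLINK-style pipeline: per-site MAF and
missingness filters, two-locus gamete-frequency estimation (direct
counting on phased data, EM on unphased), a likelihood-grid 90%
confidence interval on D', pair classification into strong-LD /
strong-recombination / uninformative, greedy block assembly with an
informative-fraction acceptance rule, and the minimum-length filter.

Pair classification depends on the data only through the four gamete
counts, so results are memoised on the count tuple; with a few dozen
chromosomes this collapses millions of pairwise evaluations to a few
thousand likelihood-grid computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "GenotypeMatrix",
    "LDPairStats",
    "HaplotypeBlock",
    "BlockParams",
    "read_vcf",
    "filter_sites",
    "em_haplotype_freqs",
    "dprime_ci",
    "find_blocks",
    "filter_blocks",
    "blocks_to_det",
    "write_det",
    "blocks_to_bed",
]

# class codes used in the pairwise matrices
UNINFORMATIVE, STRONG_LD, STRONG_RECOMB = 0, 1, 2


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a set of (possibly phased) diploids.

    ``gt`` has shape (n_sites, n_samples, 2) with allele codes 0/1 and -1
    for missing; ``phased`` flags each genotype call.  Positions are
    1-based (VCF convention); interval exports convert to 0-based.
    """

    chrom: np.ndarray           # (S,) str
    pos: np.ndarray             # (S,) int64, 1-based
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    populations: list[str]
    gt: np.ndarray              # (S, N, 2) int8
    phased: np.ndarray          # (S, N) bool

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    @property
    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency over non-missing alleles."""
        alleles = self.gt.reshape(self.n_sites, -1).astype(float)
        valid = alleles >= 0
        with np.errstate(invalid="ignore"):
            p = np.where(
                valid.sum(axis=1) > 0,
                np.where(valid, alleles, 0).sum(axis=1) / np.maximum(valid.sum(axis=1), 1),
                np.nan,
            )
        return np.minimum(p, 1 - p)

    @property
    def missing_rate(self) -> np.ndarray:
        """Per-site fraction of samples with a missing genotype."""
        miss = (self.gt < 0).any(axis=2)
        return miss.mean(axis=1)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            samples=self.samples,
            populations=self.populations,
            gt=self.gt[mask],
            phased=self.phased[mask],
        )

    def fully_phased(self) -> bool:
        return bool(self.phased.all() and (self.gt >= 0).all())

    def haplotype_matrix(self) -> np.ndarray:
        """(2N, S) allele matrix; requires fully phased, complete data."""
        if not self.fully_phased():
            raise ValueError("haplotype matrix requires fully phased, complete data")
        # gt is (S, N, 2) -> haplotypes (2N, S)
        return self.gt.transpose(1, 2, 0).reshape(2 * self.n_samples, self.n_sites)


def read_vcf(
    path: str | Path, populations: Optional[Mapping[str, str]] = None
) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF (phased or unphased GT).

    Multi-allelic and non-SNP records are skipped.  Population labels
    default to the sample-name prefix before the last underscore.
    """
    from cyvcf2 import VCF

    v = VCF(str(path))
    samples = list(v.samples)
    if populations is None:
        pops = [s.rsplit("_", 1)[0] if "_" in s else s for s in samples]
    else:
        pops = [populations[s] for s in samples]
    chroms, poss, refs, alts, gts, phs = [], [], [], [], [], []
    for var in v:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        g = np.array(var.genotypes, dtype=np.int64)  # (N, 3): a, b, phased
        gts.append(g[:, :2].astype(np.int8))
        phs.append(g[:, 2].astype(bool))
    v.close()
    S = len(poss)
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        samples=samples,
        populations=pops,
        gt=(
            np.stack(gts) if S else np.zeros((0, len(samples), 2), dtype=np.int8)
        ),
        phased=(
            np.stack(phs) if S else np.zeros((0, len(samples)), dtype=bool)
        ),
    )


def filter_sites(
    g: GenotypeMatrix, min_maf: float = 0.10, max_missing: float = 0.05
) -> GenotypeMatrix:
    """Keep sites with MAF >= ``min_maf`` and missingness <= ``max_missing``.

    Mirrors the usual variant-QC step (PLINK ``--maf`` / ``--geno``);
    site order is preserved and an empty result is allowed.
    """
    with np.errstate(invalid="ignore"):
        maf_arr = g.maf
        keep = (np.nan_to_num(maf_arr, nan=0.0) >= min_maf) & (
            g.missing_rate <= max_missing
        )
    return g.subset_sites(keep)


# ---------------------------------------------------------------------------
# Two-locus gamete frequencies
# ---------------------------------------------------------------------------

def em_haplotype_freqs(
    g: GenotypeMatrix,
    i: int,
    j: int,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int]:
    """Gamete frequencies (f00, f01, f10, f11) for the site pair (i, j).

    Samples phased at both sites contribute gametes by direct counting.
    For unphased samples only the double heterozygote is phase-ambiguous;
    its two resolutions are apportioned by EM from an equal-split
    initialisation until the largest frequency change is below ``tol``.
    Returns (frequencies, n_chromosomes_used).
    """
    gi = g.gt[i]  # (N, 2)
    gj = g.gt[j]
    ok = (gi >= 0).all(axis=1) & (gj >= 0).all(axis=1)
    if not ok.any():
        raise ValueError(f"all genotypes missing for site pair ({i}, {j})")
    gi, gj = gi[ok], gj[ok]
    ph = g.phased[i][ok] & g.phased[j][ok]

    known = np.zeros(4)  # index 2*a + b
    # phased samples: gametes read off directly
    for hap in (0, 1):
        idx = 2 * gi[ph, hap] + gj[ph, hap]
        np.add.at(known, idx, 1)
    # unphased samples: all genotype pairs except double-het are unambiguous
    di = gi[~ph].sum(axis=1)  # dosage 0/1/2
    dj = gj[~ph].sum(axis=1)
    dh = (di == 1) & (dj == 1)
    n_ambig = int(dh.sum())
    for da, db in zip(di[~dh], dj[~dh]):
        # at most one locus is het here, so both gametes are determined
        if da == 1:  # het at i, hom at j
            known[2 * 1 + db // 2] += 1
            known[2 * 0 + db // 2] += 1
        elif db == 1:  # hom at i, het at j
            known[2 * (da // 2) + 1] += 1
            known[2 * (da // 2) + 0] += 1
        else:  # hom at both
            known[2 * (da // 2) + db // 2] += 2
    n_chrom = int(known.sum() + 2 * n_ambig)
    if n_ambig == 0:
        return known / n_chrom, n_chrom

    # EM over the double-het phase: cis (00,11) vs trans (01,10)
    f = (known + n_ambig * np.array([0.5, 0.5, 0.5, 0.5])) / n_chrom
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        denom = cis + trans
        w = 0.5 if denom == 0 else cis / denom
        new = known.copy()
        new[0] += n_ambig * w
        new[3] += n_ambig * w
        new[1] += n_ambig * (1 - w)
        new[2] += n_ambig * (1 - w)
        new /= n_chrom
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f, n_chrom


# ---------------------------------------------------------------------------
# D' likelihood confidence interval
# ---------------------------------------------------------------------------

@dataclass
class LDPairStats:
    site_i: int
    site_j: int
    D: float
    Dprime: float
    ci_low: float
    ci_high: float
    klass: str                 # strong_ld / strong_recomb / uninformative
    undefined: bool = False    # monomorphic pair: CI not estimable


@dataclass(frozen=True)
class BlockParams:
    """Gabriel-method parameters (Haploview conventions, PLINK flag names)."""

    max_kb: float = 1000.0
    strong_lowci: float = 0.65
    strong_highci: float = 0.97
    recomb_highci: float = 0.90
    inform_frac: float = 0.90
    no_small_max_span: bool = True
    grid_step: float = 0.001
    ci_alpha: float = 0.05     # 90% CI: 5% / 95% cumulative bounds


_DEFAULT_PARAMS = BlockParams()


@lru_cache(maxsize=200_000)
def _ci_from_counts(
    c00: float,
    c01: float,
    c10: float,
    c11: float,
    grid_step: float,
    alpha: float,
) -> tuple[float, float, float, float]:
    """(D, Dprime, ci_low, ci_high) from gamete counts via the likelihood grid.

    Counts may be fractional (EM output scaled by n_chromosomes).  Alleles
    are oriented so that D >= 0 before the grid evaluation.
    """
    n = c00 + c01 + c10 + c11
    f = np.array([c00, c01, c10, c11]) / n
    pA = f[2] + f[3]
    pB = f[1] + f[3]
    D = f[3] - pA * pB
    if D < 0:  # flip allele coding at the second locus
        f = f[[1, 0, 3, 2]]
        pB = 1 - pB
        D = -D
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    if dmax <= 0:
        return 0.0, float("nan"), float("nan"), float("nan")
    dprime = D / dmax
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    d_abs = grid * dmax
    f11 = pA * pB + d_abs
    f10 = pA * (1 - pB) - d_abs
    f01 = (1 - pA) * pB - d_abs
    f00 = (1 - pA) * (1 - pB) + d_abs
    F = np.clip(np.stack([f00, f01, f10, f11]), 0.0, None)
    counts = f * n
    ll = (
        xlogy(counts[0], F[0])
        + xlogy(counts[1], F[1])
        + xlogy(counts[2], F[2])
        + xlogy(counts[3], F[3])
    )
    ll[~np.isfinite(ll)] = -np.inf
    w = np.exp(ll - ll.max())
    cum = np.cumsum(w)
    cum /= cum[-1]
    lo = float(grid[np.searchsorted(cum, alpha)])
    hi = float(grid[np.searchsorted(cum, 1 - alpha)])
    return float(D), float(min(dprime, 1.0)), lo, hi


def _classify(ci_low: float, ci_high: float, params: BlockParams) -> int:
    if np.isnan(ci_low):
        return UNINFORMATIVE
    if ci_low >= params.strong_lowci and ci_high >= params.strong_highci:
        return STRONG_LD
    if ci_high < params.recomb_highci:
        return STRONG_RECOMB
    return UNINFORMATIVE


def dprime_ci(
    freqs: np.ndarray,
    n_chromosomes: int,
    params: BlockParams = _DEFAULT_PARAMS,
    site_i: int = -1,
    site_j: int = -1,
) -> LDPairStats:
    """D', its 90% likelihood CI, and the Gabriel pair classification.

    The multinomial log-likelihood of the gamete counts is evaluated on a
    D' grid (step ``params.grid_step``), normalised to a unit mass;
    ``ci_low``/``ci_high`` are the smallest grid values whose cumulative
    mass reaches alpha and 1 - alpha.  A monomorphic pair is flagged
    ``undefined`` and classified uninformative.
    """
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.min() < -1e-9 or abs(freqs.sum() - 1) > 1e-6:
        raise ValueError("invalid gamete frequencies")
    c = np.round(freqs * n_chromosomes, 6)
    D, dp, lo, hi = _ci_from_counts(
        c[0], c[1], c[2], c[3], params.grid_step, params.ci_alpha
    )
    if np.isnan(dp):
        return LDPairStats(site_i, site_j, 0.0, 0.0, np.nan, np.nan,
                           "uninformative", undefined=True)
    klass = {STRONG_LD: "strong_ld", STRONG_RECOMB: "strong_recomb",
             UNINFORMATIVE: "uninformative"}[_classify(lo, hi, params)]
    return LDPairStats(site_i, site_j, D, dp, lo, hi, klass)


# ---------------------------------------------------------------------------
# Block assembly
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeBlock:
    """A detected LD block spanning consecutive SNPs.

    The interval is 0-based half-open over [first SNP, last SNP), so
    ``length_bp`` equals the bp distance between the outermost SNP
    positions (BP2 - BP1 in .det terms).
    """

    interval: GenomicInterval
    n_snps: int
    snp_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValueError("a block needs at least 2 SNPs")

    @property
    def length_bp(self) -> int:
        return self.interval.length


def _pair_class_matrices_phased(
    H: np.ndarray, pos: np.ndarray, params: BlockParams, max_bp: int,
    col_chunk: int = 512,
) -> np.ndarray:
    """Class code matrix (S x S upper triangle) from a phased haplotype
    matrix, memoising the CI computation on the gamete-count triple."""
    n, S = H.shape
    s_col = H.sum(axis=0).astype(np.int64)
    classes = np.zeros((S, S), dtype=np.int8)
    cache: dict[int, int] = {}
    Hf = H.astype(np.float32)
    base = n + 1
    for lo in range(0, S, col_chunk):
        hi = min(lo + col_chunk, S)
        C11 = (Hf.T @ Hf[:, lo:hi]).astype(np.int64)  # (S, hi-lo)
        key = (C11 * base + s_col[:, None]) * base + s_col[None, lo:hi]
        # mask to pairs i < j within the span cap
        jj = np.arange(lo, hi)
        in_span = (pos[None, jj] - pos[:, None] <= max_bp) & (
            np.arange(S)[:, None] < jj[None, :]
        )
        uk, inv = np.unique(key[in_span], return_inverse=True)
        codes = np.empty(len(uk), dtype=np.int8)
        for t, k in enumerate(uk):
            k = int(k)
            if k not in cache:
                sj = k % base
                si = (k // base) % base
                n11 = k // (base * base)
                n10 = si - n11
                n01 = sj - n11
                n00 = n - si - sj + n11
                _, _, lo_ci, hi_ci = _ci_from_counts(
                    float(n00), float(n01), float(n10), float(n11),
                    params.grid_step, params.ci_alpha,
                )
                cache[k] = (
                    UNINFORMATIVE if np.isnan(lo_ci) else _classify(lo_ci, hi_ci, params)
                )
            codes[t] = cache[k]
        block = np.zeros(key.shape, dtype=np.int8)
        block[in_span] = codes[inv]
        classes[:, lo:hi] = block
    return classes


def _pair_class_matrices_general(
    g: GenotypeMatrix, idx: np.ndarray, params: BlockParams, max_bp: int
) -> np.ndarray:
    """Pairwise class codes via EM — the path for unphased/missing data."""
    S = len(idx)
    pos = g.pos[idx]
    classes = np.zeros((S, S), dtype=np.int8)
    for a in range(S):
        for b in range(a + 1, S):
            if pos[b] - pos[a] > max_bp:
                break
            try:
                f, n_chrom = em_haplotype_freqs(g, int(idx[a]), int(idx[b]))
            except ValueError:
                continue
            st = dprime_ci(f, n_chrom, params)
            classes[a, b] = {
                "strong_ld": STRONG_LD,
                "strong_recomb": STRONG_RECOMB,
                "uninformative": UNINFORMATIVE,
            }[st.klass]
    return classes


_SMALL_SPAN_CAPS = {2: 20_000, 3: 30_000, 4: 30_000}  # Haploview-style


def find_blocks(
    g: GenotypeMatrix, params: BlockParams = _DEFAULT_PARAMS
) -> list[HaplotypeBlock]:
    """Detect haplotype blocks per chromosome with the Gabriel CI method.

    A candidate block is a run of consecutive SNPs whose outermost pair is
    strong-LD and whose bp span does not exceed ``max_kb``; it is accepted
    when strong-LD pairs make up at least ``inform_frac`` of the
    informative (strong-LD + strong-recombination) pairs in the span.
    Overlapping candidates are resolved greedily, longest span first,
    ties to the leftmost.  With ``no_small_max_span`` unset, 2-SNP
    candidates are additionally capped at 20 kb and 3-4-SNP candidates at
    30 kb.
    """
    max_bp = int(params.max_kb * 1000)
    blocks: list[HaplotypeBlock] = []
    ids = np.array(g.site_ids(), dtype=object)
    for chrom in pd.unique(g.chrom):
        idx = np.where(g.chrom == chrom)[0]
        order = np.argsort(g.pos[idx], kind="stable")
        idx = idx[order]
        pos = g.pos[idx]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{chrom}: duplicate SNP positions")
        S = len(idx)
        if S < 2:
            continue
        sub = g.subset_sites(idx)
        if sub.fully_phased():
            classes = _pair_class_matrices_phased(
                sub.haplotype_matrix(), pos, params, max_bp
            )
        else:
            classes = _pair_class_matrices_general(g, idx, params, max_bp)

        strong = classes == STRONG_LD
        recomb = classes == STRONG_RECOMB
        # LD2[i, j] = number of strong pairs (a, b) with i <= a < b <= j
        ld2 = np.zeros((S, S), dtype=np.int32)
        rc2 = np.zeros((S, S), dtype=np.int32)
        for j in range(1, S):
            col_ld = np.cumsum(strong[:j, j][::-1])[::-1]  # suffix sums
            col_rc = np.cumsum(recomb[:j, j][::-1])[::-1]
            ld2[:j, j] = ld2[:j, j - 1] + col_ld
            ld2[j, j] = 0
            rc2[:j, j] = rc2[:j, j - 1] + col_rc

        cand_i, cand_j = np.nonzero(strong)
        span = pos[cand_j] - pos[cand_i]
        keep = span <= max_bp
        if not params.no_small_max_span:
            nsnp = cand_j - cand_i + 1
            for k_snp, cap in _SMALL_SPAN_CAPS.items():
                keep &= ~((nsnp == k_snp) & (span > cap))
        cand_i, cand_j, span = cand_i[keep], cand_j[keep], span[keep]
        order = np.lexsort((cand_i, -span))  # longest first, then leftmost
        used = np.zeros(S, dtype=bool)
        for t in order:
            a, b = int(cand_i[t]), int(cand_j[t])
            if used[a : b + 1].any():
                continue
            n_ld = int(ld2[a, b])
            n_rc = int(rc2[a, b])
            if n_ld / (n_ld + n_rc) < params.inform_frac:
                continue
            used[a : b + 1] = True
            blocks.append(
                HaplotypeBlock(
                    interval=GenomicInterval(
                        str(chrom), int(pos[a]) - 1, int(pos[b]) - 1
                    ),
                    n_snps=b - a + 1,
                    snp_ids=tuple(ids[idx[a : b + 1]]),
                )
            )
    blocks.sort(key=lambda b: (b.interval.chrom, b.interval.start))
    return blocks


def filter_blocks(
    blocks: Sequence[HaplotypeBlock], min_len_bp: int = 50
) -> list[HaplotypeBlock]:
    """Keep blocks whose bp length is at least ``min_len_bp``."""
    return [b for b in blocks if b.length_bp >= min_len_bp]


# ---------------------------------------------------------------------------
# Output dialects
# ---------------------------------------------------------------------------

def blocks_to_det(blocks: Sequence[HaplotypeBlock]) -> pd.DataFrame:
    """Block table in the .det dialect (CHR, BP1, BP2, KB, NSNPS, SNPS)."""
    return pd.DataFrame(
        {
            "CHR": [b.interval.chrom for b in blocks],
            "BP1": [b.interval.start + 1 for b in blocks],
            "BP2": [b.interval.end + 1 for b in blocks],
            "KB": [b.length_bp / 1000.0 for b in blocks],
            "NSNPS": [b.n_snps for b in blocks],
            "SNPS": [";".join(b.snp_ids) for b in blocks],
        }
    )


def write_det(blocks: Sequence[HaplotypeBlock], path: str | Path) -> None:
    blocks_to_det(blocks).to_csv(path, sep="\t", index=False)


def blocks_to_bed(blocks: Sequence[HaplotypeBlock]) -> IntervalSet:
    return IntervalSet(
        [b.interval for b in blocks], sorted=True
    )
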