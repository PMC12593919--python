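"""Synthetic genomes, rho maps, phased haplotypes and TE insertions.

Stands in for the study's sequencing data so that every pipeline stage is
testable with known ground truth.  The generator emulates:

* a small multi-chromosome genome with predicted centromere ranges;
* per-individual piecewise-constant recombination maps with a
  centromere-depressed, telomere-elevated expected profile, multiplicative
  gamma noise around a shared population profile, and Poisson-seeded
  hotspot spikes;
* phased diploid genotypes with real LD-block structure, produced by an
  ancestral-haplotype-pool model (the genome is partitioned into latent
  blocks with exponential lengths; within a block every haploid genome
  copies one of a small pool of ancestral haplotypes, independently
  across blocks) — this gives direct control over true block boundaries
  at negligible compute cost, unlike a coalescent simulation;
* population-structured TE insertion clusters with configurable sharing
  classes (shared by all / partially shared / unique) and placement bias
  (uniform, coupled to low recombination, or haplotype-block avoiding).

All four generators draw from fixed-offset child streams of the master
seed, so regenerating one layer never perturbs another, and a fixed seed
reproduces every file byte for byte.
"""

from __future__ import annotations

import bisect
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .intervals import GenomeLayout, GenomicInterval, IntervalSet
from .ldblocks import GenotypeMatrix
from .popshare import ClaCluster
from .recomb import RhoTrack

__all__ = [
    "SimConfig",
    "GroundTruth",
    "RhoSimResult",
    "HaplotypeSimResult",
    "InsertionSimResult",
    "SyntheticDataset",
    "SimulationError",
    "simulate_genome",
    "simulate_rho",
    "simulate_haplotypes",
    "simulate_insertions",
    "simulate_all",
    "write_vcf",
]

# fixed offsets for the per-generator RNG streams
_STREAM_RHO, _STREAM_HAP, _STREAM_TE = 1, 2, 3


class SimulationError(RuntimeError):
    """Raised when constrained placement exhausts its rejection budget."""


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator.

    Defaults mirror the study design this package emulates: five
    populations of four diploid individuals, four chromosomes with
    centromeres, 441 ancestral TE insertion loci of which 14 are shared
    by all populations and 139 by several, and TE lengths from a
    lognormal law truncated to the observed 73-1802 bp range.  Chromosome
    lengths are desk-scale stand-ins, not the real assembly.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_lengths: tuple[int, ...] = (1_000_000, 900_000, 700_000, 300_000)
    centromere_center_fraction: float = 0.5
    centromere_width_fraction: float = 0.10
    n_populations: int = 5
    n_individuals_per_pop: int = 4
    # haplotypes
    snp_density: float = 0.002          # SNPs per bp (Poisson)
    block_length_mean: float = 10_000.0  # latent LD-block scale, bp
    haplotype_pool_size: int = 4        # ancestral haplotypes per latent block
    # TE insertions
    te_total: int = 441                 # ancestral insertion loci
    te_shared_fraction_all: float = 14 / 441
    te_shared_fraction_partial: float = 139 / 441
    te_len_meanlog: float = 5.5
    te_len_sdlog: float = 0.6
    te_len_min: int = 73
    te_len_max: int = 1802
    placement_mode: str = "uniform"     # uniform | rho_coupled | block_avoiding
    placement_beta: float = 200.0       # density ~ exp(-beta * rho(x))
    placement_q: float = 0.9            # P(reject | overlaps a block)
    avoid_block_fraction: float = 0.10  # latent blocks sampled as the avoided set
    placement_max_attempts: int = 10_000
    # recombination landscape
    rho_baseline: float = 0.0127
    rho_centromere_factor: float = 0.1
    rho_telomere_factor: float = 2.0
    rho_flank_fraction: float = 0.10
    rho_noise_shape: float = 10.0       # gamma shape (unit mean); 0 disables
    hotspot_rate_per_mb: float = 5.0
    hotspot_intensity: float = 10.0
    hotspot_width: int = 2_000
    rho_segment_bp: int = 1_000

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) != self.n_chroms:
            raise ValueError("chrom_lengths must have n_chroms entries")
        for frac in (
            self.centromere_center_fraction,
            self.centromere_width_fraction,
            self.te_shared_fraction_all,
            self.te_shared_fraction_partial,
            self.placement_q,
            self.rho_flank_fraction,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.te_shared_fraction_all + self.te_shared_fraction_partial > 1 + 1e-9:
            raise ValueError("sharing fractions sum above 1")
        if self.placement_mode not in ("uniform", "rho_coupled", "block_avoiding"):
            raise ValueError(f"unknown placement_mode {self.placement_mode!r}")
        if self.te_shared_fraction_partial > 0 and self.n_populations < 3:
            raise ValueError(
                "partially shared insertions need at least 3 populations "
                "(a partial subset must exclude at least one and contain >= 2)"
            )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def population_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["chrom_lengths"] = list(d["chrom_lengths"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "chrom_lengths" in d:
            d["chrom_lengths"] = tuple(d["chrom_lengths"])
        return cls(**d)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> GenomeLayout:
    """Chromosome lengths plus centromere ranges from the config.

    The centromere is centred at ``centromere_center_fraction`` of each
    chromosome with width ``centromere_width_fraction`` of its length.
    Fully deterministic (no random draws).
    """
    lengths = {
        name: int(L) for name, L in zip(config.chrom_names, config.chrom_lengths)
    }
    centromeres = {}
    if config.centromere_width_fraction > 0:
        for name, L in lengths.items():
            half = config.centromere_width_fraction * L / 2
            mid = config.centromere_center_fraction * L
            start = max(0, int(round(mid - half)))
            end = min(L, int(round(mid + half)))
            centromeres[name] = GenomicInterval(name, start, end)
    return GenomeLayout(chrom_lengths=lengths, centromeres=centromeres)


# ---------------------------------------------------------------------------
# Recombination maps
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray) -> np.ndarray:
    """Cosine ramp 0 -> 1 over t in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(t, 0.0, 1.0)))


def _expected_profile(
    layout: GenomeLayout, config: SimConfig, chrom: str, mids: np.ndarray
) -> np.ndarray:
    """Noise-free expected rho at positions ``mids``: baseline times a
    smooth centromere depression times a telomeric elevation."""
    L = layout.chrom_lengths[chrom]
    rho = np.full(len(mids), config.rho_baseline)
    cen = layout.centromeres.get(chrom)
    if cen is not None and config.rho_centromere_factor != 1.0:
        flank = max(1.0, config.rho_flank_fraction * L)
        dist = np.maximum(
            0.0, np.maximum(cen.start - mids, mids - cen.end)
        )
        s = _smoothstep(dist / flank)  # 0 inside the centromere, 1 beyond flank
        rho *= config.rho_centromere_factor + (1 - config.rho_centromere_factor) * s
    if config.rho_telomere_factor != 1.0:
        flank = max(1.0, config.rho_flank_fraction * L)
        d_end = np.minimum(mids, L - mids)
        s = _smoothstep(d_end / flank)  # 0 at the telomere, 1 inland
        rho *= config.rho_telomere_factor + (1 - config.rho_telomere_factor) * s
    return rho


@dataclass
class RhoSimResult:
    tracks: list[RhoTrack]                 # one per individual
    profile: RhoTrack                      # shared noise-free profile (with hotspots)
    hotspots: IntervalSet                  # true injected hotspot regions


def simulate_rho(layout: GenomeLayout, config: SimConfig) -> RhoSimResult:
    """Per-individual piecewise-constant rho tracks.

    The shared population profile is the expected centromere/telomere
    shape multiplied by Poisson-seeded hotspot spikes; each individual
    track multiplies that profile by independent per-segment gamma noise
    with unit mean (shape ``rho_noise_shape``; 0 disables noise).
    """
    rng = _rng(config, _STREAM_RHO)
    seg_bp = config.rho_segment_bp
    profile_segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    hotspot_ivs: list[GenomicInterval] = []
    for chrom, L in layout.chrom_lengths.items():
        starts = np.arange(0, L, seg_bp, dtype=np.int64)
        ends = np.minimum(starts + seg_bp, L)
        mids = (starts + ends) / 2.0
        rho = _expected_profile(layout, config, chrom, mids)
        n_hot = rng.poisson(config.hotspot_rate_per_mb * L / 1e6)
        for _ in range(int(n_hot)):
            center = int(rng.integers(0, L))
            h_s = max(0, center - config.hotspot_width // 2)
            h_e = min(L, center + config.hotspot_width // 2)
            if h_e > h_s:
                hotspot_ivs.append(GenomicInterval(chrom, h_s, h_e))
                in_hot = (mids >= h_s) & (mids < h_e)
                rho[in_hot] *= config.hotspot_intensity
        profile_segments[chrom] = (starts, ends, rho)

    profile = RhoTrack("profile", "truth", dict(profile_segments))
    tracks: list[RhoTrack] = []
    for pop in config.population_names:
        for k in range(config.n_individuals_per_pop):
            ind = f"{pop}_{k + 1}"
            segs = {}
            for chrom, (s, e, r) in profile_segments.items():
                if config.rho_noise_shape > 0:
                    noise = rng.gamma(
                        config.rho_noise_shape,
                        1.0 / config.rho_noise_shape,
                        size=len(r),
                    )
                    segs[chrom] = (s, e, r * noise)
                else:
                    segs[chrom] = (s, e, r.copy())
            tracks.append(RhoTrack(ind, pop, segs))
    hotspot_ivs.sort(key=lambda iv: (iv.chrom, iv.start))
    return RhoSimResult(tracks=tracks, profile=profile,
                        hotspots=IntervalSet(hotspot_ivs, sorted=True))


# ---------------------------------------------------------------------------
# Phased haplotypes
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class HaplotypeSimResult:
    genotypes: GenotypeMatrix
    latent_blocks: IntervalSet     # true LD-block partition per chromosome
    haplotypes: dict[str, np.ndarray]  # chrom -> (2N, S_chrom) allele matrix


def simulate_haplotypes(
    layout: GenomeLayout, config: SimConfig
) -> HaplotypeSimResult:
    """Phased diploid genotypes from the ancestral-haplotype-pool model.

    SNP positions follow a Poisson process at ``snp_density``.  Each
    chromosome is partitioned into latent blocks with exponential lengths
    (mean ``block_length_mean``); inside a block each haploid genome
    copies one of ``haplotype_pool_size`` ancestral haplotypes drawn with
    Dirichlet frequencies, independently across blocks.  Only segregating
    (biallelic) sites are emitted, so a pool of one yields no variants.
    """
    rng = _rng(config, _STREAM_HAP)
    pops = config.population_names
    samples = [
        f"{pop}_{k + 1}" for pop in pops for k in range(config.n_individuals_per_pop)
    ]
    sample_pops = [s.rsplit("_", 1)[0] for s in samples]
    n_hap = 2 * len(samples)

    chrom_arr, pos_arr, ref_arr, alt_arr, gt_list = [], [], [], [], []
    latent: list[GenomicInterval] = []
    hap_by_chrom: dict[str, np.ndarray] = {}
    for chrom, L in layout.chrom_lengths.items():
        n_snp = rng.poisson(config.snp_density * L)
        pos = np.unique(rng.integers(1, L + 1, size=n_snp))  # 1-based
        # latent block boundaries
        bounds = [0]
        while bounds[-1] < L:
            bounds.append(bounds[-1] + max(1, int(rng.exponential(config.block_length_mean))))
        bounds[-1] = L
        bounds_arr = np.array(bounds, dtype=np.int64)
        for b0, b1 in zip(bounds_arr[:-1], bounds_arr[1:]):
            latent.append(GenomicInterval(chrom, int(b0), int(b1)))
        block_of = np.searchsorted(bounds_arr, pos - 1, side="right") - 1

        H = np.zeros((n_hap, len(pos)), dtype=np.int8)
        K = config.haplotype_pool_size
        for b in range(len(bounds_arr) - 1):
            sites = np.where(block_of == b)[0]
            if len(sites) == 0:
                continue
            pool = rng.integers(0, 2, size=(K, len(sites))).astype(np.int8)
            freqs = rng.dirichlet(np.ones(K))
            choice = rng.choice(K, size=n_hap, p=freqs)
            H[:, sites] = pool[choice]
        seg = (H.sum(axis=0) > 0) & (H.sum(axis=0) < n_hap)
        pos, H = pos[seg], H[:, seg]
        hap_by_chrom[chrom] = H
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        chrom_arr.extend([chrom] * len(pos))
        pos_arr.append(pos)
        ref_arr.append(_BASES[ref_idx])
        alt_arr.append(_BASES[alt_idx])
        # (S, N, 2)
        gt = H.T.reshape(len(pos), len(samples), 2)
        gt_list.append(gt)

    S = len(chrom_arr)
    gm = GenotypeMatrix(
        chrom=np.array(chrom_arr, dtype=object),
        pos=(np.concatenate(pos_arr) if S else np.zeros(0, dtype=np.int64)),
        ref=(np.concatenate(ref_arr) if S else np.zeros(0, dtype=object)),
        alt=(np.concatenate(alt_arr) if S else np.zeros(0, dtype=object)),
        samples=samples,
        populations=sample_pops,
        gt=(
            np.concatenate(gt_list)
            if S
            else np.zeros((0, len(samples), 2), dtype=np.int8)
        ),
        phased=np.ones((S, len(samples)), dtype=bool),
    )
    return HaplotypeSimResult(
        genotypes=gm,
        latent_blocks=IntervalSet(latent, sorted=True),
        haplotypes=hap_by_chrom,
    )


def write_vcf(gm: GenotypeMatrix, layout: GenomeLayout, path: str | Path) -> None:
    """Write a phased VCF (GT-only) readable by cyvcf2/bcftools."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clarecomb-synthdata\n")
        for chrom, L in layout.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for s in range(gm.n_sites):
            gts = "\t".join(
                f"{gm.gt[s, n, 0]}{'|' if gm.phased[s, n] else '/'}{gm.gt[s, n, 1]}"
                for n in range(gm.n_samples)
            )
            fh.write(
                f"{gm.chrom[s]}\t{gm.pos[s]}\t{gm.chrom[s]}:{gm.pos[s]}\t"
                f"{gm.ref[s]}\t{gm.alt[s]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TE insertions
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    placement_mode: str
    placement_params: dict
    sharing_classes: list[str]             # per ancestral insertion
    insertion_intervals: list[GenomicInterval]
    latent_blocks: Optional[IntervalSet] = None
    avoided_blocks: Optional[IntervalSet] = None  # block_avoiding reference set
    true_window_rho: Optional[dict[str, list[float]]] = None

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "placement_mode": self.placement_mode,
            "placement_params": self.placement_params,
            "sharing_classes": self.sharing_classes,
            "insertions": [
                [iv.chrom, iv.start, iv.end] for iv in self.insertion_intervals
            ],
            "latent_blocks": (
                [[iv.chrom, iv.start, iv.end] for iv in self.latent_blocks]
                if self.latent_blocks is not None
                else None
            ),
            "true_window_rho": self.true_window_rho,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class InsertionSimResult:
    clusters: list[ClaCluster]             # ancestral loci with population sets
    per_population: dict[str, IntervalSet]  # BED-ready views per population
    ground_truth: GroundTruth


def _truncated_lognormal(
    rng: np.random.Generator, n: int, config: SimConfig
) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    filled = 0
    for _ in range(1000):
        draw = rng.lognormal(config.te_len_meanlog, config.te_len_sdlog, size=2 * n)
        draw = draw[(draw >= config.te_len_min) & (draw <= config.te_len_max)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take].astype(np.int64)
        filled += take
        if filled == n:
            return out
    raise SimulationError("TE length law truncation rejected too many draws")


def simulate_insertions(
    layout: GenomeLayout,
    config: SimConfig,
    rho_tracks: Optional[Sequence[RhoTrack]] = None,
    blocks: Optional[IntervalSet] = None,
) -> InsertionSimResult:
    """Population-structured TE insertion loci.

    Sharing classes are assigned to ancestral loci first (deterministic
    counts: round(fraction * total)); populations then inherit positions
    exactly, so shared insertions are coordinate-identical across
    populations.  Placement density is uniform, proportional to
    exp(-beta * rho(x)) (``rho_coupled``; requires ``rho_tracks``), or
    uniform with insertions overlapping a block rejected with probability
    q (``block_avoiding``; requires ``blocks``).  Ancestral loci never
    overlap one another; an exhausted rejection budget raises
    :class:`SimulationError` naming the constraint.
    """
    mode = config.placement_mode
    if mode == "rho_coupled" and not rho_tracks:
        raise ValueError("rho_coupled placement requires rho_tracks")
    if mode == "block_avoiding" and blocks is None:
        raise ValueError("block_avoiding placement requires blocks")
    rng = _rng(config, _STREAM_TE)
    n_pops = config.n_populations
    pops = config.population_names
    N = config.te_total
    n_all = int(round(config.te_shared_fraction_all * N))
    n_partial = int(round(config.te_shared_fraction_partial * N))
    n_unique = N - n_all - n_partial
    if n_unique < 0:
        raise ValueError("sharing fractions leave no room for unique insertions")
    classes = ["shared_all"] * n_all + ["shared_partial"] * n_partial + [
        "unique"
    ] * n_unique

    lengths = _truncated_lognormal(rng, N, config)
    chrom_names = list(layout.chrom_lengths)
    chrom_L = np.array([layout.chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_L / chrom_L.sum()

    # rho-coupled weights per segment of the averaged track grid
    seg_weights: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if mode == "rho_coupled":
        first = rho_tracks[0]
        for chrom, (s, e, _) in first.segments.items():
            rho_mean = np.mean(
                [t.segments[chrom][2] for t in rho_tracks if chrom in t.segments],
                axis=0,
            )
            w = np.exp(-config.placement_beta * rho_mean) * (e - s)
            seg_weights[chrom] = (s, e, w / w.sum())

    block_idx = blocks.by_chrom() if blocks is not None else {}
    block_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in block_idx.items():
        bs = np.array([iv.start for iv in ivs], dtype=np.int64)
        be = np.array([iv.end for iv in ivs], dtype=np.int64)
        order = np.argsort(bs)
        block_arrays[chrom] = (bs[order], np.maximum.accumulate(be[order]))

    def overlaps_block(chrom: str, s: int, e: int) -> bool:
        if chrom not in block_arrays:
            return False
        bs, be_cm = block_arrays[chrom]
        i = np.searchsorted(bs, e, side="left")
        return bool(i > 0 and be_cm[i - 1] > s)

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def overlaps_placed(chrom: str, s: int, e: int) -> bool:
        lst = placed[chrom]
        i = bisect.bisect_right(lst, (s, np.iinfo(np.int64).max))
        if i > 0 and lst[i - 1][1] > s:
            return True
        return i < len(lst) and lst[i][0] < e

    intervals: list[GenomicInterval] = []
    for k in range(N):
        L_te = int(lengths[k])
        ok = False
        for _ in range(config.placement_max_attempts):
            if mode == "rho_coupled":
                ci = int(rng.choice(len(chrom_names), p=chrom_p))
                chrom = chrom_names[ci]
                s_arr, e_arr, w = seg_weights[chrom]
                seg = int(rng.choice(len(w), p=w))
                start = int(rng.integers(s_arr[seg], e_arr[seg]))
            else:
                ci = int(rng.choice(len(chrom_names), p=chrom_p))
                chrom = chrom_names[ci]
                high = layout.chrom_lengths[chrom] - L_te
                if high < 0:
                    continue
                start = int(rng.integers(0, high + 1))
            end = min(start + L_te, layout.chrom_lengths[chrom])
            if end - start < 1:
                continue
            if overlaps_placed(chrom, start, end):
                continue
            if mode == "block_avoiding" and overlaps_block(chrom, start, end):
                if rng.random() < config.placement_q:
                    continue
            bisect.insort(placed[chrom], (start, end))
            intervals.append(GenomicInterval(chrom, start, end))
            ok = True
            break
        if not ok:
            raise SimulationError(
                f"placement budget exhausted for insertion {k} "
                f"(mode={mode}, constraint=no-overlap"
                + ("/block-avoidance" if mode == "block_avoiding" else "")
                + ")"
            )

    clusters: list[ClaCluster] = []
    for k, iv in enumerate(intervals):
        cls = classes[k]
        if cls == "shared_all":
            members = frozenset(pops)
        elif cls == "shared_partial":
            size = int(rng.integers(2, n_pops))  # 2 .. n_pops - 1
            members = frozenset(
                pops[i] for i in rng.choice(n_pops, size=size, replace=False)
            )
        else:
            members = frozenset({pops[int(rng.integers(0, n_pops))]})
        clusters.append(ClaCluster(iv, members, n_pops))

    per_pop = {
        pop: IntervalSet(
            sorted(
                (c.interval for c in clusters if pop in c.populations_present),
                key=lambda iv: (iv.chrom, iv.start),
            ),
            sorted=True,
        )
        for pop in pops
    }
    gt = GroundTruth(
        placement_mode=mode,
        placement_params={
            "beta": config.placement_beta if mode == "rho_coupled" else None,
            "q": config.placement_q if mode == "block_avoiding" else None,
        },
        sharing_classes=classes,
        insertion_intervals=intervals,
    )
    return InsertionSimResult(clusters=clusters, per_population=per_pop, ground_truth=gt)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimConfig
    layout: GenomeLayout
    rho: RhoSimResult
    haplotypes: HaplotypeSimResult
    insertions: InsertionSimResult


def simulate_all(config: SimConfig) -> SyntheticDataset:
    """Run all four generators in order with their fixed-offset streams.

    For ``block_avoiding`` placement the avoided reference set is a
    random ``avoid_block_fraction`` subsample of the latent blocks (the
    full latent partition tiles the genome, which would make avoidance
    vacuous); the subsample is recorded in the ground truth.
    """
    layout = simulate_genome(config)
    rho = simulate_rho(layout, config)
    haps = simulate_haplotypes(layout, config)
    avoided: Optional[IntervalSet] = None
    if config.placement_mode == "block_avoiding":
        sel_rng = _rng(config, _STREAM_TE + 10)
        keep = sel_rng.random(len(haps.latent_blocks)) < config.avoid_block_fraction
        avoided = IntervalSet(
            [iv for iv, k in zip(haps.latent_blocks, keep) if k], sorted=True
        )
    ins = simulate_insertions(
        layout,
        config,
        rho_tracks=rho.tracks if config.placement_mode == "rho_coupled" else None,
        blocks=avoided,
    )
    ins.ground_truth.latent_blocks = haps.latent_blocks
    ins.ground_truth.avoided_blocks = avoided
    return SyntheticDataset(
        config=config, layout=layout, rho=rho, haplotypes=haps, insertions=ins
    )
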