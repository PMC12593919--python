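"""End-to-end driver chaining every analysis stage on synthetic or user data.

Stage order mirrors the analysis this package reproduces: simulate (or
load) inputs -> haplotype blocks -> recombination windows, summaries and
hotspots -> distance decay -> overlap / permutation statistics ->
population sharing.  Every stage writes its tables under the output
directory; a run log records the master seed, derived seeds and
parameters, so a fixed seed reproduces the whole bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decay import (
    build_decay,
    correlate_decay,
    decay_heatmap_table,
    split_by_size,
)
from .intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    read_bed,
    read_chrom_sizes,
    write_bed,
)
from .ldblocks import (
    BlockParams,
    blocks_to_bed,
    filter_blocks,
    filter_sites,
    find_blocks,
    read_vcf,
    write_det,
)
from .overlap import (
    InfeasiblePlacementError,
    binomial_test,
    classify_overlap,
    permutation_test,
    wilcoxon_rank_sum,
)
from .popshare import merge_population_calls, sharing_percentages, tally_sharing
from .recomb import (
    classify_hotspots,
    pool_windows,
    read_rho_track,
    split_arms,
    summarize_rho,
    write_rho_track,
)
from .synthdata import SimConfig, simulate_all, write_vcf

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ConfigError",
    "DataError",
    "StageError",
    "run_pipeline",
]

log = logging.getLogger("clarecomb")


class PipelineError(RuntimeError):
    pass


class ConfigError(PipelineError):
    pass


class DataError(PipelineError):
    pass


class StageError(PipelineError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs and knobs of the full pipeline.

    Either ``sim`` is set (synthetic mode) or the explicit input paths
    are: a phased VCF, a rho-track manifest TSV (individual, population,
    path), per-population insertion BEDs, a chromosome-sizes TSV and an
    optional centromere BED.
    """

    output_dir: Path
    sim: Optional[SimConfig] = None
    vcf: Optional[Path] = None
    rho_manifest: Optional[Path] = None
    insertion_beds: dict[str, Path] = field(default_factory=dict)
    chrom_sizes: Optional[Path] = None
    centromeres: Optional[Path] = None
    # analysis parameters (field defaults follow the study conventions)
    landscape_width: int = 10_000
    cla_decay_width: int = 100_000
    hb_decay_width: int = 1_000
    min_maf: float = 0.10
    max_missing: float = 0.05
    block_params: BlockParams = field(default_factory=BlockParams)
    min_block_len: int = 50
    n_perm: int = 5000
    perm_seed: int = 0
    centromere_flank_fraction: float = 0.05
    whole_chromosomes: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.landscape_width <= 0 or self.cla_decay_width <= 0 or self.hb_decay_width <= 0:
            raise ConfigError("window widths must be positive")
        if self.sim is None:
            missing = [
                name
                for name, p in (
                    ("vcf", self.vcf),
                    ("rho_manifest", self.rho_manifest),
                    ("chrom_sizes", self.chrom_sizes),
                )
                if p is None or not Path(p).exists()
            ]
            if not self.insertion_beds:
                missing.append("insertion_beds")
            else:
                missing += [
                    f"insertion_beds[{pop}]"
                    for pop, p in self.insertion_beds.items()
                    if not Path(p).exists()
                ]
            if missing:
                raise ConfigError(
                    "non-simulation mode requires existing inputs; missing: "
                    + ", ".join(missing)
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "sim" in d and d["sim"] is not None:
            d["sim"] = SimConfig(**d["sim"])
        if "block_params" in d and d["block_params"] is not None:
            d["block_params"] = BlockParams(**d["block_params"])
        if "insertion_beds" in d and d["insertion_beds"]:
            d["insertion_beds"] = {k: Path(v) for k, v in d["insertion_beds"].items()}
        for key in ("output_dir", "vcf", "rho_manifest", "chrom_sizes", "centromeres"):
            if d.get(key) is not None:
                d[key] = Path(d[key])
        if "whole_chromosomes" in d and d["whole_chromosomes"] is not None:
            d["whole_chromosomes"] = tuple(d["whole_chromosomes"])
        return cls(**d)


def _load_layout(config: PipelineConfig) -> GenomeLayout:
    sizes = read_chrom_sizes(config.chrom_sizes)
    centromeres = {}
    if config.centromeres is not None and Path(config.centromeres).exists():
        for iv in read_bed(config.centromeres):
            centromeres[iv.chrom] = GenomicInterval(iv.chrom, iv.start, iv.end)
    return GenomeLayout(chrom_lengths=sizes, centromeres=centromeres)


def _analysis_layout(layout: GenomeLayout, config: PipelineConfig) -> GenomeLayout:
    """Drop centromere annotations for chromosomes analysed whole."""
    if not config.whole_chromosomes:
        return layout
    return GenomeLayout(
        chrom_lengths=dict(layout.chrom_lengths),
        centromeres={
            c: iv
            for c, iv in layout.centromeres.items()
            if c not in config.whole_chromosomes
        },
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report bundle (also written as JSON).

    Any stage failure raises :class:`StageError` naming the stage;
    outputs of completed stages are retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "stages": {}}
    t0 = time.time()

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        if config.sim is not None:
            ds = simulate_all(config.sim)
            layout = ds.layout
            gm = ds.haplotypes.genotypes
            tracks = ds.rho.tracks
            per_pop = ds.insertions.per_population
            sim_dir = out / "synthetic"
            sim_dir.mkdir(exist_ok=True)
            config.sim.to_yaml(sim_dir / "sim_config.yaml")
            with open(sim_dir / "chrom_sizes.tsv", "w") as fh:
                for c, L in layout.chrom_lengths.items():
                    fh.write(f"{c}\t{L}\n")
            write_bed(
                IntervalSet(list(layout.centromeres.values()), sorted=True),
                sim_dir / "centromeres.bed",
            )
            write_vcf(gm, layout, sim_dir / "haplotypes.vcf")
            (sim_dir / "tracks").mkdir(exist_ok=True)
            for t in tracks:
                write_rho_track(t, sim_dir / "tracks" / f"{t.individual}.tsv")
            (sim_dir / "insertions").mkdir(exist_ok=True)
            for pop, ivset in per_pop.items():
                write_bed(ivset, sim_dir / "insertions" / f"{pop}.bed")
            ds.insertions.ground_truth.to_yaml(sim_dir / "ground_truth.yaml")
            report["stages"][stage] = {
                "mode": "simulate",
                "seed": config.sim.seed,
                "n_sites": gm.n_sites,
                "n_insertion_loci": len(ds.insertions.clusters),
            }
        else:
            layout = _load_layout(config)
            gm = read_vcf(config.vcf)
            manifest = pd.read_csv(
                config.rho_manifest,
                sep="\t",
                names=["individual", "population", "path"],
                header=None,
            )
            tracks = [
                read_rho_track(r.path, r.individual, r.population)
                for r in manifest.itertuples()
            ]
            per_pop = {
                pop: read_bed(path) for pop, path in config.insertion_beds.items()
            }
            report["stages"][stage] = {
                "mode": "load",
                "n_sites": gm.n_sites,
            }
    except PipelineError:
        raise
    except InfeasiblePlacementError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, exc) from exc

    analysis_layout = _analysis_layout(layout, config)

    # ---- stage: blocks -------------------------------------------------
    stage = "blocks"
    try:
        gm_f = filter_sites(gm, config.min_maf, config.max_missing)
        blocks_all = find_blocks(gm_f, config.block_params)
        blocks = filter_blocks(blocks_all, config.min_block_len)
        write_det(blocks, out / "blocks.det")
        block_set = blocks_to_bed(blocks)
        write_bed(block_set, out / "blocks.bed")
        report["stages"][stage] = {
            "n_sites_after_filter": gm_f.n_sites,
            "n_blocks_detected": len(blocks_all),
            "n_blocks_retained": len(blocks),
            "blocks_bp": block_set.total_bp(),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: windows / hotspots ------------------------------------
    stage = "windows"
    try:
        landscape = pool_windows(tracks, layout, config.landscape_width)
        landscape.values.reset_index().to_csv(
            out / f"windows_{config.landscape_width}.tsv", sep="\t", index=False
        )
        summaries = pd.concat(
            [
                summarize_rho(landscape, "chromosome").assign(group="chromosome"),
                summarize_rho(landscape, "population").assign(group="population"),
                summarize_rho(landscape, "total").assign(group="total"),
            ],
            ignore_index=True,
        )
        summaries.to_csv(out / "rho_summary.tsv", sep="\t", index=False)
        hotspots = classify_hotspots(landscape)
        write_bed(hotspots.union, out / "hotspots.bed")
        hotspots.thresholds.to_csv(out / "hotspot_thresholds.tsv", sep="\t", index=False)
        report["stages"][stage] = {
            "n_windows": int(len(landscape.values)),
            "n_hotspot_windows": len(hotspots.union),
            "total_mean_rho": float(
                summaries.loc[summaries["group"] == "total", "mean"].iloc[0]
            )
            if (summaries["group"] == "total").any()
            else None,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: decay --------------------------------------------------
    stage = "decay"
    try:
        results = {}
        cla_windows = pool_windows(tracks, layout, config.cla_decay_width)
        pops = sorted(set(landscape.populations.values()))
        for pop in pops:
            wmean = cla_windows.population_mean(pop)
            features = per_pop.get(pop, IntervalSet())
            by_size = split_by_size(features)
            for chrom in analysis_layout.chromosomes:
                parts = split_arms(analysis_layout, chrom)
                for part_label, part_iv in parts.items():
                    for klass, feats in by_size.items():
                        dsd = build_decay(
                            wmean, feats, part_iv, part_label, klass,
                            config.cla_decay_width,
                        )
                        results[(pop, chrom, part_label, klass, "pearson")] = (
                            correlate_decay(dsd, "pearson")
                        )
        hb_windows = pool_windows(tracks, layout, config.hb_decay_width)
        for pop in pops:
            wmean = hb_windows.population_mean(pop)
            for chrom in analysis_layout.chromosomes:
                whole = GenomicInterval(chrom, 0, layout.chrom_lengths[chrom])
                dsd = build_decay(
                    wmean, block_set, whole, "whole", "haplotype_block",
                    config.hb_decay_width,
                )
                results[(pop, chrom, "whole", "haplotype_block", "spearman")] = (
                    correlate_decay(dsd, "spearman")
                )
        heat = decay_heatmap_table(results)
        heat.to_csv(out / "decay_correlations.tsv", sep="\t", index=False)
        hb_rows = heat[heat["feature_class"] == "haplotype_block"]
        report["stages"][stage] = {
            "n_rows": int(len(heat)),
            "hb_spearman_mean_r": float(hb_rows["r"].mean())
            if len(hb_rows)
            else None,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: overlap ------------------------------------------------
    stage = "overlap"
    try:
        clusters = merge_population_calls(per_pop)
        placed = [
            c for c in clusters if c.interval.chrom in layout.chrom_lengths
        ]
        cluster_set = IntervalSet(
            [c.interval for c in placed], sorted=True
        )
        cls = classify_overlap(cluster_set, block_set)
        overlap_report: dict = {
            "n_clusters": cls.n_total,
            "n_inside": cls.n_inside,
            "n_outside": cls.n_outside,
        }
        binom = binomial_test(cls.n_outside, cls.n_total)
        overlap_report["binomial"] = {
            "k": binom.k,
            "n": binom.n,
            "point_estimate": binom.point_estimate_7dp,
            "p_value": binom.p_value,
        }
        sizes_in = [c.length_bp for c, f in zip(placed, cls.inside) if f]
        sizes_out = [c.length_bp for c, f in zip(placed, cls.inside) if not f]
        if sizes_in and sizes_out:
            w, p = wilcoxon_rank_sum(sizes_in, sizes_out)
            overlap_report["wilcoxon_cluster_size"] = {"W": w, "p_value": p}
        blen_with = [
            b.length for b, f in zip(block_set, cls.block_has_cluster) if f
        ]
        blen_without = [
            b.length for b, f in zip(block_set, cls.block_has_cluster) if not f
        ]
        if blen_with and blen_without:
            w, p = wilcoxon_rank_sum(blen_with, blen_without)
            overlap_report["wilcoxon_block_length"] = {"W": w, "p_value": p}
        if len(block_set) and len(cluster_set):
            perm = permutation_test(
                cluster_set,
                block_set,
                layout,
                statistic="n_overlapping",
                n_perm=config.n_perm,
                seed=config.perm_seed,
                alternative="auto",
            )
            overlap_report["permutation"] = {
                **{k: v for k, v in perm.as_dict().items()},
                "observed_outside": cls.n_total - perm.observed,
                "permuted_mean_outside": cls.n_total - perm.permuted_mean,
            }
        with open(out / "overlap_report.json", "w") as fh:
            json.dump(overlap_report, fh, indent=2)
        report["stages"][stage] = overlap_report
    except InfeasiblePlacementError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: sharing ------------------------------------------------
    stage = "sharing"
    try:
        tally = tally_sharing(
            clusters, analysis_layout, config.centromere_flank_fraction
        )
        tally.by_compartment.to_csv(out / "sharing_compartments.tsv", sep="\t")
        pct = sharing_percentages(tally)
        sharing = {
            "by_class": tally.by_class,
            "per_population": tally.per_population,
            "percentages": pct,
            "n_total": tally.n_total,
        }
        with open(out / "sharing.json", "w") as fh:
            json.dump(sharing, fh, indent=2)
        merged_rows = [
            (
                c.interval.chrom,
                c.interval.start,
                c.interval.end,
                ",".join(sorted(c.populations_present)),
                c.sharing,
            )
            for c in clusters
        ]
        pd.DataFrame(
            merged_rows, columns=["chrom", "start", "end", "populations", "sharing"]
        ).to_csv(out / "clusters_merged.tsv", sep="\t", index=False)
        report["stages"][stage] = sharing
    except Exception as exc:
        raise StageError(stage, exc) from exc

    report["runtime_s"] = round(time.time() - t0, 3)
    report["parameters"] = {
        "landscape_width": config.landscape_width,
        "cla_decay_width": config.cla_decay_width,
        "hb_decay_width": config.hb_decay_width,
        "min_maf": config.min_maf,
        "max_missing": config.max_missing,
        "min_block_len": config.min_block_len,
        "n_perm": config.n_perm,
        "perm_seed": config.perm_seed,
        "block_params": dataclasses.asdict(config.block_params),
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    log.info("pipeline finished in %.1fs", report["runtime_s"])
    return report
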