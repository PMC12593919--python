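"""Synthetic-data generator: determinism, closed forms, placement bias."""

import numpy as np
import pytest
from scipy import stats

from clarecomb.intervals import GenomicInterval, IntervalSet
from clarecomb.ldblocks import dprime_ci, em_haplotype_freqs
from clarecomb.synthdata import (
    SimConfig,
    SimulationError,
    simulate_all,
    simulate_genome,
    simulate_haplotypes,
    simulate_insertions,
    simulate_rho,
)


def small_config(**kw):
    base = dict(
        seed=1,
        n_chroms=2,
        chrom_lengths=(300_000, 200_000),
        n_populations=3,
        n_individuals_per_pop=2,
        te_total=90,
        te_shared_fraction_all=0.1,
        te_shared_fraction_partial=0.3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_mismatched_chrom_lengths(self):
        with pytest.raises(ValueError):
            SimConfig(n_chroms=3, chrom_lengths=(100, 100))

    def test_sharing_fractions_bounded(self):
        with pytest.raises(ValueError):
            small_config(te_shared_fraction_all=0.7, te_shared_fraction_partial=0.7)

    def test_partial_sharing_needs_three_populations(self):
        with pytest.raises(ValueError, match="3 populations"):
            small_config(n_populations=2, te_shared_fraction_partial=0.3)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=9)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SimConfig.from_yaml(p) == cfg


class TestGenome:
    def test_centromere_width_fraction(self):
        cfg = SimConfig(
            n_chroms=1, chrom_lengths=(1_000_000,), centromere_width_fraction=0.1,
            n_populations=3,
        )
        layout = simulate_genome(cfg)
        cen = layout.centromeres["chr1"]
        assert cen.length == 100_000
        assert cen.start == 450_000  # centred at the configured fraction

    def test_chromosome_count(self):
        layout = simulate_genome(small_config())
        assert len(layout.chrom_lengths) == 2

    def test_deterministic(self):
        a = simulate_genome(small_config())
        b = simulate_genome(small_config())
        assert a.chrom_lengths == b.chrom_lengths and a.centromeres == b.centromeres


class TestRho:
    def test_noiseless_centromere_midpoint_closed_form(self):
        cfg = small_config(rho_noise_shape=0.0, hotspot_rate_per_mb=0.0)
        layout = simulate_genome(cfg)
        res = simulate_rho(layout, cfg)
        track = res.tracks[0]
        cen = layout.centromeres["chr1"]
        mid = (cen.start + cen.end) // 2
        s, e, r = track.segments["chr1"]
        seg = np.searchsorted(e, mid, side="right")
        assert r[seg] == pytest.approx(
            cfg.rho_baseline * cfg.rho_centromere_factor, rel=1e-12
        )

    def test_gamma_noise_preserves_profile_mean(self):
        # one long chromosome -> 10^4 segments; Monte-Carlo mean vs closed form
        cfg = SimConfig(
            seed=4, n_chroms=1, chrom_lengths=(10_000_000,),
            n_populations=3, n_individuals_per_pop=1,
            hotspot_rate_per_mb=0.0, rho_noise_shape=10.0,
        )
        layout = simulate_genome(cfg)
        noisy = simulate_rho(layout, cfg)
        noiseless = simulate_rho(
            layout, SimConfig(**{**cfg.__dict__, "rho_noise_shape": 0.0})
        )
        r_noisy = noisy.tracks[0].segments["chr1"][2]
        r_clean = noiseless.tracks[0].segments["chr1"][2]
        # segment value = clean * Gamma(k, 1/k); relative SE of the mean
        k = cfg.rho_noise_shape
        se = np.sqrt(np.sum(r_clean**2) / k) / len(r_clean)
        assert abs(r_noisy.mean() - r_clean.mean()) < 3 * se

    def test_same_seed_identical_tracks(self):
        cfg = small_config()
        layout = simulate_genome(cfg)
        a = simulate_rho(layout, cfg).tracks
        b = simulate_rho(layout, cfg).tracks
        for ta, tb in zip(a, b):
            for chrom in ta.segments:
                assert np.array_equal(ta.segments[chrom][2], tb.segments[chrom][2])

    def test_hotspots_elevate_profile(self):
        cfg = small_config(rho_noise_shape=0.0, hotspot_rate_per_mb=20.0)
        layout = simulate_genome(cfg)
        res = simulate_rho(layout, cfg)
        assert len(res.hotspots) > 0
        s, e, r = res.profile.segments["chr1"]
        assert r.max() > cfg.rho_baseline * cfg.rho_telomere_factor


class TestHaplotypes:
    def test_pool_size_one_is_monomorphic(self):
        cfg = small_config(haplotype_pool_size=1)
        haps = simulate_haplotypes(simulate_genome(cfg), cfg)
        assert haps.genotypes.n_sites == 0

    def test_pool_size_two_gives_perfect_intrablock_ld(self):
        cfg = small_config(haplotype_pool_size=2, block_length_mean=20_000)
        haps = simulate_haplotypes(simulate_genome(cfg), cfg)
        gm = haps.genotypes
        # pick intra-block site pairs on chr1 and check |D'| = 1
        blocks = [iv for iv in haps.latent_blocks if iv.chrom == "chr1"]
        checked = 0
        on_chr1 = np.where(gm.chrom == "chr1")[0]
        for blk in blocks:
            sites = [
                i for i in on_chr1 if blk.start < gm.pos[i] <= blk.end
            ]
            for i, j in zip(sites, sites[1:]):
                f, n = em_haplotype_freqs(gm, i, j)
                st_ = dprime_ci(f, n)
                assert st_.Dprime == pytest.approx(1.0, abs=1e-9)
                checked += 1
            if checked >= 20:
                break
        assert checked > 0

    def test_same_seed_identical_genotypes(self):
        cfg = small_config()
        layout = simulate_genome(cfg)
        a = simulate_haplotypes(layout, cfg).genotypes
        b = simulate_haplotypes(layout, cfg).genotypes
        assert np.array_equal(a.gt, b.gt) and np.array_equal(a.pos, b.pos)

    def test_all_sites_segregating_biallelic(self):
        cfg = small_config()
        gm = simulate_haplotypes(simulate_genome(cfg), cfg).genotypes
        assert gm.n_sites > 0
        counts = gm.gt.reshape(gm.n_sites, -1).sum(axis=1)
        assert np.all(counts > 0) and np.all(counts < 2 * gm.n_samples)
        assert np.all(gm.ref != gm.alt)


class TestInsertions:
    def test_deterministic_sharing_class_counts(self):
        cfg = small_config(
            te_total=200,
            te_shared_fraction_all=0.1,
            te_shared_fraction_partial=0.3,
            n_populations=5,
            n_individuals_per_pop=1,
        )
        res = simulate_insertions(simulate_genome(cfg), cfg)
        classes = res.ground_truth.sharing_classes
        assert classes.count("shared_all") == 20
        assert classes.count("shared_partial") == 60
        assert classes.count("unique") == 120
        # cluster objects agree with the recorded classes
        assert [c.sharing for c in res.clusters] == classes

    def test_lengths_truncated_to_te_range(self):
        cfg = small_config(te_total=300)
        res = simulate_insertions(simulate_genome(cfg), cfg)
        lens = np.array([c.length_bp for c in res.clusters])
        assert lens.min() >= cfg.te_len_min
        assert lens.max() <= cfg.te_len_max

    def test_shared_insertions_coordinate_identical_across_pops(self):
        cfg = small_config()
        res = simulate_insertions(simulate_genome(cfg), cfg)
        for cl in res.clusters:
            for pop in cl.populations_present:
                assert any(
                    iv.start == cl.interval.start and iv.chrom == cl.interval.chrom
                    for iv in res.per_population[pop]
                )

    def test_beta_zero_positions_are_uniform(self):
        # KS test of midpoints against uniform on one chromosome, n = 2000
        cfg = SimConfig(
            seed=11, n_chroms=1, chrom_lengths=(20_000_000,),
            n_populations=3, n_individuals_per_pop=1,
            te_total=2000, te_shared_fraction_all=0.0,
            te_shared_fraction_partial=0.0,
            placement_mode="rho_coupled", placement_beta=0.0,
        )
        layout = simulate_genome(cfg)
        rho = simulate_rho(layout, cfg)
        res = simulate_insertions(layout, cfg, rho_tracks=rho.tracks)
        mids = np.array(
            [(c.interval.start + c.interval.end) / 2 for c in res.clusters]
        )
        p = stats.kstest(mids / 20_000_000, "uniform").pvalue
        assert p > 0.01

    def test_q_one_hard_exclusion(self):
        cfg = small_config(placement_mode="block_avoiding", placement_q=1.0)
        layout = simulate_genome(cfg)
        blocks = IntervalSet(
            [GenomicInterval("chr1", 0, 100_000), GenomicInterval("chr2", 0, 50_000)],
            sorted=True,
        )
        res = simulate_insertions(layout, cfg, blocks=blocks)
        for cl in res.clusters:
            for blk in blocks:
                assert not cl.interval.overlaps(blk)

    def test_infeasible_placement_raises(self):
        cfg = small_config(
            placement_mode="block_avoiding", placement_q=1.0,
            placement_max_attempts=50,
        )
        layout = simulate_genome(cfg)
        # blocks covering both chromosomes completely: no legal position
        blocks = IntervalSet(
            [GenomicInterval("chr1", 0, 300_000), GenomicInterval("chr2", 0, 200_000)],
            sorted=True,
        )
        with pytest.raises(SimulationError, match="budget"):
            simulate_insertions(layout, cfg, blocks=blocks)

    def test_rho_coupled_requires_tracks(self):
        cfg = small_config(placement_mode="rho_coupled")
        with pytest.raises(ValueError, match="rho_tracks"):
            simulate_insertions(simulate_genome(cfg), cfg)


class TestFullDataset:
    def test_simulate_all_deterministic(self):
        a = simulate_all(small_config())
        b = simulate_all(small_config())
        assert np.array_equal(a.haplotypes.genotypes.gt, b.haplotypes.genotypes.gt)
        assert [c.interval for c in a.insertions.clusters] == [
            c.interval for c in b.insertions.clusters
        ]
        ta = a.rho.tracks[0].segments["chr1"][2]
        tb = b.rho.tracks[0].segments["chr1"][2]
        assert np.array_equal(ta, tb)

    def test_regenerating_one_layer_does_not_perturb_another(self):
        # different TE totals must not change the haplotype draw (stream isolation)
        a = simulate_all(small_config(te_total=60))
        b = simulate_all(small_config(te_total=120))
        assert np.array_equal(a.haplotypes.genotypes.gt, b.haplotypes.genotypes.gt)
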