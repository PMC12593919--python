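"""Gabriel CI haplotype blocks: EM counting, D' CI oracle cases, assembly."""

import numpy as np
import pytest

from clarecomb.intervals import GenomicInterval
from clarecomb.ldblocks import (
    BlockParams,
    GenotypeMatrix,
    HaplotypeBlock,
    blocks_to_det,
    dprime_ci,
    em_haplotype_freqs,
    filter_blocks,
    filter_sites,
    find_blocks,
    read_vcf,
)
from clarecomb.synthdata import SimConfig, simulate_genome, simulate_haplotypes, write_vcf


def gm_from_haplotypes(H, pos=None, chrom="c1", phased=True):
    """Build a GenotypeMatrix from a (2N, S) haplotype allele matrix."""
    H = np.asarray(H, dtype=np.int8)
    n_hap, S = H.shape
    assert n_hap % 2 == 0
    N = n_hap // 2
    if pos is None:
        pos = np.arange(1, S + 1) * 100
    gt = H.T.reshape(S, N, 2)
    return GenotypeMatrix(
        chrom=np.array([chrom] * S, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * S, dtype=object),
        alt=np.array(["G"] * S, dtype=object),
        samples=[f"s{i}" for i in range(N)],
        populations=["p"] * N,
        gt=gt,
        phased=np.full((S, N), phased, dtype=bool),
    )


class TestFilterSites:
    def make(self, mafs, missing_fracs, n_samples=20):
        S = len(mafs)
        gt = np.zeros((S, n_samples, 2), dtype=np.int8)
        for s, (maf, mf) in enumerate(zip(mafs, missing_fracs)):
            n_alt = int(round(maf * 2 * n_samples))
            flat = np.zeros(2 * n_samples, dtype=np.int8)
            flat[:n_alt] = 1
            gt[s] = flat.reshape(n_samples, 2)
            n_miss = int(round(mf * n_samples))
            gt[s, :n_miss] = -1
        return GenotypeMatrix(
            chrom=np.array(["c1"] * S, dtype=object),
            pos=np.arange(1, S + 1) * 10,
            ref=np.array(["A"] * S, dtype=object),
            alt=np.array(["G"] * S, dtype=object),
            samples=[f"s{i}" for i in range(n_samples)],
            populations=["p"] * n_samples,
            gt=gt,
            phased=np.ones((S, n_samples), dtype=bool),
        )

    def test_maf_threshold(self):
        g = self.make([0.05, 0.10, 0.30], [0, 0, 0])
        out = filter_sites(g, min_maf=0.10, max_missing=0.05)
        assert out.n_sites == 2  # the 5% site is dropped, 10% kept (>=)

    def test_missing_threshold(self):
        g = self.make([0.3, 0.3], [0.06, 0.04], n_samples=50)
        out = filter_sites(g, min_maf=0.10, max_missing=0.05)
        assert out.n_sites == 1

    def test_identity_when_all_pass(self):
        g = self.make([0.2, 0.4, 0.5], [0, 0, 0])
        out = filter_sites(g)
        assert np.array_equal(out.pos, g.pos)


class TestEmHaplotypeFreqs:
    def test_phased_equals_direct_counting(self):
        H = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])  # {AB, AB, ab, ab}
        g = gm_from_haplotypes(H)
        f, n = em_haplotype_freqs(g, 0, 1)
        assert n == 4
        np.testing.assert_array_equal(f, [0.5, 0.0, 0.0, 0.5])

    def test_phased_random_matches_counting_exactly(self):
        rng = np.random.default_rng(3)
        H = rng.integers(0, 2, size=(40, 6)).astype(np.int8)
        g = gm_from_haplotypes(H)
        for i in range(5):
            f, n = em_haplotype_freqs(g, i, i + 1)
            expect = np.zeros(4)
            for h in range(40):
                expect[2 * H[h, i] + H[h, i + 1]] += 1
            np.testing.assert_array_equal(f, expect / 40)

    def test_unphased_double_het_symmetric_fixed_point(self):
        # a single unphased double heterozygote: EM stays at the symmetric
        # solution selected by the equal-split initialisation
        g = gm_from_haplotypes(np.array([[0, 1], [1, 0]]), phased=False)
        f, n = em_haplotype_freqs(g, 0, 1)
        assert n == 2
        np.testing.assert_allclose(f, [0.25, 0.25, 0.25, 0.25])

    def test_monomorphic_second_locus_gives_zero_D(self):
        H = np.array([[0, 0], [1, 0], [0, 0], [1, 0]])
        g = gm_from_haplotypes(H)
        f, n = em_haplotype_freqs(g, 0, 1)
        pA = f[2] + f[3]
        pB = f[1] + f[3]
        assert f[3] - pA * pB == pytest.approx(0.0, abs=1e-15)

    def test_all_missing_raises(self):
        g = gm_from_haplotypes(np.array([[0, 0], [1, 1]]))
        g.gt[:] = -1
        with pytest.raises(ValueError, match="missing"):
            em_haplotype_freqs(g, 0, 1)

    def test_unphased_em_recovers_strong_ld(self):
        # mixture dominated by cis gametes; EM should push mass to cis
        rng = np.random.default_rng(5)
        H = np.zeros((60, 2), dtype=np.int8)
        H[:30] = [0, 0]
        H[30:] = [1, 1]
        g = gm_from_haplotypes(H, phased=False)
        f, n = em_haplotype_freqs(g, 0, 1)
        assert f[0] + f[3] > 0.99


class TestDprimeCI:
    def test_perfect_ld_large_n(self):
        st = dprime_ci(np.array([0.5, 0, 0, 0.5]), 200)
        assert st.Dprime == pytest.approx(1.0)
        assert st.ci_low > 0.9
        assert st.ci_high == pytest.approx(1.0)
        assert st.klass == "strong_ld"

    def test_independent_loci_strong_recomb(self):
        st = dprime_ci(np.array([0.25, 0.25, 0.25, 0.25]), 200)
        assert st.ci_high < 0.90
        assert st.klass == "strong_recomb"

    def test_small_n_wide_ci_uninformative(self):
        # 4 chromosomes with D' = 1 but almost no evidence: CI spans most
        # of [0, 1] and the pair is uninformative
        st = dprime_ci(np.array([2, 0, 1, 1]) / 4, 4)
        assert st.ci_high - st.ci_low > 0.5
        assert st.klass == "uninformative"

    def test_monomorphic_pair_flagged_undefined(self):
        st = dprime_ci(np.array([0.5, 0.5, 0.0, 0.0]), 100)
        assert st.undefined and st.klass == "uninformative"

    def test_evidence_monotonicity(self):
        # same proportions, 10x the chromosomes: ci_low must not decrease
        weak = dprime_ci(np.array([0.5, 0, 0, 0.5]), 20)
        strong = dprime_ci(np.array([0.5, 0, 0, 0.5]), 200)
        assert strong.ci_low >= weak.ci_low

    def test_ci_bounds_ordered(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            f = rng.dirichlet(np.ones(4))
            st = dprime_ci(f, 60)
            if not st.undefined:
                assert 0 <= st.ci_low <= st.ci_high <= 1
                assert 0 <= st.Dprime <= 1


def perfect_ld_haplotypes(n_hap, n_snps, rng=None):
    """Two complementary haplotypes only -> every pair is in perfect LD."""
    H = np.zeros((n_hap, n_snps), dtype=np.int8)
    H[n_hap // 2 :] = 1
    return H


class TestFindBlocks:
    def test_three_snps_all_strong_one_block(self):
        g = gm_from_haplotypes(perfect_ld_haplotypes(200, 3))
        blocks = find_blocks(g)
        assert len(blocks) == 1
        assert blocks[0].n_snps == 3

    def test_independent_snps_no_blocks(self):
        rng = np.random.default_rng(17)
        # independent balanced columns at large n: strong recombination
        H = np.stack([rng.permutation([0] * 100 + [1] * 100) for _ in range(4)], axis=1)
        g = gm_from_haplotypes(H.astype(np.int8))
        assert find_blocks(g) == []

    def test_two_ld_islands_give_two_blocks(self):
        rng = np.random.default_rng(23)
        left = perfect_ld_haplotypes(200, 3)
        right = left[rng.permutation(200)]  # same LD island, shuffled labels
        H = np.concatenate([left, right], axis=1).astype(np.int8)
        g = gm_from_haplotypes(H, pos=[100, 200, 300, 5000, 5100, 5200])
        blocks = find_blocks(g)
        assert len(blocks) == 2
        assert [b.n_snps for b in blocks] == [3, 3]

    def test_outermost_pair_of_each_block_is_strong_ld(self):
        cfg = SimConfig(
            seed=6, n_chroms=1, chrom_lengths=(100_000,),
            n_populations=5, n_individuals_per_pop=4,
            haplotype_pool_size=2, snp_density=0.003,
        )
        haps = simulate_haplotypes(simulate_genome(cfg), cfg)
        g = filter_sites(haps.genotypes)
        blocks = find_blocks(g)
        assert blocks
        for b in blocks:
            first, last = b.snp_ids[0], b.snp_ids[-1]
            i = int(np.where(g.pos == int(first.split(":")[1]))[0][0])
            j = int(np.where(g.pos == int(last.split(":")[1]))[0][0])
            f, n = em_haplotype_freqs(g, i, j)
            assert dprime_ci(f, n).klass == "strong_ld"

    def test_max_kb_caps_block_span(self):
        g = gm_from_haplotypes(
            perfect_ld_haplotypes(200, 3), pos=[100, 500_000, 2_000_100]
        )
        blocks = find_blocks(g, BlockParams(max_kb=1000))
        # outermost pair spans ~2 Mb > 1 Mb: best candidate is the 500 kb pair
        assert len(blocks) == 1
        assert blocks[0].length_bp <= 1_000_000

    def test_duplicate_positions_rejected(self):
        g = gm_from_haplotypes(perfect_ld_haplotypes(20, 2), pos=[100, 100])
        with pytest.raises(ValueError, match="duplicate"):
            find_blocks(g)


class TestFilterBlocks:
    def make_block(self, length, chrom="c1", start=1000):
        return HaplotypeBlock(
            interval=GenomicInterval(chrom, start, start + length),
            n_snps=2,
            snp_ids=(f"{chrom}:{start + 1}", f"{chrom}:{start + length + 1}"),
        )

    def test_boundary_at_min_length(self):
        assert filter_blocks([self.make_block(49)], 50) == []
        kept = filter_blocks([self.make_block(50)], 50)
        assert len(kept) == 1

    def test_census_sizes(self):
        blocks = [self.make_block(L, start=10_000 * k)
                  for k, L in enumerate([2, 49, 50, 22_367])]
        assert sorted(b.length_bp for b in filter_blocks(blocks)) == [50, 22_367]


class TestVcfRoundTrip:
    def test_simulated_vcf_reads_back_identically(self, tmp_path):
        cfg = SimConfig(
            seed=2, n_chroms=1, chrom_lengths=(50_000,),
            n_populations=3, n_individuals_per_pop=2,
        )
        layout = simulate_genome(cfg)
        haps = simulate_haplotypes(layout, cfg)
        path = tmp_path / "sim.vcf"
        write_vcf(haps.genotypes, layout, path)
        back = read_vcf(path)
        assert back.samples == haps.genotypes.samples
        assert np.array_equal(back.pos, haps.genotypes.pos)
        assert np.array_equal(back.gt, haps.genotypes.gt)
        assert back.fully_phased()

    def test_det_table_columns(self):
        g = gm_from_haplotypes(perfect_ld_haplotypes(200, 3), pos=[100, 200, 300])
        det = blocks_to_det(find_blocks(g))
        assert list(det.columns) == ["CHR", "BP1", "BP2", "KB", "NSNPS", "SNPS"]
        assert det.iloc[0]["BP1"] == 100 and det.iloc[0]["BP2"] == 300
        assert det.iloc[0]["KB"] == pytest.approx(0.2)
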