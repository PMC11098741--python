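"""Generator fidelity: determinism, LD decay, depth and cosegregation."""

import numpy as np
import pytest

from scsnv.simulate import (
    SomaticSite,
    clone_population,
    simulate_cells,
    simulate_panel,
    simulate_sample,
)


class TestPanel:
    def test_same_seed_bit_identical(self):
        a = simulate_panel(n_hap=20, n_sites=100, seed=5)
        b = simulate_panel(n_hap=20, n_sites=100, seed=5)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)
        assert a.ref == b.ref and a.alt == b.alt

    def test_maf_floor_enforced(self):
        p = simulate_panel(n_hap=40, n_sites=300, maf_min=0.05, seed=9)
        assert p.maf().min() >= 0.05 - 1e-12

    def test_r2_decays_with_distance(self):
        """Mean r^2 below 1 kb exceeds mean r^2 beyond 100 kb."""
        p = simulate_panel(
            n_hap=40, n_sites=500, span_bp=1_000_000, recomb_intensity=1e-5,
            maf_min=0.05, seed=11,
        )
        H = p.haplotypes.astype(float)
        Hc = H - H.mean(axis=0)
        sd = H.std(axis=0)
        corr = (Hc.T @ Hc) / len(H) / np.outer(sd, sd)
        r2 = corr**2
        d = np.abs(p.positions[:, None] - p.positions[None, :])
        iu = np.triu_indices(p.n_sites, k=1)
        near = r2[iu][d[iu] < 1_000]
        far = r2[iu][d[iu] > 100_000]
        assert len(near) > 10 and len(far) > 10
        assert near.mean() > far.mean()

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_panel(n_hap=2, n_sites=100)
        with pytest.raises(ValueError):
            simulate_panel(n_hap=10, n_sites=1)
        with pytest.raises(ValueError):
            simulate_panel(n_hap=10, n_sites=10, maf_min=0.6)


class TestSample:
    def test_no_breakpoints_copies_single_panel_haplotype(self, small_panel):
        s = simulate_sample(small_panel, expected_breakpoints=0.0, seed=1)
        assert s.breakpoints == []
        H = small_panel.haplotypes
        assert any(np.array_equal(s.hap1, H[h]) for h in range(small_panel.n_hap))
        assert any(np.array_equal(s.hap2, H[h]) for h in range(small_panel.n_hap))

    def test_genotype_is_allele_sum(self, small_sample):
        assert np.array_equal(
            small_sample.genotypes, small_sample.hap1 + small_sample.hap2
        )

    def test_breakpoint_count_matches_poisson_rate(self, small_panel):
        """Empirical mean breakpoints over 1000 draws within 3 s.e. of 5."""
        counts = [
            len(simulate_sample(small_panel, expected_breakpoints=5.0, seed=s).breakpoints)
            for s in range(1000)
        ]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 5.0) <= 3 * se

    def test_same_seed_bit_identical(self, small_panel):
        a = simulate_sample(small_panel, 2.0, seed=3)
        b = simulate_sample(small_panel, 2.0, seed=3)
        assert np.array_equal(a.hap1, b.hap1) and np.array_equal(a.hap2, b.hap2)


class TestClones:
    def test_fractions_exact_and_carriers_follow_tree(self):
        pop = clone_population([0.5, 0.3, 0.2], 100, parents=[-1, 0, 1], seed=0)
        counts = np.bincount(pop.cell_labels, minlength=3)
        assert list(counts) == [50, 30, 20]
        # clone 1's mutation is carried by clones 1 and 2 (descendant)
        carriers = pop.carrier_cells(1)
        assert carriers.sum() == 50
        assert set(pop.cell_labels[carriers]) == {1, 2}

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            clone_population([0.5, 0.4], 10)


class TestCells:
    def test_same_seed_bit_identical(self, small_sample):
        clones = clone_population([1.0], 30, seed=0)
        kw = dict(mean_depth=1.0, dropout=0.1, error_rate=1e-3, seed=7)
        a = simulate_cells(small_sample, clones, [], **kw)
        b = simulate_cells(small_sample, clones, [], **kw)
        assert np.array_equal(a.ref_counts, b.ref_counts)
        assert np.array_equal(a.alt_counts, b.alt_counts)

    def test_noise_free_homref_sites_have_only_ref_counts(self, small_sample):
        clones = clone_population([1.0], 40, seed=1)
        ds = simulate_cells(
            small_sample, clones, [], mean_depth=50.0, dropout=0.0,
            error_rate=0.0, zero_inflation=0.0, seed=8,
        )
        hom_ref = np.nonzero(ds.truth["germline_genotypes"] == 0)[0]
        assert len(hom_ref) > 0
        assert ds.alt_counts[hom_ref].sum() == 0

    def test_truth_carrier_flags_equal_clone_membership(self, small_sample):
        clones = clone_population([0.6, 0.4], 50, seed=2)
        gap = int(np.argmax(np.diff(small_sample.panel.positions)))
        pos = int(small_sample.panel.positions[gap]) + 1
        ds = simulate_cells(
            small_sample, clones, [SomaticSite(pos=pos, carrier_hap=1, clone=1)],
            mean_depth=2.0, seed=9,
        )
        np.testing.assert_array_equal(
            ds.truth["somatic_carrier_flags"][0], clones.cell_labels == 1
        )

    def test_mean_depth_calibrated(self, small_sample):
        """1000 cells at mean depth 2: empirical mean within 5%."""
        clones = clone_population([1.0], 1000, seed=3)
        ds = simulate_cells(
            small_sample, clones, [], mean_depth=2.0, dropout=0.0,
            error_rate=0.0, seed=10,
        )
        total = ds.ref_counts + ds.alt_counts
        assert total.mean() == pytest.approx(2.0, rel=0.05)

    def test_pooled_baf_near_half_at_het_sites(self, small_sample):
        # pooled across many cells, each sampling one haplotype locally
        clones = clone_population([1.0], 2500, seed=4)
        ds = simulate_cells(
            small_sample, clones, [], mean_depth=1.5, dropout=0.0,
            error_rate=0.0, zero_inflation=0.0, seed=11,
        )
        het = np.nonzero(ds.truth["germline_genotypes"] == 1)[0]
        depth = (ds.ref_counts + ds.alt_counts)[het].sum(axis=1)
        baf = ds.alt_counts[het].sum(axis=1) / depth
        assert depth.min() >= 2000
        assert np.all(np.abs(baf - 0.5) < 0.05)

    def test_somatic_collision_with_het_site_rejected(self, small_sample):
        het = np.nonzero(small_sample.genotypes == 1)[0][0]
        pos = int(small_sample.panel.positions[het])
        clones = clone_population([0.5, 0.5], 10, seed=5)
        with pytest.raises(ValueError, match="two alleles"):
            simulate_cells(
                small_sample, clones, [SomaticSite(pos=pos, carrier_hap=1, clone=1)],
                mean_depth=1.0, seed=12,
            )

    def test_cosegregation_short_range_tight_long_range_half(self):
        """Fragment sharing below the read length, independence far away."""
        from scsnv.designs import two_locus_decay

        prof = two_locus_decay(seed=31)
        eps = 1e-3
        assert prof.n2[0] > 200 and np.isfinite(prof.score2[0])
        assert prof.score2[0] <= 2 * eps + 0.01
        # beyond the haplotype-field correlation length (10 kb default):
        # discordance approaches one half
        far = [b for b in range(8, 13) if np.isfinite(prof.score2[b]) and prof.n2[b] > 500]
        assert far, "no populated long-range bins"
        assert prof.score2[far[-1]] > 0.4
        # and the decay is monotone from phased to independent
        assert prof.score2[0] < prof.score2[far[-1]]

    def test_truth_consistent_with_counts_when_noise_free(self, small_sample):
        clones = clone_population([1.0], 30, seed=6)
        ds = simulate_cells(
            small_sample, clones, [], mean_depth=5.0, dropout=0.0,
            error_rate=0.0, zero_inflation=0.0, seed=13,
        )
        g = ds.truth["germline_genotypes"]
        # hom-alt sites show only alt reads; hom-ref only ref reads
        assert ds.ref_counts[g == 2].sum() == 0
        assert ds.alt_counts[g == 0].sum() == 0
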