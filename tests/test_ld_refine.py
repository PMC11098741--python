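"""Cosegregation profiles, de novo phasing and somatic classification."""

import numpy as np
import pytest

from oracles import brute_force_ld_profile
from scsnv.ld_refine import (
    DEFAULT_BIN_EDGES,
    CellAlleleMatrix,
    DeNovoCall,
    LDRefinementScorer,
    SomaticClass,
    classify_somatic,
    cluster_genotype,
    distance_bin,
    ld_profile,
    neighborhoods_two,
)


def matrix_from(positions, c1_rows, c2_rows, phased):
    return CellAlleleMatrix(
        positions=np.asarray(positions),
        c1=np.asarray(c1_rows),
        c2=np.asarray(c2_rows),
        phased=np.asarray(phased, dtype=bool),
    )


class TestBins:
    def test_thirteen_default_bins(self):
        assert len(DEFAULT_BIN_EDGES) - 1 == 13

    @pytest.mark.parametrize(
        "d,b",
        [(0, 0), (99, 0), (100, 1), (249, 1), (250, 2), (500_000, 12), (10**7, 12)],
    )
    def test_bin_lookup_lower_edge_inclusive(self, d, b):
        assert distance_bin(d) == b


class TestNeighborhoods:
    def test_gap_skipped_middle_site_uncovered(self):
        # cell covers sites 0 and 2; site 1 uncovered -> (0, 2) adjacent
        m = matrix_from([100, 200, 300], [[1], [0], [2]], [[0], [0], [0]], [1, 1, 1])
        assert list(neighborhoods_two(m)) == [(0, 2, 0)]

    def test_fully_covered_cell_gives_adjacent_pairs_only(self):
        m = matrix_from([100, 200, 300], [[1], [1], [1]], [[0], [0], [0]], [1, 1, 1])
        assert list(neighborhoods_two(m)) == [(0, 1, 0), (1, 2, 0)]

    def test_single_covered_site_gives_none(self):
        m = matrix_from([100, 200], [[1], [0]], [[0], [0]], [1, 1])
        assert list(neighborhoods_two(m)) == []


class TestProfile:
    def test_single_haplotype_observations_give_zero_score(self):
        rng = np.random.default_rng(0)
        c1 = rng.integers(1, 3, size=(6, 8))
        c2 = np.zeros_like(c1)
        m = matrix_from(np.arange(6) * 50 + 1, c1, c2, np.ones(6))
        prof = ld_profile(m)
        defined = np.isfinite(prof.score2)
        assert defined.any()
        assert np.allclose(prof.score2[defined], 0.0)

    def test_independent_balanced_alleles_approach_half(self):
        rng = np.random.default_rng(1)
        n_cells = 4000
        pick = rng.integers(0, 2, size=(2, n_cells))
        c1 = (pick == 0).astype(int)
        c2 = (pick == 1).astype(int)
        m = matrix_from([1, 600_000], c1, c2, [1, 1])
        prof = ld_profile(m)
        assert prof.score2[12] == pytest.approx(0.5, abs=0.03)

    def test_matches_exhaustive_enumeration_on_random_matrices(self, tiny_random_matrices):
        """Vectorised profile equals direct set enumeration (>=100 matrices)."""
        for m in tiny_random_matrices:
            prof = ld_profile(m)
            s2, n2, s3, n3 = brute_force_ld_profile(
                m.positions, m.c1, m.c2, m.phased, DEFAULT_BIN_EDGES
            )
            np.testing.assert_array_equal(prof.n2, n2)
            np.testing.assert_array_equal(prof.n3, n3)
            np.testing.assert_allclose(prof.score2, s2, equal_nan=True)
            np.testing.assert_allclose(prof.score3, s3, equal_nan=True)

    def test_empty_bins_flagged_not_zero(self):
        m = matrix_from([100, 150], [[1], [1]], [[0], [0]], [1, 1])
        prof = ld_profile(m)
        assert np.isfinite(prof.score2[0])
        assert np.isnan(prof.score2[5])
        assert prof.n2[5] == 0


def _toy_phasing_matrix(
    n_cells=200, f=0.0, carrier_hap=1, seed=0, germline_het=False
):
    """Germline hets at 500 bp spacing around a middle de novo site.

    Every cell observes one haplotype at all loci (one tight fragment).
    With ``germline_het`` the middle site is a true heterozygote (allele
    follows the cell's haplotype); otherwise it is a gain-of-het somatic
    site: reference on both haplotypes except for carrier cells, which
    show the new allele on ``carrier_hap``.
    """
    rng = np.random.default_rng(seed)
    positions = np.array([1000, 1500, 2000, 2500, 3000])
    s = 2  # middle row is the de novo site
    c1 = np.zeros((5, n_cells), dtype=int)
    c2 = np.zeros_like(c1)
    carriers = rng.random(n_cells) < f
    for j in range(n_cells):
        hap = rng.integers(0, 2)  # 0 -> haplotype 1
        for row in range(5):
            if row == s:
                if germline_het:
                    (c1 if hap == 0 else c2)[row, j] = 1
                elif carriers[j] and hap == carrier_hap - 1:
                    c2[row, j] = 1  # somatic allele A2
                else:
                    c1[row, j] = 1  # reference allele A1
            else:
                (c1 if hap == 0 else c2)[row, j] = 1
    phased = np.array([1, 1, 0, 1, 1], dtype=bool)
    return CellAlleleMatrix(positions=positions, c1=c1, c2=c2, phased=phased), s


class TestPhaseDeNovo:
    def test_germline_like_site_scores_near_zero(self):
        m, s = _toy_phasing_matrix(germline_het=True)
        scorer = LDRefinementScorer(cap2=600, cap3=2000).fit(m)
        call = scorer.predict(m, site_indices=[s])[0]
        assert call.ps <= 0.02
        assert call.classification is SomaticClass.GERMLINE_LIKE

    def test_allele_label_swap_flips_orientation_not_ps(self):
        m, s = _toy_phasing_matrix(f=0.3, seed=3)
        swapped = CellAlleleMatrix(
            positions=m.positions, c1=m.c1.copy(), c2=m.c2.copy(), phased=m.phased
        )
        swapped.c1[s], swapped.c2[s] = m.c2[s].copy(), m.c1[s].copy()
        scorer = LDRefinementScorer(cap2=600, cap3=2000)
        call = scorer.fit(m).predict(m, site_indices=[s])[0]
        call_sw = scorer.fit(swapped).predict(swapped, site_indices=[s])[0]
        assert call.ps == pytest.approx(call_sw.ps, abs=1e-12)
        assert call.orientation != call_sw.orientation
        assert call.p_orient == pytest.approx(call_sw.p_flip)

    @pytest.mark.parametrize("carrier_hap", [1, 2])
    def test_ideal_somatic_fraction_recovered(self, carrier_hap):
        """f = 0.3 of cells carry the allele: p_s lands within 0.05 of 0.3."""
        m, s = _toy_phasing_matrix(
            n_cells=2000, f=0.3, carrier_hap=carrier_hap, seed=7
        )
        # germline spacing 500 bp: two-locus (cap 100 bp) never fires and
        # the three-locus channel on the carrier haplotype carries the call
        scorer = LDRefinementScorer(cap2=100, cap3=2000).fit(m)
        call = scorer.predict(m, site_indices=[s])[0]
        assert call.ps == pytest.approx(0.3, abs=0.05)
        assert call.classification is SomaticClass.PUTATIVE_SOMATIC

    def test_zero_informative_cells_unknown(self):
        m, s = _toy_phasing_matrix(n_cells=5, seed=2)
        empty = CellAlleleMatrix(
            positions=m.positions,
            c1=np.where(np.arange(5)[:, None] == s, 0, m.c1),
            c2=np.where(np.arange(5)[:, None] == s, 0, m.c2),
            phased=m.phased,
        )
        scorer = LDRefinementScorer(cap2=600, cap3=2000).fit(empty)
        call = scorer.predict(empty, site_indices=[s])[0]
        assert call.n_informative_cells == 0
        assert call.classification is SomaticClass.UNKNOWN
        assert call.ps == 0.5

    def test_branch_exchange_leaves_ps_bitwise_unchanged(self):
        m, s = _toy_phasing_matrix(n_cells=400, f=0.25, seed=11)
        printed = LDRefinementScorer(cap2=600, cap3=2000, printed_branches=True).fit(m)
        corrected = LDRefinementScorer(cap2=600, cap3=2000).fit(m)
        a = printed.predict(m, site_indices=[s])[0]
        b = corrected.predict(m, site_indices=[s])[0]
        assert a.ps == b.ps  # bitwise


class TestClassify:
    @pytest.mark.parametrize(
        "ps,expected",
        [
            (0.30, SomaticClass.PUTATIVE_SOMATIC),
            (0.10, SomaticClass.GERMLINE_LIKE),
            (0.25, SomaticClass.GERMLINE_LIKE),  # strictly-greater rule
        ],
    )
    def test_threshold_rule(self, ps, expected):
        call = DeNovoCall(
            site_index=0, position=1, p_orient=1 - ps, p_flip=ps,
            orientation="A1|A2", ps=ps, n_informative_cells=10,
        )
        assert classify_somatic(call) is expected


class TestCallInvariants:
    def test_probabilities_complementary_and_ps_bounded(self, somatic_recovery):
        for calls in somatic_recovery["calls_by_f"].values():
            for c in calls:
                assert c.p_orient + c.p_flip == pytest.approx(1.0, abs=1e-9)
                assert 0.0 <= c.ps <= 0.5 + 1e-12

    def test_randomized_suite_invariants(self, tiny_random_matrices):
        for m in tiny_random_matrices:
            if m.n_sites < 3:
                continue
            phased = m.phased.copy()
            phased[m.n_sites // 2] = False
            m2 = CellAlleleMatrix(
                positions=m.positions, c1=m.c1, c2=m.c2, phased=phased
            )
            scorer = LDRefinementScorer(cap2=10**7, cap3=10**7).fit(m2)
            (call,) = scorer.predict(m2)
            assert call.p_orient + call.p_flip == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= call.ps <= 0.5 + 1e-12


class TestClusterGenotype:
    def test_pooled_cluster_calls(self):
        m = matrix_from(
            [100, 200],
            [[0, 0, 10, 10], [0, 0, 0, 5]],
            [[4, 4, 10, 10], [0, 0, 0, 5]],
            [0, 0],
        )
        labels = ["a", "a", "b", "b"]
        out = cluster_genotype(m, [0, 1], labels)
        assert out["a"][0][0] == 2  # only allele-2 reads -> hom alt
        assert out["a"][1] == (None, 0, 0)  # no reads -> missing
        assert out["b"][0][0] == 1  # balanced 20/20 -> het
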