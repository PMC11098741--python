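"""Site features, training-set labelling and the SVM artifact filter."""

import numpy as np
import pytest

from scsnv.genolike import PileupSite, ReadObservation
from scsnv.svm_filter import (
    DeNovoSVMFilter,
    build_training_sets,
    classify_denovo,
    rank_sum,
    site_features,
)


def obs(allele, bq=30.0, mq=60.0, rp=50, strand="+", cell="c0"):
    return ReadObservation(
        allele=allele, base_quality=bq, mapping_quality=mq,
        read_position=rp, strand=strand, cell_id=cell,
    )


class TestSiteFeatures:
    def test_balanced_site_has_baf_half(self):
        site = PileupSite("1", 10, "A", "T", [obs("A")] * 50 + [obs("T")] * 50)
        feats = site_features(site)
        assert feats[6] == pytest.approx(0.5)

    def test_identical_read_position_multisets_give_zero_rpb(self):
        reads = [obs("A", rp=p) for p in (10, 20, 30)] + [obs("T", rp=p) for p in (10, 20, 30)]
        feats = site_features(PileupSite("1", 10, "A", "T", reads))
        assert feats[2] == pytest.approx(0.0)

    def test_rank_sum_u_zero_for_fully_separated_groups(self):
        # pairs with alt position < ref position: none
        u, z = rank_sum([70, 80, 90], [10, 20, 30])
        assert u == 0.0
        assert z < 0

    def test_rank_sum_neutral_imputation_when_one_side_empty(self):
        _, z = rank_sum([], [1.0, 2.0])
        assert z == 0.0

    def test_features_permutation_invariant(self):
        rng = np.random.default_rng(0)
        reads = [
            obs("A", bq=float(b), rp=int(p), strand=s, cell=f"c{c}")
            for b, p, s, c in zip(
                rng.integers(20, 40, 30), rng.integers(0, 100, 30),
                rng.choice(["+", "-"], 30), rng.integers(0, 10, 30),
            )
        ] + [
            obs("T", bq=float(b), rp=int(p), strand=s, cell=f"c{c}")
            for b, p, s, c in zip(
                rng.integers(20, 40, 10), rng.integers(0, 100, 10),
                rng.choice(["+", "-"], 10), rng.integers(0, 10, 10),
            )
        ]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        f1 = site_features(PileupSite("1", 10, "A", "T", reads))
        f2 = site_features(PileupSite("1", 10, "A", "T", shuffled))
        assert np.allclose(f1, f2)


class TestBuildTrainingSets:
    def test_run_of_three_in_germline_free_chunk_is_negative(self):
        tset = build_training_sets([10_000], [120_000, 121_000, 122_000])
        assert tset.negatives == [0, 1, 2] and tset.test == []

    def test_short_run_is_test_when_negatives_exist_elsewhere(self):
        # a run of two fails the >2 rule and stays in the test set
        tset = build_training_sets(
            [10_000], [120_000, 121_000, 200_000, 201_000, 202_000]
        )
        assert tset.test == [0, 1]
        assert tset.negatives == [2, 3, 4]

    def test_chunk_with_germline_is_test_even_for_long_runs(self):
        tset = build_training_sets(
            [120_500], [120_000, 121_000, 122_000, 123_000,
                        200_000, 201_000, 202_000]
        )
        assert tset.test == [0, 1, 2, 3]
        assert tset.negatives == [4, 5, 6]

    def test_no_negatives_raises_actionable_error(self):
        with pytest.raises(ValueError, match="negative"):
            build_training_sets([10_000], [12_000, 13_000])

    def test_relaxing_run_length_never_shrinks_negatives(self):
        germ = [10_000]
        deno = [120_000, 121_000, 200_000, 201_000, 202_000]
        strict = build_training_sets(germ, deno, min_run=2)
        relaxed = build_training_sets(germ, deno, min_run=0)
        assert set(strict.negatives) <= set(relaxed.negatives)


class TestClassifier:
    @staticmethod
    def _clouds(delta, n=150, seed=0, d=7):
        rng = np.random.default_rng(seed)
        pos = rng.normal(delta, 1.0, size=(n, d))
        neg = rng.normal(0.0, 1.0, size=(n, d))
        return pos, neg

    def test_well_separated_clouds_retain_positives(self):
        """Gaussian clouds 5 sigma apart: >=99% of held-out positives kept."""
        pos, neg = self._clouds(5.0)
        test_pos, _ = self._clouds(5.0, seed=1)
        probs, keep = classify_denovo(pos, neg, test_pos)
        assert keep.mean() >= 0.99
        assert np.all((probs >= 0) & (probs <= 1))

    def test_probability_invariant_to_feature_rescaling(self):
        pos, neg = self._clouds(3.0)
        test, _ = self._clouds(3.0, seed=2)
        p1, _ = classify_denovo(pos, neg, test)
        scale = np.ones(pos.shape[1])
        scale[2] = 1000.0
        p2, _ = classify_denovo(pos * scale, neg * scale, test * scale)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_single_class_training_rejected(self):
        clf = DeNovoSVMFilter()
        with pytest.raises(ValueError):
            clf.fit(np.zeros((10, 3)), np.zeros(10))

    def test_threshold_semantics_probability_below_half_dropped(self):
        pos, neg = self._clouds(4.0)
        clf = DeNovoSVMFilter().fit(
            np.vstack([pos, neg]),
            np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]),
        )
        grid, _ = self._clouds(2.0, seed=3, n=60)
        p = clf.predict_proba(grid)[:, 1]
        assert np.array_equal(clf.predict(grid), (p >= 0.5).astype(int))
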