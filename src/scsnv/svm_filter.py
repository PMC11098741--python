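"""SVM-based artifact filter for de novo SNV candidates.

Candidates absent from the reference panel are scored by a support-vector
classifier. Panel-overlapping germline calls serve as positives; runs of
more than two consecutive de novo SNVs inside genomic chunks that contain
no germline SNV serve as negatives (a region accumulating several putative
SNVs but not a single known germline variant is far more likely a mapping
or amplification artifact than a run of somatic mutations). The remaining
de novo SNVs form the test set and are kept iff the predicted probability
of the positive class is at least 0.5.

Feature definitions
-------------------
The variant-quality metrics named after the bcftools annotations (QS, VDB,
RPB, BQB, MQSB, SGB) are computed with this package's own documented
formulas (docs/methods.md):

* ``QS``   phred-scaled confidence that the site is non-reference,
  ``-10 log10 P(g=0)`` from the normalised genotype likelihoods (capped).
* ``RPB`` / ``BQB``  signed rank-sum z statistic comparing alt- versus
  ref-supporting reads on read position / base quality; 0 when either
  side is empty (neutral imputation).
* ``MQSB``  mean of |rank-sum z| on mapping quality and a z-transformed
  Fisher exact statistic of the strand-by-allele 2x2 table.
* ``VDB``  variance of alt read positions over the variance expected
  under a uniform placement (ratio, 1 = unbiased), neutral 1.
* ``SGB``  segregation of alt reads across cells: distinct
  alt-supporting cells divided by alt read count (1 = every alt read in
  a different cell), neutral 0.
* ``BAF``  pooled alternative-allele fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .genolike import PileupSite, genotype_likelihoods

__all__ = [
    "FEATURE_NAMES",
    "rank_sum",
    "site_features",
    "TrainingSet",
    "build_training_sets",
    "DeNovoSVMFilter",
    "classify_denovo",
]

FEATURE_NAMES = ("QS", "VDB", "RPB", "BQB", "MQSB", "SGB", "BAF")

DEFAULT_CHUNK_SIZE = 50_000
DEFAULT_MIN_RUN = 2  # negatives need strictly more than this many SNVs


def rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (pairs with x < y counted, ties as 1/2) and z.

    Returns ``(U, z)`` where ``z`` is the tie-corrected normal
    approximation of the two-sample rank-sum statistic; ``(nan, 0.0)``
    when either sample is empty or the statistic is degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        return float("nan"), 0.0
    u = 0.0
    for xi in x:
        u += np.sum(xi < y) + 0.5 * np.sum(xi == y)
    mu = n1 * n2 / 2.0
    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return float(u), 0.0
    return float(u), float((u - mu) / np.sqrt(sigma2))


def _strand_fisher_z(site: PileupSite) -> float:
    ref_f = sum(1 for o in site.observations if o.allele == site.ref and o.strand == "+")
    ref_r = sum(1 for o in site.observations if o.allele == site.ref and o.strand == "-")
    alt_f = sum(1 for o in site.observations if o.allele == site.alt and o.strand == "+")
    alt_r = sum(1 for o in site.observations if o.allele == site.alt and o.strand == "-")
    if (alt_f + alt_r) == 0 or (ref_f + ref_r) == 0:
        return 0.0
    _, p = stats.fisher_exact([[ref_f, ref_r], [alt_f, alt_r]])
    p = min(max(p, 1e-300), 1.0)
    return float(stats.norm.isf(p / 2.0))


def site_features(site: PileupSite) -> np.ndarray:
    """Feature vector (order :data:`FEATURE_NAMES`) for one candidate."""
    ref_obs = [o for o in site.observations if o.allele == site.ref]
    alt_obs = [o for o in site.observations if o.allele == site.alt]

    gl = genotype_likelihoods(site).normalized()
    qs = min(99.0, -10.0 * np.log10(max(gl[0], 1e-10)))

    _, rpb = rank_sum([o.read_position for o in alt_obs], [o.read_position for o in ref_obs])
    _, bqb = rank_sum([o.base_quality for o in alt_obs], [o.base_quality for o in ref_obs])
    _, z_mq = rank_sum([o.mapping_quality for o in alt_obs], [o.mapping_quality for o in ref_obs])
    mqsb = 0.5 * (abs(z_mq) + _strand_fisher_z(site))

    if len(alt_obs) >= 2:
        positions = np.array([o.read_position for o in alt_obs], dtype=float)
        span = max(positions.max(), 1.0)
        expected = span**2 / 12.0  # uniform placement on [0, span]
        vdb = float(np.var(positions) / expected) if expected > 0 else 1.0
    else:
        vdb = 1.0

    if alt_obs:
        cells = {o.cell_id for o in alt_obs}
        sgb = len(cells) / len(alt_obs)
    else:
        sgb = 0.0

    feats = np.array([qs, vdb, rpb, bqb, mqsb, sgb, site.baf], dtype=float)
    return np.where(np.isfinite(feats), feats, 0.0)


@dataclass
class TrainingSet:
    """Index partition of candidate sites for the SVM."""

    positives: list[int]  # indices into the germline call list
    negatives: list[int]  # indices into the de novo candidate list
    test: list[int]  # remaining de novo candidate indices


def build_training_sets(
    germline_positions: Sequence[int],
    denovo_positions: Sequence[int],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    min_run: int = DEFAULT_MIN_RUN,
) -> TrainingSet:
    """Label candidates by the consecutive-de-novo-chunk rule.

    A de novo SNV is a negative iff its genomic chunk (fixed windows of
    ``chunk_size`` bp) contains no germline SNV and its maximal run of
    consecutive de novo SNVs within the chunk exceeds ``min_run`` sites.
    Positions must be sorted.
    """
    germ = np.asarray(germline_positions, dtype=np.int64)
    deno = np.asarray(denovo_positions, dtype=np.int64)
    if np.any(np.diff(germ) < 0) or np.any(np.diff(deno) < 0):
        raise ValueError("positions must be sorted")
    germ_chunks = set((germ // chunk_size).tolist())
    negatives: list[int] = []
    test: list[int] = []
    chunk_of = deno // chunk_size
    for chunk in np.unique(chunk_of):
        members = np.nonzero(chunk_of == chunk)[0]
        if int(chunk) not in germ_chunks and len(members) > min_run:
            negatives.extend(int(i) for i in members)
        else:
            test.extend(int(i) for i in members)
    if len(germ) == 0:
        raise ValueError(
            "no positive (germline) sites: refine germline calls before SVM training"
        )
    if not negatives:
        raise ValueError(
            "no negative sites: no germline-free chunk holds more than "
            f"{min_run} consecutive de novo SNVs; lower chunk_size or min_run"
        )
    return TrainingSet(
        positives=list(range(len(germ))), negatives=negatives, test=test
    )


class DeNovoSVMFilter(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVC with probability calibration over site features.

    Features are standardised inside the pipeline, so the decision is
    invariant to affine rescaling of any single feature. Candidates with
    positive-class probability below ``prob_threshold`` are dropped.
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma: str | float = "scale",
        prob_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.C = C
        self.gamma = gamma
        self.prob_threshold = prob_threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            SVC(
                C=self.C,
                gamma=self.gamma,
                kernel="rbf",
                probability=True,
                random_state=self.random_state,
            ),
        )
        self.pipeline_.fit(X, y)
        return self

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        """1 = retained (probability of positive class >= threshold)."""
        p = self.predict_proba(X)[:, 1]
        return (p >= self.prob_threshold).astype(int)


def classify_denovo(
    X_pos,
    X_neg,
    X_test,
    prob_threshold: float = 0.5,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Train on positives/negatives, return (probabilities, retained mask)."""
    X_pos = np.asarray(X_pos, dtype=float)
    X_neg = np.asarray(X_neg, dtype=float)
    if len(X_pos) == 0 or len(X_neg) == 0:
        raise ValueError("both positive and negative training sets are required")
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos), dtype=int), np.zeros(len(X_neg), dtype=int)])
    clf = DeNovoSVMFilter(prob_threshold=prob_threshold, random_state=random_state)
    clf.fit(X, y)
    X_test = np.asarray(X_test, dtype=float)
    if len(X_test) == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    p = clf.predict_proba(X_test)[:, 1]
    return p, p >= prob_threshold
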