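"""Sequencing-error model from het-to-hom refinement discordances.

Loci that look heterozygous from the raw genotype likelihoods but are
refined to homozygous-reference by the panel are taken as sequencing
errors. Each such locus falls in one of exactly 12 categories (6 unordered
het base pairs times 2 collapse directions, e.g. AT->AA and AT->TT); the
median pooled B-allele fraction per category becomes the threshold below
which a de novo candidate of that allele pair is indistinguishable from a
sequencing error. De novo candidates additionally need a minimal pooled
sequencing depth (default 100, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "BASES",
    "ALL_CATEGORIES",
    "discordance_category",
    "SequencingErrorModel",
    "fit_error_model",
    "filter_denovo_candidates",
    "FilterResult",
]

BASES = ("A", "C", "G", "T")

#: the 12 valid het-to-hom collapse categories
ALL_CATEGORIES = tuple(
    f"{x}{y}->{h}{h}" for x, y in combinations(BASES, 2) for h in (x, y)
)

DEFAULT_MIN_DEPTH = 100
DEFAULT_FALLBACK_BAF = 0.1


def discordance_category(het_alleles: Iterable[str], hom_allele: str) -> str:
    """Category label for a het pair collapsing to one of its alleles."""
    pair = sorted(set(het_alleles))
    if len(pair) != 2 or any(b not in BASES for b in pair):
        raise ValueError(f"het_alleles must be two distinct bases, got {het_alleles!r}")
    if hom_allele not in pair:
        raise ValueError(f"{hom_allele!r} is not one of the het alleles {pair}")
    return f"{pair[0]}{pair[1]}->{hom_allele}{hom_allele}"


@dataclass
class FilterResult:
    passed: bool
    reason: str | None = None  # "dp_low" | "baf_error_like" | None

    def __bool__(self) -> bool:  # pragma: no cover
        return self.passed


class SequencingErrorModel(BaseEstimator):
    """Per-category BAF thresholds learned from discordant loci.

    Parameters
    ----------
    min_depth : int
        Minimal pooled depth for a de novo candidate (inclusive).
    default_fallback : float
        Threshold used when no discordant loci exist at all.
    """

    def __init__(
        self,
        min_depth: int = DEFAULT_MIN_DEPTH,
        default_fallback: float = DEFAULT_FALLBACK_BAF,
    ):
        self.min_depth = min_depth
        self.default_fallback = default_fallback

    def fit(self, error_loci: Iterable[tuple[str, float]]):
        """Fit thresholds from ``(category, BAF)`` pairs.

        Empty categories fall back to the global median BAF; with no loci
        at all the configured default is used for every category.
        """
        per_cat: dict[str, list[float]] = {c: [] for c in ALL_CATEGORIES}
        all_bafs: list[float] = []
        for category, baf in error_loci:
            if category not in per_cat:
                raise ValueError(f"unknown discordance category {category!r}")
            if not 0.0 <= baf <= 1.0:
                raise ValueError("BAF must lie in [0, 1]")
            per_cat[category].append(float(baf))
            all_bafs.append(float(baf))
        if all_bafs:
            self.global_fallback_ = float(np.median(all_bafs))
        else:
            self.global_fallback_ = float(self.default_fallback)
        self.thresholds_ = {
            c: (float(np.median(v)) if v else self.global_fallback_)
            for c, v in per_cat.items()
        }
        self.counts_ = {c: len(v) for c, v in per_cat.items()}
        self.n_loci_ = len(all_bafs)
        return self

    def threshold_for_pair(self, allele_a: str, allele_b: str) -> float:
        """max of the two collapse-direction thresholds of an allele pair."""
        self._check_fitted()
        t1 = self.thresholds_[discordance_category((allele_a, allele_b), allele_a)]
        t2 = self.thresholds_[discordance_category((allele_a, allele_b), allele_b)]
        return max(t1, t2)

    def predict_site(self, ref: str, alt: str, depth: int, baf: float) -> FilterResult:
        """Depth and BAF filter for one de novo candidate."""
        self._check_fitted()
        if depth < self.min_depth:
            return FilterResult(False, "dp_low")
        if baf < self.threshold_for_pair(ref, alt):
            return FilterResult(False, "baf_error_like")
        return FilterResult(True, None)

    def _check_fitted(self) -> None:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("SequencingErrorModel is not fitted")

    def to_table(self):
        """12-row (category, threshold, n) records for serialisation."""
        self._check_fitted()
        return [
            (c, self.thresholds_[c], self.counts_[c]) for c in ALL_CATEGORIES
        ]


def fit_error_model(
    error_loci: Iterable[tuple[str, float]], **kwargs
) -> SequencingErrorModel:
    return SequencingErrorModel(**kwargs).fit(error_loci)


def filter_denovo_candidates(
    site,
    model: SequencingErrorModel,
    min_depth: int | None = None,
) -> FilterResult:
    """Apply the depth/BAF filters to a :class:`~scsnv.genolike.PileupSite`."""
    depth_cut = model.min_depth if min_depth is None else min_depth
    if site.depth < depth_cut:
        return FilterResult(False, "dp_low")
    if site.baf < model.threshold_for_pair(site.ref, site.alt):
        return FilterResult(False, "baf_error_like")
    return FilterResult(True, None)
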