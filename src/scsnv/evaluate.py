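"""Benchmarking and concordance metrics.

Call sets are keyed by ``(chrom, pos, ref, alt)`` and restricted to
bi-allelic loci with at least one alternative allele (genotype 1 or 2).
Sensitivity (recall) is |N ∩ W| / |W| against a truth set W, precision is
|N ∩ W| / |N|, genotype accuracy is the fraction of identical genotypes on
the intersection, and the overall accuracy is precision times genotype
accuracy. Array concordance counts matching alleles per locus, subtracts
the minimum achievable match (1 when either genotype is heterozygous) and
normalises; clone concordance compares somatic-SNV cell groups against
reference (e.g. mtDNA) clones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BenchmarkReport",
    "benchmark",
    "array_concordance",
    "clone_concordance",
    "match_clones",
    "enrichment_pvalue",
]

SiteKey = tuple[str, int, str, str]


@dataclass
class BenchmarkReport:
    n_calls: int
    n_truth: int
    n_overlap: int
    sensitivity: float  # NaN when undefined
    precision: float
    genotype_accuracy: float
    overall_accuracy: float
    genotype_errors: dict[str, int] = field(default_factory=dict)


def benchmark(
    calls: Mapping[SiteKey, int], truth: Mapping[SiteKey, int]
) -> BenchmarkReport:
    """Compare a call set N against a truth set W (genotypes 1 or 2)."""
    n_set = {k: g for k, g in calls.items() if g in (1, 2)}
    w_set = {k: g for k, g in truth.items() if g in (1, 2)}
    overlap = set(n_set) & set(w_set)
    nN, nW, nI = len(n_set), len(w_set), len(overlap)
    sens = nI / nW if nW else float("nan")
    prec = nI / nN if nN else float("nan")
    errors: dict[str, int] = {}
    same = 0
    for k in overlap:
        if n_set[k] == w_set[k]:
            same += 1
        else:
            label = f"{_gt_str(w_set[k])}->{_gt_str(n_set[k])}"
            errors[label] = errors.get(label, 0) + 1
    gacc = same / nI if nI else float("nan")
    overall = prec * gacc if nI else float("nan")
    return BenchmarkReport(
        n_calls=nN, n_truth=nW, n_overlap=nI,
        sensitivity=sens, precision=prec,
        genotype_accuracy=gacc, overall_accuracy=overall,
        genotype_errors=errors,
    )


def _gt_str(g: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1"}[g]


def array_concordance(
    call_genotypes: Mapping[SiteKey, int],
    array_genotypes: Mapping[SiteKey, int],
    normalization: str = "attainable",
) -> float:
    """Allele-level concordance against array genotypes on shared loci.

    Per locus the number of matching alleles (allele-multiset
    intersection, 0-2) is counted and the minimum achievable match (1 if
    either genotype is heterozygous, else 0) subtracted.

    ``normalization="attainable"`` divides by the attainable excess
    ``sum(2 - min_possible)`` so the score is the achieved fraction of
    possible agreement in [0, 1]; ``"per_locus"`` divides by the raw
    locus count instead.
    """
    shared = set(call_genotypes) & set(array_genotypes)
    if not shared:
        raise ValueError("no shared loci between the call set and the array")
    num = 0.0
    den = 0.0
    for k in shared:
        a = _alleles(call_genotypes[k])
        b = _alleles(array_genotypes[k])
        match = sum(min(a.count(x), b.count(x)) for x in set(a))
        min_possible = 1 if (call_genotypes[k] == 1 or array_genotypes[k] == 1) else 0
        num += match - min_possible
        den += 2 - min_possible
    if normalization == "attainable":
        return num / den
    if normalization == "per_locus":
        return num / len(shared)
    raise ValueError(f"unknown normalization {normalization!r}")


def _alleles(g: int) -> list[int]:
    return {0: [0, 0], 1: [0, 1], 2: [1, 1]}[g]


def enrichment_pvalue(
    clone_cells: set, mutated_cells: set, universe: Sequence
) -> float:
    """Rank-sum p-value for enrichment of mutated cells in a clone.

    Two-sample test on the per-cell binary mutation indicator, clone
    members versus the rest (the FindMarker-style enrichment check).
    """
    indicator = np.array([1.0 if c in mutated_cells else 0.0 for c in universe])
    in_clone = np.array([c in clone_cells for c in universe])
    if in_clone.all() or not in_clone.any():
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            indicator[in_clone], indicator[~in_clone], alternative="greater"
        )
    return float(res.pvalue)


def match_clones(
    snv_groups: Mapping[str, set],
    reference_clones: Mapping[str, set],
    universe: Sequence | None = None,
    p_cutoff: float | None = None,
) -> dict[str, str | None]:
    """Best-overlap (Jaccard) assignment of an SNV group per reference clone.

    With ``p_cutoff`` set, only SNV groups enriched in the clone
    (rank-sum p < cutoff on per-cell indicators) are eligible.
    """
    matching: dict[str, str | None] = {}
    for clone_id, clone_cells in reference_clones.items():
        best, best_j = None, 0.0
        for group_id, group_cells in snv_groups.items():
            if p_cutoff is not None:
                if universe is None:
                    raise ValueError("universe is required for the enrichment pre-filter")
                if enrichment_pvalue(clone_cells, group_cells, universe) >= p_cutoff:
                    continue
            union = clone_cells | group_cells
            j = len(clone_cells & group_cells) / len(union) if union else 0.0
            if j > best_j:
                best, best_j = group_id, j
        matching[clone_id] = best
    return matching


def clone_concordance(
    snv_groups: Mapping[str, set],
    reference_clones: Mapping[str, set],
    matching: Mapping[str, str | None] | None = None,
) -> tuple[dict[str, float], float]:
    """Per-clone cellular concordance and its unweighted mean.

    For each reference clone A with matched SNV group B the concordance
    is |A ∩ B| / |A|; empty reference clones are skipped with a warning.
    """
    if matching is None:
        matching = match_clones(snv_groups, reference_clones)
    per_clone: dict[str, float] = {}
    for clone_id, clone_cells in reference_clones.items():
        if not clone_cells:
            warnings.warn(f"reference clone {clone_id!r} is empty; skipped")
            continue
        group_id = matching.get(clone_id)
        group_cells = snv_groups.get(group_id, set()) if group_id is not None else set()
        per_clone[clone_id] = len(clone_cells & group_cells) / len(clone_cells)
    overall = float(np.mean(list(per_clone.values()))) if per_clone else math.nan
    return per_clone, overall
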