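"""Reference study designs used by the validation suite.

These functions wire the synthetic-data generator to the calling method
under fixed, documented conditions (docs/methods.md):

* somatic parameter recovery: 500 cells, mean per-cell-site depth 5,
  base-error rate 0.1%, allelic dropout 10%, DNA-like fragments
  (read length 100 bp, haplotype-field correlation 10 kb), germline het
  SNVs at ~1/kb density, 30 somatic SNVs alternating carrier haplotype;
* germline p_s distribution under the same sequencing conditions;
* panel-refinement benchmark: 20% of sites covered at pooled depth 1-2
  with 1% base errors, where the haplotype-copying refinement is compared
  against raw genotype-likelihood calls;
* two-locus cosegregation distance decay of the generator.
"""

from __future__ import annotations

import numpy as np

from .genolike import genotype_likelihoods_from_counts
from .ld_refine import CellAlleleMatrix, DeNovoCall, LDRefinementScorer, ld_profile
from .panel_refine import PanelGenotypeRefiner
from .simulate import (
    SomaticSite,
    clone_population,
    simulate_cells,
    simulate_panel,
    simulate_sample,
)

__all__ = [
    "somatic_recovery_calls",
    "germline_ps_scores",
    "refinement_benchmark",
    "two_locus_decay",
]

_PANEL_KW = dict(
    n_hap=40, n_sites=2000, span_bp=2_000_000, recomb_intensity=1e-5, maf_min=0.05
)
_CELL_KW = dict(
    mean_depth=5.0, dropout=0.10, error_rate=1e-3, read_len=100, zero_inflation=0.3
)


def somatic_recovery_calls(
    somatic_fraction: float,
    seed: int,
    n_cells: int = 500,
    n_somatic: int = 30,
) -> list[DeNovoCall]:
    """Score synthetic somatic SNVs carried by a clone of the given fraction.

    Somatic sites are placed in the widest gaps between germline SNVs
    (so the three-locus neighbourhood dominates, as in DNA-like data
    where germline hets are rarely within a read length) and alternate
    between the two carrier haplotypes.
    """
    panel = simulate_panel(seed=seed, **_PANEL_KW)
    sample = simulate_sample(panel, expected_breakpoints=2.0, seed=seed + 1)
    clones = clone_population(
        [1.0 - somatic_fraction, somatic_fraction], n_cells, seed=seed + 2
    )
    gaps = np.argsort(np.diff(panel.positions))[::-1][:n_somatic]
    somatic = [
        SomaticSite(
            pos=int((panel.positions[g] + panel.positions[g + 1]) // 2) + i,
            carrier_hap=1 + (i % 2),
            clone=1,
        )
        for i, g in enumerate(gaps)
    ]
    ds = simulate_cells(sample, clones, somatic, seed=seed + 4, **_CELL_KW)
    scorer = LDRefinementScorer().fit(ds.matrix)
    return scorer.predict(ds.matrix)


def germline_ps_scores(seed: int, n_cells: int = 500, n_probe: int = 40) -> np.ndarray:
    """p_s of true germline het SNVs scored as if they were de novo."""
    panel = simulate_panel(seed=seed, **_PANEL_KW)
    sample = simulate_sample(panel, expected_breakpoints=2.0, seed=seed + 1)
    clones = clone_population([1.0], n_cells, seed=seed + 2)
    ds = simulate_cells(sample, clones, [], seed=seed + 4, **_CELL_KW)
    m = ds.matrix
    probe = np.nonzero(m.phased)[0][::10][:n_probe]
    phased = m.phased.copy()
    phased[probe] = False
    unlabelled = CellAlleleMatrix(
        positions=m.positions, c1=m.c1, c2=m.c2, phased=phased, chrom=m.chrom
    )
    scorer = LDRefinementScorer().fit(unlabelled)
    calls = scorer.predict(unlabelled, site_indices=probe)
    return np.array([c.ps for c in calls if c.n_informative_cells > 0])


def refinement_benchmark(
    seed: int,
    n_sites: int = 800,
    coverage: float = 0.20,
    error_rate: float = 0.01,
) -> tuple[float, float, int]:
    """Genotype accuracy of raw GL calls versus panel-refined calls.

    A mosaic diploid sample is observed at ``coverage`` of the panel
    sites with pooled depth 1-2 and the given base-error rate; returns
    ``(accuracy_raw, accuracy_refined, n_sites)``.
    """
    rng = np.random.default_rng(seed)
    panel = simulate_panel(
        n_hap=60, n_sites=n_sites, span_bp=n_sites * 1000,
        recomb_intensity=1e-5, maf_min=0.05, seed=seed,
    )
    sample = simulate_sample(panel, expected_breakpoints=2.0, seed=seed + 1)
    truth = sample.genotypes
    gl_log = np.empty((n_sites, 3))
    for m in range(n_sites):
        if rng.random() < coverage:
            depth = int(rng.integers(1, 3))
            haps = rng.random(depth) < 0.5
            alleles = np.where(haps, sample.hap1[m], sample.hap2[m])
            flips = rng.random(depth) < error_rate
            alleles = np.where(flips, 1 - alleles, alleles)
            n_alt = int(alleles.sum())
            gl = genotype_likelihoods_from_counts(depth - n_alt, n_alt, error_rate)
        else:
            gl = genotype_likelihoods_from_counts(0, 0, error_rate)
        gl_log[m] = gl.log_likelihoods
    raw = np.argmax(gl_log, axis=1)
    refiner = PanelGenotypeRefiner().fit(panel.haplotypes, panel.positions)
    refined = np.array([g.argmax() for g in refiner.transform(gl_log)])
    return float((raw == truth).mean()), float((refined == truth).mean()), n_sites


def two_locus_decay(seed: int, n_cells: int = 400):
    """Germline two-locus cosegregation profile of the generator."""
    panel = simulate_panel(
        n_hap=40, n_sites=1500, span_bp=3_000_000,
        recomb_intensity=1e-5, maf_min=0.05, seed=seed,
    )
    sample = simulate_sample(panel, expected_breakpoints=2.0, seed=seed + 1)
    clones = clone_population([1.0], n_cells, seed=seed + 2)
    ds = simulate_cells(
        sample, clones, [], mean_depth=3.0, dropout=0.05, error_rate=1e-3,
        read_len=100, zero_inflation=0.3, seed=seed + 3,
    )
    return ld_profile(ds.matrix)
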