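"""Synthetic single-cell sequencing data with known truth.

The generator emulates the statistical structure the calling method
assumes: a phased reference haplotype panel with distance-decaying LD, a
diploid study sample mosaicked from the panel, a clonal cell population in
which somatic alleles sit on one haplotype of a cell subpopulation, and
sparse per-cell allele-support counts.

Per-cell read sampling
----------------------
Reads at a cell-site are drawn from a zero-inflated Poisson depth model
(zero inflation mimics expression/accessibility sparsity). Within a cell,
the haplotype that reads sample is a Markov *haplotype field* along the
genome: loci closer than the read length essentially always share one
haplotype draw (physical phasing within a fragment), and the correlation
decays with distance at scale ``frag_corr_len`` (default 100 x read
length), emulating amplification bias and allelic expression, which is
what carries cosegregation information beyond the read length in real
single-cell data. Far-apart loci sample haplotypes independently, so the
two-locus cosegregation score decays to 0.5 at long range. Whole-allele
dropout is applied per cell-site, and each read's observed allele flips
with the base-error probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genolike import PileupSite, ReadObservation
from .ld_refine import CellAlleleMatrix

__all__ = [
    "ReferencePanel",
    "DiploidSample",
    "ClonePopulation",
    "SomaticSite",
    "SimulatedDataset",
    "simulate_panel",
    "simulate_sample",
    "clone_population",
    "simulate_cells",
]

_BASES = np.array(list("ACGT"))


@dataclass
class ReferencePanel:
    """Phased bi-allelic haplotype panel (0 = ref allele, 1 = alt)."""

    chrom: str
    positions: np.ndarray  # (n_sites,) 1-based, strictly increasing
    ref: list[str]
    alt: list[str]
    haplotypes: np.ndarray  # (n_hap, n_sites) int8

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("panel positions must be strictly increasing")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("haplotype matrix does not match sites")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        f = self.allele_frequencies()
        return np.minimum(f, 1.0 - f)


@dataclass
class DiploidSample:
    """A diploid genome mosaicked from panel haplotypes."""

    panel: ReferencePanel
    hap1: np.ndarray  # (n_sites,) int8 allele on haplotype 1
    hap2: np.ndarray
    breakpoints: list[int] = field(default_factory=list)

    @property
    def genotypes(self) -> np.ndarray:
        return (self.hap1 + self.hap2).astype(np.int8)


@dataclass
class ClonePopulation:
    """Clone tree with per-cell clone assignments."""

    parents: list[int]  # parent index per clone, -1 for the root
    fractions: np.ndarray  # cell fraction per clone, sums to 1
    cell_labels: np.ndarray  # (n_cells,) clone index per cell

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.cell_labels = np.asarray(self.cell_labels, dtype=np.int64)
        if np.any(self.fractions < 0) or abs(self.fractions.sum() - 1.0) > 1e-12:
            raise ValueError("clone fractions must be non-negative and sum to 1")
        if len(self.parents) != len(self.fractions):
            raise ValueError("parents and fractions must align")

    @property
    def n_cells(self) -> int:
        return len(self.cell_labels)

    def descendants(self, clone: int) -> set[int]:
        """The clone itself plus all clones below it in the tree."""
        out = {clone}
        changed = True
        while changed:
            changed = False
            for c, p in enumerate(self.parents):
                if p in out and c not in out:
                    out.add(c)
                    changed = True
        return out

    def carrier_cells(self, clone: int) -> np.ndarray:
        """Boolean mask of cells carrying a mutation that arose in ``clone``."""
        carriers = self.descendants(clone)
        return np.isin(self.cell_labels, sorted(carriers))


@dataclass(frozen=True)
class SomaticSite:
    """A gain-of-heterozygosity somatic SNV specification."""

    pos: int
    carrier_hap: int  # 1 or 2: the haplotype gaining the alternative allele
    clone: int  # originating clone index


@dataclass
class SimulatedDataset:
    """Counts, pooled pileups and truth tables from one simulation."""

    positions: np.ndarray  # all emitted sites, sorted
    ref_alleles: list[str]
    alt_alleles: list[str]
    is_somatic: np.ndarray  # bool per site
    is_artifact: np.ndarray  # bool per site
    ref_counts: np.ndarray  # (n_sites, n_cells)
    alt_counts: np.ndarray
    matrix: CellAlleleMatrix  # het germline (phased) + de novo rows
    matrix_site_index: np.ndarray  # row -> index into ``positions``
    truth: dict
    params: dict
    pileups: list[PileupSite] | None = None


# ---------------------------------------------------------------------------
# panel


def simulate_panel(
    n_hap: int,
    n_sites: int,
    span_bp: int = 1_000_000,
    recomb_intensity: float = 1e-5,
    maf_min: float = 0.05,
    seed: int = 0,
    n_founders: int = 8,
    mutation_rate: float = 0.01,
    chrom: str = "1",
) -> ReferencePanel:
    """Panel haplotypes from a founder copying process with LD decay.

    Each haplotype is a mosaic of ``n_founders`` founder haplotypes; the
    copied founder switches between adjacent sites with probability
    ``1 - exp(-recomb_intensity * distance)``, and copied alleles mutate
    with ``mutation_rate``. Block sharing among haplotypes produces r^2
    that decays with distance. Columns violating ``maf_min`` are repaired
    by flipping randomly chosen majority alleles.
    """
    if n_hap < 4 or n_sites < 2:
        raise ValueError("need n_hap >= 4 and n_sites >= 2")
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    if span_bp < n_sites:
        raise ValueError("span_bp too small for n_sites distinct positions")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(1, span_bp + 1), size=n_sites, replace=False))
    founders = (rng.random((n_founders, n_sites)) < rng.uniform(0.2, 0.8, size=n_sites)).astype(np.int8)

    hap = np.empty((n_hap, n_sites), dtype=np.int8)
    d = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-recomb_intensity * d)
    for h in range(n_hap):
        tmpl = np.empty(n_sites, dtype=np.int64)
        tmpl[0] = rng.integers(n_founders)
        switches = rng.random(n_sites - 1) < p_switch
        for m in range(1, n_sites):
            tmpl[m] = rng.integers(n_founders) if switches[m - 1] else tmpl[m - 1]
        alleles = founders[tmpl, np.arange(n_sites)]
        flips = rng.random(n_sites) < mutation_rate
        hap[h] = np.where(flips, 1 - alleles, alleles)

    # repair columns whose MAF fell below the floor
    if maf_min > 0:
        need = int(np.ceil(maf_min * n_hap))
        counts = hap.sum(axis=0)
        for m in np.nonzero(np.minimum(counts, n_hap - counts) < need)[0]:
            minor = 1 if counts[m] <= n_hap - counts[m] else 0
            deficit = need - int(np.sum(hap[:, m] == minor))
            majors = np.nonzero(hap[:, m] != minor)[0]
            flip_rows = rng.choice(majors, size=deficit, replace=False)
            hap[flip_rows, m] = minor

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    ref = [_BASES[i] for i in ref_idx]
    alt = [_BASES[(i + s) % 4] for i, s in zip(ref_idx, alt_shift)]
    return ReferencePanel(chrom=chrom, positions=positions, ref=ref, alt=alt, haplotypes=hap)


# ---------------------------------------------------------------------------
# diploid sample


def simulate_sample(
    panel: ReferencePanel, expected_breakpoints: float = 2.0, seed: int = 0
) -> DiploidSample:
    """Draw two mosaic haplotypes by Poisson switching among panel rows."""
    if panel.n_sites == 0 or panel.n_hap == 0:
        raise ValueError("panel must be non-empty")
    if expected_breakpoints < 0:
        raise ValueError("expected_breakpoints must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = int(panel.positions[0]), int(panel.positions[-1])
    haps = []
    all_bp: list[int] = []
    for _ in range(2):
        n_bp = rng.poisson(expected_breakpoints / 2.0)
        bps = np.sort(rng.integers(lo, hi + 1, size=n_bp))
        all_bp.extend(int(b) for b in bps)
        seg_start = np.concatenate([[lo - 1], bps])
        tmpl = rng.integers(panel.n_hap, size=len(seg_start))
        seg_of_site = np.searchsorted(bps, panel.positions, side="left")
        haps.append(panel.haplotypes[tmpl[seg_of_site], np.arange(panel.n_sites)])
    return DiploidSample(panel=panel, hap1=haps[0], hap2=haps[1], breakpoints=sorted(all_bp))


# ---------------------------------------------------------------------------
# clones


def clone_population(
    fractions: Sequence[float],
    n_cells: int,
    parents: Sequence[int] | None = None,
    seed: int = 0,
) -> ClonePopulation:
    """Assign cells to clones in exact proportions (largest remainder)."""
    frac = np.asarray(fractions, dtype=float)
    if parents is None:
        parents = [-1] + [0] * (len(frac) - 1)
    counts = np.floor(frac * n_cells).astype(int)
    remainder = frac * n_cells - counts
    short = n_cells - counts.sum()
    for idx in np.argsort(-remainder)[:short]:
        counts[idx] += 1
    labels = np.repeat(np.arange(len(frac)), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return ClonePopulation(parents=list(parents), fractions=frac, cell_labels=labels)


# ---------------------------------------------------------------------------
# cells


def simulate_cells(
    sample: DiploidSample,
    clones: ClonePopulation,
    somatic_spec: Sequence[SomaticSite] = (),
    mean_depth: float = 1.0,
    dropout: float = 0.1,
    error_rate: float = 1e-3,
    read_len: int = 100,
    seed: int = 0,
    zero_inflation: float = 0.3,
    frag_corr_len: float | None = None,
    emit_pileups: bool = False,
    artifact_spec: dict | None = None,
) -> SimulatedDataset:
    """Per-cell allele-support counts with known germline/somatic truth.

    ``artifact_spec`` optionally adds clustered sequencing-artifact sites
    (``{"n_clusters", "sites_per_cluster", "cell_fraction", "offset_bp",
    "spacing_bp"}``) whose alternative reads are scattered across cells
    with no haplotype linkage, low base qualities and read-end positions.
    """
    if not 0.0 <= dropout < 1.0 or not 0.0 <= error_rate < 1.0:
        raise ValueError("dropout and error_rate must lie in [0, 1)")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0.0 <= zero_inflation < 1.0:
        raise ValueError("zero_inflation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    panel = sample.panel
    L_corr = float(frag_corr_len) if frag_corr_len is not None else 100.0 * read_len

    germ_pos = panel.positions
    het_mask = sample.genotypes == 1
    germ_set = set(int(p) for p in germ_pos)
    het_set = set(int(p) for p in germ_pos[het_mask])
    for s in somatic_spec:
        if s.pos in het_set:
            raise ValueError(
                f"somatic site {s.pos} collides with a heterozygous germline site: "
                "only two alleles may be present in the cell population"
            )
        if s.pos in germ_set:
            raise ValueError(f"somatic site {s.pos} collides with a panel site")
        if s.carrier_hap not in (1, 2):
            raise ValueError("carrier_hap must be 1 or 2")

    som_pos = np.array(sorted(s.pos for s in somatic_spec), dtype=np.int64)
    som_by_pos = {s.pos: s for s in somatic_spec}

    # artifact sites (no haplotype linkage; pure noise candidates)
    art_pos_list: list[int] = []
    art_frac = 0.0
    if artifact_spec:
        spacing = artifact_spec.get("spacing_bp", 300)
        offset = artifact_spec.get("offset_bp", 20_000)
        base = int(germ_pos[-1]) + offset
        art_frac = artifact_spec.get("cell_fraction", 0.3)
        for c in range(artifact_spec.get("n_clusters", 0)):
            start = base + c * artifact_spec.get("cluster_gap_bp", 60_000)
            for k in range(artifact_spec.get("sites_per_cluster", 4)):
                art_pos_list.append(start + k * spacing)
    art_pos = np.array(art_pos_list, dtype=np.int64)

    positions = np.concatenate([germ_pos, som_pos, art_pos])
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    n_sites = len(positions)
    n_cells = clones.n_cells

    kind = np.concatenate(
        [np.zeros(len(germ_pos), int), np.ones(len(som_pos), int), 2 * np.ones(len(art_pos), int)]
    )[order]
    src_index = np.concatenate(
        [np.arange(len(germ_pos)), np.arange(len(som_pos)), np.arange(len(art_pos))]
    )[order]

    # per-site allele carried by each haplotype (germline); somatic overlay later
    h1 = np.zeros(n_sites, dtype=np.int8)
    h2 = np.zeros(n_sites, dtype=np.int8)
    germ_rows = kind == 0
    h1[germ_rows] = sample.hap1[src_index[germ_rows]]
    h2[germ_rows] = sample.hap2[src_index[germ_rows]]

    carrier_flags = np.zeros((len(som_pos), n_cells), dtype=bool)
    carrier_hap = np.zeros(len(som_pos), dtype=np.int8)
    for i, p in enumerate(som_pos):
        s = som_by_pos[int(p)]
        carrier_flags[i] = clones.carrier_cells(s.clone)
        carrier_hap[i] = s.carrier_hap
    som_rows = np.array(
        [np.nonzero(positions == p)[0][0] for p in som_pos], dtype=np.int64
    )

    lam = mean_depth / (1.0 - zero_inflation)
    d_adj = np.diff(positions).astype(float)
    p_keep = np.exp(-d_adj / L_corr)  # field persistence between adjacent sites

    ref_counts = np.zeros((n_sites, n_cells), dtype=np.int32)
    alt_counts = np.zeros((n_sites, n_cells), dtype=np.int32)

    for j in range(n_cells):
        # Markov haplotype field: redraw uniformly on 'switch events'
        redraw = np.concatenate([[True], rng.random(n_sites - 1) >= p_keep])
        draws = rng.integers(0, 2, size=n_sites)
        seg = np.cumsum(redraw) - 1
        field_hap = draws[np.nonzero(redraw)[0]][seg] if n_sites else draws

        depth = rng.poisson(lam, size=n_sites)
        depth[rng.random(n_sites) < zero_inflation] = 0
        if dropout > 0:
            drop = rng.random((n_sites, 2)) < dropout
            depth[drop[np.arange(n_sites), field_hap]] = 0

        active_allele = np.where(field_hap == 0, h1, h2)
        # somatic overlay: carrier cells gain the alt allele on carrier_hap
        for i, row in enumerate(som_rows):
            if carrier_flags[i, j] and field_hap[row] == carrier_hap[i] - 1:
                active_allele[row] = 1

        flips = rng.binomial(depth, error_rate)
        n_alt = np.where(active_allele == 1, depth - flips, flips)
        alt_counts[:, j] = n_alt
        ref_counts[:, j] = depth - n_alt

    # artifact sites overwrite: sparse random alt support, no linkage
    for p in art_pos:
        row = np.nonzero(positions == p)[0][0]
        hit = rng.random(n_cells) < art_frac
        alt_counts[row] = np.where(hit, rng.poisson(max(lam * 0.6, 1.0), n_cells) + 1, 0)
        ref_counts[row] = rng.poisson(lam * (1.0 - zero_inflation), n_cells)

    # allele labels
    ref_alleles: list[str] = []
    alt_alleles: list[str] = []
    alt_pool = rng.integers(0, 4, size=n_sites)
    for m in range(n_sites):
        if kind[m] == 0:
            ref_alleles.append(panel.ref[src_index[m]])
            alt_alleles.append(panel.alt[src_index[m]])
        else:
            r = _BASES[alt_pool[m]]
            ref_alleles.append(r)
            alt_alleles.append(_BASES[(alt_pool[m] + 1) % 4])

    # cell-allele matrix: phased germline het rows + unphased de novo rows
    is_som = kind == 1
    is_art = kind == 2
    het_rows = germ_rows & ((h1 + h2) == 1)
    mat_rows = np.nonzero(het_rows | is_som | is_art)[0]
    c1 = np.empty((len(mat_rows), n_cells), dtype=np.int32)
    c2 = np.empty_like(c1)
    phased = np.zeros(len(mat_rows), dtype=bool)
    for r, m in enumerate(mat_rows):
        if het_rows[m]:
            phased[r] = True
            if h1[m] == 1:  # haplotype 1 carries the alternative allele
                c1[r], c2[r] = alt_counts[m], ref_counts[m]
            else:
                c1[r], c2[r] = ref_counts[m], alt_counts[m]
        else:
            c1[r], c2[r] = ref_counts[m], alt_counts[m]
    matrix = CellAlleleMatrix(
        positions=positions[mat_rows],
        c1=c1,
        c2=c2,
        phased=phased,
        chrom=panel.chrom,
        allele1=[ref_alleles[m] if not het_rows[m] or h1[m] == 0 else alt_alleles[m] for m in mat_rows],
        allele2=[alt_alleles[m] if not het_rows[m] or h1[m] == 0 else ref_alleles[m] for m in mat_rows],
        cell_ids=[f"cell{j:05d}" for j in range(n_cells)],
    )

    truth = {
        "germline_genotypes": (h1 + h2).astype(np.int8),
        "hap1_alleles": h1.copy(),
        "hap2_alleles": h2.copy(),
        "germline_site_mask": germ_rows,
        "somatic_positions": som_pos,
        "somatic_carrier_hap": carrier_hap,
        "somatic_carrier_flags": carrier_flags,
        "somatic_fractions": carrier_flags.mean(axis=1) if len(som_pos) else np.empty(0),
        "artifact_positions": art_pos,
        "clone_labels": clones.cell_labels.copy(),
    }
    params = {
        "mean_depth": mean_depth,
        "dropout": dropout,
        "error_rate": error_rate,
        "read_len": read_len,
        "zero_inflation": zero_inflation,
        "frag_corr_len": L_corr,
        "seed": seed,
        "n_cells": n_cells,
    }

    pileups = None
    if emit_pileups:
        pileups = _build_pileups(
            positions, ref_alleles, alt_alleles, ref_counts, alt_counts,
            is_art, read_len, rng,
        )

    return SimulatedDataset(
        positions=positions,
        ref_alleles=ref_alleles,
        alt_alleles=alt_alleles,
        is_somatic=is_som,
        is_artifact=is_art,
        ref_counts=ref_counts,
        alt_counts=alt_counts,
        matrix=matrix,
        matrix_site_index=mat_rows,
        truth=truth,
        params=params,
        pileups=pileups,
    )


def _build_pileups(
    positions, ref_alleles, alt_alleles, ref_counts, alt_counts,
    is_artifact, read_len, rng,
) -> list[PileupSite]:
    """Expand per-cell counts into pooled read observations.

    Artifact sites get the hallmarks of sequencing noise: low base
    qualities and read-end positions for their alternative reads.
    """
    out: list[PileupSite] = []
    n_cells = ref_counts.shape[1]
    for m in range(len(positions)):
        obs: list[ReadObservation] = []
        for j in range(n_cells):
            for allele, n in ((ref_alleles[m], ref_counts[m, j]), (alt_alleles[m], alt_counts[m, j])):
                is_alt = allele == alt_alleles[m]
                for _ in range(int(n)):
                    if is_artifact[m] and is_alt:
                        bq = float(np.clip(rng.normal(18, 3), 5, 35))
                        rp = int(rng.integers(max(read_len - 12, 0), read_len))
                        strand = "+" if rng.random() < 0.9 else "-"
                    else:
                        bq = float(np.clip(rng.normal(32, 3), 13, 41))
                        rp = int(rng.integers(0, read_len))
                        strand = "+" if rng.random() < 0.5 else "-"
                    obs.append(
                        ReadObservation(
                            allele=allele,
                            base_quality=round(bq, 1),
                            mapping_quality=60.0,
                            read_position=rp,
                            strand=strand,
                            mismatch_count=int(rng.poisson(0.4)),
                            cell_id=f"cell{j:05d}",
                        )
                    )
        out.append(
            PileupSite(
                chrom="1", pos=int(positions[m]), ref=ref_alleles[m],
                alt=alt_alleles[m], observations=obs,
            )
        )
    return out
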