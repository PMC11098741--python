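"""Cell-population LD refinement: cosegregation profiles, de novo phasing
and putative somatic classification.

A germline heterozygous SNV has its two alleles split across the sample's
two haplotypes in *every* cell, so alleles observed at nearby het SNVs in
the same cell cosegregate. A recently gained (somatic) allele sits on one
haplotype in only the carrier subpopulation, so its cosegregation with
neighbouring germline alleles is inconsistent across cells. This module

1. estimates distance-binned cosegregation scores from phased germline
   SNVs (two-locus and three-locus models over a sparse cell x locus
   allele-count matrix),
2. statistically phases each de novo SNV against its germline neighbours,
   cell by cell, combining the two models, and
3. aggregates the per-cell phasing evidence into the LD refinement score
   p_s = min{p(A1|A2), p(A2|A1)} in [0, 0.5], thresholded (default 0.25)
   to call putative somatic SNVs.

Neighbourhood definitions
-------------------------
In cell j, two germline loci k < i form a two-locus neighbourhood when
both have reads and every germline locus strictly between them has none.
The pair cosegregates when the same phased allele is seen at both
(c1_k c1_i > 0 or c2_k c2_i > 0). A three-locus neighbourhood chains two
two-locus neighbourhoods k < i < l and conditions on the two flanks
showing the haplotype-1 allele (c1_k c1_l > 0); it cosegregates when the
middle locus also shows haplotype 1 (c1_i > 0). Profile estimation pools
the haplotype-2 mirror image of the three-locus sets (unbiased for
germline SNVs by phase symmetry); de novo *phasing* deliberately keeps
the one-haplotype conditioning, which is what makes p_s estimate the
fraction of cells whose alleles do not cosegregate.

Distances are grouped into 13 bins: <100 bp, 100-250, 250-500, 500-1k,
1-2.5k, 2.5-5k, 5-10k, 10-25k, 25-50k, 50-100k, 100-250k, 250-500k and
>500 kb (lower edge inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .genolike import genotype_likelihoods_from_counts

__all__ = [
    "DEFAULT_BIN_EDGES",
    "distance_bin",
    "CellAlleleMatrix",
    "LDProfile",
    "DeNovoCall",
    "SomaticClass",
    "LDRefinementScorer",
    "neighborhoods_two",
    "ld_profile",
    "phase_denovo_snv",
    "classify_somatic",
    "cluster_genotype",
]

#: default distance-bin edges in bp (13 bins, lower edge inclusive)
DEFAULT_BIN_EDGES = np.array(
    [0, 100, 250, 500, 1_000, 2_500, 5_000, 10_000, 25_000,
     50_000, 100_000, 250_000, 500_000, np.inf]
)

DEFAULT_CAP2_BP = 100  # two-locus model distance cap (DNA-like data)
DEFAULT_CAP3_BP = 10_000  # three-locus model distance cap (DNA-like data)
DEFAULT_PS_THRESHOLD = 0.25


def distance_bin(d: float, edges: np.ndarray = DEFAULT_BIN_EDGES) -> int:
    """Index of the distance bin containing ``d`` (lower edge inclusive)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return int(np.searchsorted(edges, d, side="right")) - 1


class SomaticClass(str, Enum):
    PUTATIVE_SOMATIC = "putative_somatic"
    GERMLINE_LIKE = "germline_like"
    UNKNOWN = "unknown"


@dataclass
class CellAlleleMatrix:
    """Sparse-in-spirit cell x locus allele-support counts.

    ``c1[i, j]`` / ``c2[i, j]`` count the reads in cell j supporting the
    site's first / second allele. For phased germline rows the first
    allele is the one on haplotype 1 (orientation ``A1|A2``); de novo
    rows are unphased (``A1/A2``).
    """

    positions: np.ndarray  # (n_sites,) 1-based bp, sorted
    c1: np.ndarray  # (n_sites, n_cells) int
    c2: np.ndarray
    phased: np.ndarray  # (n_sites,) bool: True = phased germline row
    chrom: str = "1"
    allele1: list[str] | None = None
    allele2: list[str] | None = None
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.c1 = np.asarray(self.c1)
        self.c2 = np.asarray(self.c2)
        self.phased = np.asarray(self.phased, dtype=bool)
        if self.c1.shape != self.c2.shape or self.c1.shape[0] != len(self.positions):
            raise ValueError("count matrices must be (n_sites, n_cells) and aligned")
        if len(self.phased) != len(self.positions):
            raise ValueError("phased flags must align with sites")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("sites must be position-sorted")
        if np.any(self.c1 < 0) or np.any(self.c2 < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_cells(self) -> int:
        return self.c1.shape[1]

    def covered(self) -> np.ndarray:
        """(n_sites, n_cells) boolean coverage mask."""
        return (self.c1 + self.c2) > 0


@dataclass
class LDProfile:
    """Distance-binned two-/three-locus cosegregation scores."""

    bin_edges: np.ndarray
    score2: np.ndarray  # (n_bins,) with NaN where undefined
    n2: np.ndarray  # neighbourhood counts per bin
    score3: np.ndarray
    n3: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def _lookup(self, scores: np.ndarray, d: float) -> float:
        """Score of the bin containing ``d``; undefined bins fall back to
        the nearest defined bin, preferring wider (larger-distance) bins."""
        b = distance_bin(d, self.bin_edges)
        if np.isfinite(scores[b]):
            return float(scores[b])
        for offset in range(1, self.n_bins):
            for cand in (b + offset, b - offset):
                if 0 <= cand < self.n_bins and np.isfinite(scores[cand]):
                    return float(scores[cand])
        return float("nan")

    def score2_at(self, d: float) -> float:
        return self._lookup(self.score2, d)

    def score3_at(self, d: float) -> float:
        return self._lookup(self.score3, d)


@dataclass
class DeNovoCall:
    """Phasing outcome and LD refinement score of one de novo SNV."""

    site_index: int
    position: int
    p_orient: float  # p(A1|A2)
    p_flip: float  # p(A2|A1) = 1 - p_orient
    orientation: str  # "A1|A2" or "A2|A1"
    ps: float  # min of the two, in [0, 0.5]
    n_informative_cells: int
    classification: SomaticClass = SomaticClass.UNKNOWN
    n_two_locus_terms: int = 0
    n_three_locus_terms: int = 0


def neighborhoods_two(matrix: CellAlleleMatrix) -> Iterator[tuple[int, int, int]]:
    """Yield two-locus neighbourhoods ``(k, i, j)`` over phased rows.

    Per cell j, consecutive covered germline loci (k, i): both with reads
    in j and every germline locus between them without reads in j.
    """
    germ = np.nonzero(matrix.phased)[0]
    cov = matrix.covered()[germ]
    for j in range(matrix.n_cells):
        covered = germ[cov[:, j]]
        for k, i in zip(covered[:-1], covered[1:]):
            yield int(k), int(i), j


def _accumulate_profile(
    matrix: CellAlleleMatrix, edges: np.ndarray, symmetrize: bool
) -> LDProfile:
    n_bins = len(edges) - 1
    tot2 = np.zeros(n_bins, dtype=np.int64)
    cos2 = np.zeros(n_bins, dtype=np.int64)
    tot3 = np.zeros(n_bins, dtype=np.int64)
    cos3 = np.zeros(n_bins, dtype=np.int64)

    germ = np.nonzero(matrix.phased)[0]
    pos = matrix.positions[germ]
    c1 = matrix.c1[germ]
    c2 = matrix.c2[germ]
    cov = (c1 + c2) > 0

    for j in range(matrix.n_cells):
        idx = np.nonzero(cov[:, j])[0]
        if len(idx) < 2:
            continue
        a1 = c1[idx, j] > 0
        a2 = c2[idx, j] > 0
        d = pos[idx[1:]] - pos[idx[:-1]]
        bins = np.searchsorted(edges, d, side="right") - 1
        coseg = (a1[:-1] & a1[1:]) | (a2[:-1] & a2[1:])
        np.add.at(tot2, bins, 1)
        np.add.at(cos2, bins[coseg], 1)
        if len(idx) < 3:
            continue
        # triples of consecutive covered loci (k, i, l)
        d3 = pos[idx[1:-1]] - pos[idx[:-2]]  # upstream flank to middle
        bins3 = np.searchsorted(edges, d3, side="right") - 1
        flank1 = a1[:-2] & a1[2:]
        np.add.at(tot3, bins3[flank1], 1)
        np.add.at(cos3, bins3[flank1 & a1[1:-1]], 1)
        if symmetrize:
            flank2 = a2[:-2] & a2[2:]
            np.add.at(tot3, bins3[flank2], 1)
            np.add.at(cos3, bins3[flank2 & a2[1:-1]], 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        score2 = np.where(tot2 > 0, 1.0 - cos2 / np.maximum(tot2, 1), np.nan)
        score3 = np.where(tot3 > 0, 1.0 - cos3 / np.maximum(tot3, 1), np.nan)
    return LDProfile(bin_edges=edges, score2=score2, n2=tot2, score3=score3, n3=tot3)


class LDRefinementScorer(BaseEstimator):
    """Fit germline cosegregation profiles; score and phase de novo SNVs.

    Parameters
    ----------
    bin_edges : array of bin edges in bp (14 values for 13 bins).
    cap2, cap3 : distance caps (bp) for the two- and three-locus models
        (100 bp / 10 kb suit DNA-like data; 1 kb / 50 kb RNA-like data).
    ps_threshold : p_s above which a call is classified putative somatic
        (strictly greater).
    symmetrize_profile : pool the haplotype-2 mirror of three-locus
        neighbourhoods when estimating the germline profile.
    printed_branches : exchange the two branch values of the per-cell
        phasing terms (orientation labels flip; p_s is invariant).
    """

    def __init__(
        self,
        bin_edges=None,
        cap2: float = DEFAULT_CAP2_BP,
        cap3: float = DEFAULT_CAP3_BP,
        ps_threshold: float = DEFAULT_PS_THRESHOLD,
        symmetrize_profile: bool = True,
        printed_branches: bool = False,
    ):
        self.bin_edges = bin_edges
        self.cap2 = cap2
        self.cap3 = cap3
        self.ps_threshold = ps_threshold
        self.symmetrize_profile = symmetrize_profile
        self.printed_branches = printed_branches

    def _edges(self) -> np.ndarray:
        return DEFAULT_BIN_EDGES if self.bin_edges is None else np.asarray(self.bin_edges, float)

    def fit(self, matrix: CellAlleleMatrix):
        """Estimate the LD profile from the phased germline rows."""
        if not np.any(matrix.phased):
            raise ValueError("matrix has no phased germline rows")
        self.profile_ = _accumulate_profile(matrix, self._edges(), self.symmetrize_profile)
        return self

    def predict(self, matrix: CellAlleleMatrix, site_indices=None) -> list[DeNovoCall]:
        """Phase and score the (unphased) de novo rows of ``matrix``."""
        if not hasattr(self, "profile_"):
            raise RuntimeError("LDRefinementScorer is not fitted")
        if site_indices is None:
            site_indices = np.nonzero(~matrix.phased)[0]
        calls = [self._phase_one(int(s), matrix) for s in site_indices]
        return calls

    # -- per-site phasing --------------------------------------------------
    def _phase_one(self, s: int, matrix: CellAlleleMatrix) -> DeNovoCall:
        profile = self.profile_
        pos_s = int(matrix.positions[s])
        germ = np.nonzero(matrix.phased)[0]
        gpos = matrix.positions[germ]
        gc1 = matrix.c1[germ]
        gc2 = matrix.c2[germ]
        gcov = (gc1 + gc2) > 0
        c1s = matrix.c1[s]
        c2s = matrix.c2[s]
        cells = np.nonzero((c1s + c2s) > 0)[0]

        below_sel = gpos < pos_s
        above_sel = gpos > pos_s

        # A somatic allele may sit on either sample haplotype; the
        # three-locus conditioning is haplotype-selective, so it is run as
        # two channels (flanks agreeing on haplotype 1 and, mirrored, on
        # haplotype 2). A germline het cosegregates in both channels; a
        # subpopulation-restricted allele breaks cosegregation in the
        # channel of its carrier haplotype, which then reports p_s ~
        # carrier fraction. The channel with the larger p_s is reported.
        # per channel: separate sums of the per-cell term under the two
        # orientation hypotheses, so that exchanging the branch values
        # swaps the sums exactly and p_s stays bitwise identical
        sums: dict[int, list] = {1: [0.0, 0.0, 0], 2: [0.0, 0.0, 0]}
        n_two = 0
        n_three = 0
        for j in cells:
            covj = gcov[:, j]
            below = np.nonzero(below_sel & covj)[0]
            above = np.nonzero(above_sel & covj)[0]
            k = below[-1] if len(below) else None
            l = above[0] if len(above) else None

            P = self._two_locus_term(
                pos_s, c1s[j], c2s[j], k, l, gpos, gc1[:, j], gc2[:, j], profile
            )
            if P is not None:
                n_two += 1
            for channel in (1, 2):
                Q = self._three_locus_term(
                    pos_s, c1s[j], c2s[j], k, l, gpos, gc1[:, j], gc2[:, j],
                    profile, channel,
                )
                if Q is not None and channel == 1:
                    n_three += 1
                if P is not None and Q is not None:
                    cell = (0.5 * (P[0] + Q[0]), 0.5 * (P[1] + Q[1]))
                elif P is not None:
                    cell = P
                elif Q is not None:
                    cell = Q
                else:
                    continue
                sums[channel][0] += cell[0]
                sums[channel][1] += cell[1]
                sums[channel][2] += 1

        candidates = []
        for channel in (1, 2):
            s_o, s_f, n = sums[channel]
            if n:
                total = s_o + s_f
                candidates.append(
                    (min(s_o, s_f) / total, -channel, s_o / total, n)
                )
        if not candidates:
            return DeNovoCall(
                site_index=s, position=pos_s, p_orient=0.5, p_flip=0.5,
                orientation="A1|A2", ps=0.5, n_informative_cells=0,
                classification=SomaticClass.UNKNOWN,
            )
        ps, _, p_orient, n_inf = max(candidates)
        p_flip = 1.0 - p_orient
        orientation = "A1|A2" if p_orient > p_flip else "A2|A1"
        call = DeNovoCall(
            site_index=s, position=pos_s, p_orient=p_orient, p_flip=p_flip,
            orientation=orientation, ps=ps, n_informative_cells=n_inf,
            n_two_locus_terms=n_two, n_three_locus_terms=n_three,
        )
        call.classification = classify_somatic(call, self.ps_threshold)
        return call

    def _branch(self, p: float, consistent: bool) -> tuple[float, float]:
        """Per-cell term pair (orientation A1|A2, orientation A2|A1).

        With the corrected branch assignment a cosegregation-consistent
        observation gets 1 - p (profile score p is near 0 under tight
        LD); ``printed_branches`` exchanges the two values, which flips
        the orientation labels and leaves p_s unchanged.
        """
        if self.printed_branches:
            consistent = not consistent
        pair = (1.0 - p, p)
        return pair if consistent else (pair[1], pair[0])

    def _two_locus_term(self, pos_s, c1sj, c2sj, k, l, gpos, gc1j, gc2j, profile):
        # nearer covered germline neighbour (WLOG |d_k - d_s| < |d_s - d_l|)
        cand = []
        if k is not None:
            cand.append((pos_s - int(gpos[k]), k))
        if l is not None:
            cand.append((int(gpos[l]) - pos_s, l))
        if not cand:
            return None
        d, n = min(cand)
        if d > self.cap2:
            return None
        p = profile.score2_at(d)
        if not np.isfinite(p):
            return None
        cons_orient = (c1sj > 0 and gc1j[n] > 0) or (c2sj > 0 and gc2j[n] > 0)
        cons_flip = (c1sj > 0 and gc2j[n] > 0) or (c2sj > 0 and gc1j[n] > 0)
        if cons_orient == cons_flip:
            return None  # ambiguous (both alleles seen) or uninformative
        return self._branch(p, cons_orient)

    def _three_locus_term(
        self, pos_s, c1sj, c2sj, k, l, gpos, gc1j, gc2j, profile, channel: int = 1
    ):
        # flanking germline loci agreeing on one haplotype (Neighb3);
        # channel 2 is the haplotype-2 mirror image
        if k is None or l is None:
            return None
        flank = gc1j if channel == 1 else gc2j
        if not (flank[k] > 0 and flank[l] > 0):
            return None
        d_up = pos_s - int(gpos[k])
        d_down = int(gpos[l]) - pos_s
        if d_up > self.cap3 or d_down > self.cap3:
            return None
        p = profile.score3_at(d_up)
        if not np.isfinite(p):
            return None
        v1 = c1sj > 0
        v2 = c2sj > 0
        if v1 == v2:
            return None  # both alleles seen: ambiguous fragment
        # consistency with orientation A1|A2: allele 1 on the hap-1
        # fragment (channel 1) / allele 2 on the hap-2 fragment (channel 2)
        consistent = v1 if channel == 1 else v2
        return self._branch(p, consistent)


# -- functional wrappers ---------------------------------------------------

def ld_profile(
    matrix: CellAlleleMatrix,
    bin_edges=None,
    symmetrize: bool = True,
) -> LDProfile:
    """Distance-binned cosegregation profile over phased germline rows."""
    if not np.any(matrix.phased):
        raise ValueError("matrix has no phased germline rows")
    edges = DEFAULT_BIN_EDGES if bin_edges is None else np.asarray(bin_edges, float)
    return _accumulate_profile(matrix, edges, symmetrize)


def phase_denovo_snv(
    s: int,
    matrix: CellAlleleMatrix,
    profile: LDProfile,
    cap2: float = DEFAULT_CAP2_BP,
    cap3: float = DEFAULT_CAP3_BP,
    ps_threshold: float = DEFAULT_PS_THRESHOLD,
    printed_branches: bool = False,
) -> DeNovoCall:
    """Phase one de novo SNV against a pre-computed germline profile."""
    scorer = LDRefinementScorer(
        cap2=cap2, cap3=cap3, ps_threshold=ps_threshold,
        printed_branches=printed_branches,
    )
    scorer.profile_ = profile
    return scorer._phase_one(s, matrix)


def classify_somatic(call: DeNovoCall, threshold: float = DEFAULT_PS_THRESHOLD) -> SomaticClass:
    """Putative somatic iff p_s strictly exceeds the threshold."""
    if call.n_informative_cells == 0:
        return SomaticClass.UNKNOWN
    return (
        SomaticClass.PUTATIVE_SOMATIC
        if call.ps > threshold
        else SomaticClass.GERMLINE_LIKE
    )


def cluster_genotype(
    matrix: CellAlleleMatrix,
    site_indices: Sequence[int],
    cell_cluster_labels: Sequence[str],
    error_rate: float = 1e-3,
) -> dict[str, dict[int, tuple[int | None, int, int]]]:
    """Per-cluster genotypes at the given sites from pooled cluster counts.

    Returns ``{cluster: {site_index: (genotype | None, n_allele1, n_allele2)}}``
    where the genotype is argmax of the pooled genotype likelihood (counting
    allele 2 as the alternative) and None when the cluster has no reads.
    """
    labels = np.asarray(cell_cluster_labels)
    if len(labels) != matrix.n_cells:
        raise ValueError("cluster labels must cover all cells")
    out: dict[str, dict[int, tuple[int | None, int, int]]] = {}
    for cluster in np.unique(labels):
        members = labels == cluster
        per_site: dict[int, tuple[int | None, int, int]] = {}
        for s in site_indices:
            n1 = int(matrix.c1[s, members].sum())
            n2 = int(matrix.c2[s, members].sum())
            if n1 + n2 == 0:
                per_site[int(s)] = (None, 0, 0)
            else:
                gl = genotype_likelihoods_from_counts(n1, n2, error_rate)
                per_site[int(s)] = (gl.argmax(), n1, n2)
        out[str(cluster)] = per_site
    return out
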