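"""Read filtering, candidate-site scanning and genotype likelihoods.

Single-cell SNV calling starts from a pooled (across cells) pileup. Reads
with many alignment mismatches or low mapping quality are removed, every
locus with at least one non-reference read becomes a candidate SNV, and each
candidate gets a genotype-likelihood triplet GL(g | d) for g in {0, 1, 2}
copies of the alternative allele, under the classical symmetric per-read
error model: a read drawn from a heterozygous site shows either allele with
probability 1/2, and base-calling/alignment error flips the observed allele
with probability e = 10^(-min(base_quality, mapping_quality)/10).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ReadObservation",
    "PileupSite",
    "GLTriplet",
    "filter_read",
    "scan_candidates",
    "genotype_likelihoods",
    "genotype_likelihoods_from_counts",
]

#: default read-filter settings
DEFAULT_MAX_MISMATCH = 4
DEFAULT_MIN_MAPQ = 20


@dataclass(frozen=True)
class ReadObservation:
    """One read's evidence at one locus.

    ``mismatch_count`` counts substitutions plus indel bases of the
    alignment (the NM-style total); whether indels are included is
    controlled upstream by the pileup producer.
    """

    allele: str
    base_quality: float = 30.0
    mapping_quality: float = 60.0
    read_position: int = 0
    strand: str = "+"
    mismatch_count: int = 0
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.base_quality < 0 or self.mapping_quality < 0:
            raise ValueError("phred qualities must be >= 0")
        if self.read_position < 0:
            raise ValueError("read_position must be >= 0")


@dataclass
class PileupSite:
    """Pooled per-read evidence at one bi-allelic candidate SNV."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    observations: list[ReadObservation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)

    @property
    def alt_count(self) -> int:
        return sum(1 for o in self.observations if o.allele == self.alt)

    @property
    def ref_count(self) -> int:
        return sum(1 for o in self.observations if o.allele == self.ref)

    @property
    def baf(self) -> float:
        """Pooled alternative-allele fraction; 0.0 at zero depth."""
        return self.alt_count / self.depth if self.depth else 0.0


class GLTriplet:
    """Genotype log-likelihoods for g in {0, 1, 2} alternative alleles."""

    __slots__ = ("log_likelihoods",)

    def __init__(self, log_likelihoods: Sequence[float]):
        arr = np.asarray(log_likelihoods, dtype=float)
        if arr.shape != (3,):
            raise ValueError("GLTriplet needs exactly three log-likelihoods")
        if not np.all(np.isfinite(arr)):
            raise ValueError("log-likelihoods must be finite")
        self.log_likelihoods = arr

    def normalized(self) -> np.ndarray:
        """Linear-scale likelihoods normalised to sum to one."""
        shifted = self.log_likelihoods - self.log_likelihoods.max()
        lin = np.exp(shifted)
        return lin / lin.sum()

    def argmax(self) -> int:
        """Most likely genotype; ties broken toward the smaller g."""
        return int(np.argmax(self.log_likelihoods))

    def __repr__(self) -> str:  # pragma: no cover
        return f"GLTriplet({self.log_likelihoods.tolist()})"


def filter_read(
    obs: ReadObservation,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_mapq: float = DEFAULT_MIN_MAPQ,
) -> bool:
    """Return True to keep the read.

    A read is dropped when its mismatch count exceeds ``max_mismatch``
    (the default four mismatches are tolerated) or its mapping quality is
    below ``min_mapq``.
    """
    return obs.mismatch_count <= max_mismatch and obs.mapping_quality >= min_mapq


def scan_candidates(
    pileups: Iterable[tuple[str, int, str, Sequence[ReadObservation]]],
) -> list[PileupSite]:
    """Scan pooled pileup columns for candidate SNVs.

    Every locus where at least one read carries a non-reference base is
    emitted. The alternative allele is the most frequent non-reference
    base (ties broken alphabetically); reads carrying any other base are
    discarded so the site stays bi-allelic.
    """
    out: list[PileupSite] = []
    for chrom, pos, ref, observations in pileups:
        non_ref = Counter(o.allele for o in observations if o.allele != ref)
        if not non_ref:
            continue
        top = max(non_ref.values())
        alt = min(b for b, n in non_ref.items() if n == top)
        kept = [o for o in observations if o.allele in (ref, alt)]
        out.append(PileupSite(chrom=chrom, pos=pos, ref=ref, alt=alt, observations=kept))
    return out


def _per_read_error(obs: ReadObservation) -> float:
    q = min(obs.base_quality, obs.mapping_quality)
    return 10.0 ** (-q / 10.0)


def genotype_likelihoods(site: PileupSite) -> GLTriplet:
    """Genotype likelihoods from the pooled reads at one site.

    Per read with error probability e: P(ref | g=0) = 1 - e,
    P(ref | g=1) = 1/2, P(ref | g=2) = e, with complements for the
    alternative allele. Zero observations give a flat triplet.
    """
    ll = np.zeros(3)
    for obs in site.observations:
        e = _per_read_error(obs)
        if obs.allele == site.ref:
            probs = (1.0 - e, 0.5, e)
        elif obs.allele == site.alt:
            probs = (e, 0.5, 1.0 - e)
        else:
            continue  # non-biallelic leftovers carry no information here
        ll += np.log(np.maximum(probs, 1e-300))
    return GLTriplet(ll)


def genotype_likelihoods_from_counts(
    n_ref: int, n_alt: int, error_rate: float = 1e-3
) -> GLTriplet:
    """GL triplet for ``n_ref``/``n_alt`` reads sharing one error rate.

    Convenience path for count matrices where per-read qualities have
    been collapsed; equivalent to :func:`genotype_likelihoods` with all
    reads at phred -10 log10(error_rate).
    """
    if n_ref < 0 or n_alt < 0:
        raise ValueError("counts must be non-negative")
    e = float(error_rate)
    log = np.log
    ll = np.array(
        [
            n_ref * log(max(1.0 - e, 1e-300)) + n_alt * log(max(e, 1e-300)),
            (n_ref + n_alt) * log(0.5) if (n_ref + n_alt) else 0.0,
            n_ref * log(max(e, 1e-300)) + n_alt * log(max(1.0 - e, 1e-300)),
        ]
    )
    return GLTriplet(ll)
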