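"""Reference-panel genotype refinement via a diploid haplotype-copying HMM.

Sparse single-cell data yields noisy genotype likelihoods GL(g | d). For
sites present in a phased reference haplotype panel H, linkage
disequilibrium in the panel can be borrowed to produce genotype posteriors
GP(g | H, d): the sample's two haplotypes are modelled as mosaics of panel
haplotypes (a Li-Stephens copying process per chromosome copy), and the GL
is folded into the emission at every site. The refined posterior both
rescues heterozygotes hidden by allelic dropout and flags persistent
het-to-hom discordances that feed the sequencing-error model.

Model
-----
State space: ordered pairs (h1, h2) of panel haplotype indices, K^2 states
for |H| = K. Transitions factorise over the two chains; each chain switches
template with probability r(d) = 1 - exp(-d / rho_scale) over an inter-site
distance of d bp, landing uniformly on one of the K templates (so staying
put has probability (1 - r) + r/K). Emission at site m for state (h1, h2):

    E_m(h1, h2) = sum_{a1, a2 in {0,1}} P(a1 | h1) P(a2 | h2) GL_m(a1 + a2)

with copying fidelity P(a | h) = 1 - theta if a equals the template allele
and theta otherwise. The per-site genotype posterior is obtained from the
forward-backward state posterior by re-weighting the GL with the state's
allele-pair mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.base import BaseEstimator

from .genolike import GLTriplet

__all__ = [
    "GPTriplet",
    "CallStatus",
    "RefinedCall",
    "PanelGenotypeRefiner",
    "refine_genotype_probs",
    "consensus_calls",
]


class GPTriplet:
    """Normalised genotype posterior for g in {0, 1, 2}."""

    __slots__ = ("probs",)

    def __init__(self, probs):
        arr = np.asarray(probs, dtype=float)
        if arr.shape != (3,) or np.any(arr < -1e-12):
            raise ValueError("GPTriplet needs three non-negative probabilities")
        total = arr.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("degenerate genotype posterior")
        self.probs = np.maximum(arr, 0.0) / total

    def argmax(self) -> int:
        """Most probable genotype; ties broken toward the smaller g."""
        return int(np.argmax(self.probs))

    def __repr__(self) -> str:  # pragma: no cover
        return f"GPTriplet({self.probs.tolist()})"


class CallStatus(str, Enum):
    GERMLINE_KEPT = "germline_kept"
    DISCORDANT_ERROR_CANDIDATE = "discordant_error_candidate"
    DISCORDANT_OTHER = "discordant_other"


@dataclass
class RefinedCall:
    """Per-site outcome of the panel refinement."""

    site_index: int
    gl: GLTriplet
    gp: GPTriplet
    genotype_raw: int  # argmax GL
    genotype_refined: int  # argmax GP
    status: CallStatus
    #: posterior probability that haplotype 1 carries the alternative allele
    #: and haplotype 2 the reference (phase orientation at het sites)
    p_alt_on_hap1: float


class PanelGenotypeRefiner(BaseEstimator):
    """Diploid Li-Stephens refinement of genotype likelihoods.

    Parameters
    ----------
    theta : float
        Copying infidelity (mutation/mismatch) per chain and site.
    rho_scale : float
        Exponential distance scale of template switching, in bp
        (default one expected switch per 100 kb).
    max_panel_haplotypes : int or None
        Optional cap on the number of panel haplotypes used (first rows).
    """

    def __init__(
        self,
        theta: float = 1e-3,
        rho_scale: float = 100_000.0,
        max_panel_haplotypes: int | None = None,
    ):
        self.theta = theta
        self.rho_scale = rho_scale
        self.max_panel_haplotypes = max_panel_haplotypes

    # -- estimator API -----------------------------------------------------
    def fit(self, panel_haplotypes, panel_positions):
        """Store the phased panel.

        Parameters
        ----------
        panel_haplotypes : (n_hap, n_sites) binary array
            0 = reference allele, 1 = alternative allele.
        panel_positions : (n_sites,) int array of 1-based bp positions,
            strictly increasing.
        """
        H = np.asarray(panel_haplotypes, dtype=np.int8)
        pos = np.asarray(panel_positions, dtype=np.int64)
        if H.ndim != 2 or H.shape[0] < 2:
            raise ValueError("panel needs at least two haplotypes")
        if H.shape[1] != pos.shape[0]:
            raise ValueError("haplotype matrix and positions disagree")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("panel positions must be strictly increasing")
        if self.max_panel_haplotypes is not None:
            H = H[: self.max_panel_haplotypes]
            if H.shape[0] < 2:
                raise ValueError("max_panel_haplotypes leaves fewer than 2 haplotypes")
        self.haplotypes_ = H
        self.positions_ = pos
        self.n_haplotypes_ = H.shape[0]
        return self

    def transform(self, gl_by_site, site_indices=None):
        """Refine genotype likelihoods into posteriors.

        Parameters
        ----------
        gl_by_site : sequence of GLTriplet (or (n_sites, 3) array of
            log-likelihoods), one per refined site in panel order.
        site_indices : optional indices into the panel's site list; defaults
            to ``0..n-1``. Must be sorted and within the panel.

        Returns
        -------
        list of GPTriplet, and stores ``phase_posteriors_`` (probability
        that haplotype 1 carries the alt allele, given g = 1).
        """
        self._check_fitted()
        logL = self._as_log_array(gl_by_site)
        idx = (
            np.arange(logL.shape[0])
            if site_indices is None
            else np.asarray(site_indices, dtype=np.int64)
        )
        if np.any(idx < 0) or np.any(idx >= self.positions_.shape[0]):
            raise ValueError("site index outside the panel")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("site indices must be strictly increasing")
        if idx.shape[0] != logL.shape[0]:
            raise ValueError("one GL triplet per site is required")

        post_g, p_alt_hap1 = self._forward_backward(logL, idx)
        self.phase_posteriors_ = p_alt_hap1
        return [GPTriplet(row) for row in post_g]

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _as_log_array(gl_by_site) -> np.ndarray:
        if len(gl_by_site) == 0:
            raise ValueError("no sites to refine")
        if isinstance(gl_by_site[0], GLTriplet):
            return np.vstack([g.log_likelihoods for g in gl_by_site])
        arr = np.asarray(gl_by_site, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("expected (n_sites, 3) log-likelihood array")
        return arr

    def _check_fitted(self) -> None:
        if not hasattr(self, "haplotypes_"):
            raise RuntimeError("PanelGenotypeRefiner is not fitted")

    def _emission_parts(self, logL: np.ndarray, idx: np.ndarray):
        """Per-site linear GL and per-haplotype alt-allele emission weight."""
        lin = np.exp(logL - logL.max(axis=1, keepdims=True))
        lin /= lin.sum(axis=1, keepdims=True)
        H = self.haplotypes_[:, idx].astype(float)  # (K, M)
        w_alt = H * (1.0 - self.theta) + (1.0 - H) * self.theta  # P(a=1 | h)
        return lin, w_alt

    def _site_emission(self, lin_m: np.ndarray, w_m: np.ndarray):
        """Joint emission matrix over (h1, h2) plus per-genotype parts."""
        w = w_m
        comb0 = np.outer(1.0 - w, 1.0 - w)
        comb1 = np.outer(w, 1.0 - w) + np.outer(1.0 - w, w)
        comb2 = np.outer(w, w)
        E = lin_m[0] * comb0 + lin_m[1] * comb1 + lin_m[2] * comb2
        return E, (comb0, comb1, comb2)

    def _forward_backward(self, logL: np.ndarray, idx: np.ndarray):
        K = self.n_haplotypes_
        M = idx.shape[0]
        lin, w_alt = self._emission_parts(logL, idx)
        pos = self.positions_[idx]

        def step(mat: np.ndarray, r: float) -> np.ndarray:
            """Apply the factorised two-chain transition to a (K, K) mass."""
            stay = 1.0 - r
            u = r / K
            row = mat.sum(axis=0)  # over h1
            col = mat.sum(axis=1)  # over h2
            tot = row.sum()
            return (
                stay * stay * mat
                + stay * u * col[:, None]
                + u * stay * row[None, :]
                + u * u * tot
            )

        alphas = np.empty((M, K, K))
        scales = np.empty(M)
        f = np.full((K, K), 1.0 / (K * K))
        for m in range(M):
            if m > 0:
                d = float(pos[m] - pos[m - 1])
                f = step(f, 1.0 - np.exp(-d / self.rho_scale))
            E, _ = self._site_emission(lin[m], w_alt[:, m])
            f = f * E
            scales[m] = f.sum()
            if scales[m] <= 0:
                raise FloatingPointError("forward mass vanished")
            f = f / scales[m]
            alphas[m] = f

        b = np.ones((K, K))
        post_g = np.empty((M, 3))
        p_alt_hap1 = np.empty(M)
        for m in range(M - 1, -1, -1):
            post = alphas[m] * b
            post = post / post.sum()
            E, (c0, c1, c2) = self._site_emission(lin[m], w_alt[:, m])
            # re-weight: within a state, P(g | state, d_m) = lin[g] comb_g / E
            with np.errstate(invalid="ignore", divide="ignore"):
                inv = np.where(E > 0, post / E, 0.0)
            g0 = lin[m, 0] * float((inv * c0).sum())
            g1 = lin[m, 1] * float((inv * c1).sum())
            g2 = lin[m, 2] * float((inv * c2).sum())
            tot = g0 + g1 + g2
            post_g[m] = (g0 / tot, g1 / tot, g2 / tot)
            # phase orientation: P(a1=1, a2=0 | .) vs P(a1=0, a2=1 | .)
            w = w_alt[:, m]
            alt_first = lin[m, 1] * float((inv * np.outer(w, 1.0 - w)).sum())
            ref_first = lin[m, 1] * float((inv * np.outer(1.0 - w, w)).sum())
            denom = alt_first + ref_first
            p_alt_hap1[m] = alt_first / denom if denom > 0 else 0.5
            if m > 0:
                d = float(pos[m] - pos[m - 1])
                b = step(b * E, 1.0 - np.exp(-d / self.rho_scale))
                b = b / b.max()
        return post_g, p_alt_hap1


def refine_genotype_probs(
    gl_by_site,
    panel_haplotypes,
    panel_positions,
    site_indices=None,
    theta: float = 1e-3,
    rho_scale: float = 100_000.0,
) -> list[GPTriplet]:
    """Functional wrapper over :class:`PanelGenotypeRefiner`."""
    refiner = PanelGenotypeRefiner(theta=theta, rho_scale=rho_scale)
    refiner.fit(panel_haplotypes, panel_positions)
    return refiner.transform(gl_by_site, site_indices=site_indices)


def consensus_calls(
    gls: list[GLTriplet],
    gps: list[GPTriplet],
    phase_posteriors=None,
) -> tuple[list[RefinedCall], list[RefinedCall]]:
    """Split refined sites into final germline calls and error-model loci.

    A site is kept as a germline call iff the raw (argmax GL) and refined
    (argmax GP) genotypes agree. Heterozygous-by-GL sites refined to
    homozygous *reference* are routed to the sequencing-error model; every
    other discordance is excluded without feeding the error model.
    """
    if len(gls) != len(gps):
        raise ValueError("GL and GP lists must align")
    if phase_posteriors is None:
        phase_posteriors = [0.5] * len(gls)
    germline: list[RefinedCall] = []
    error_loci: list[RefinedCall] = []
    for i, (gl, gp, ph) in enumerate(zip(gls, gps, phase_posteriors)):
        g_raw = gl.argmax()
        g_ref = gp.argmax()
        if g_raw == g_ref:
            status = CallStatus.GERMLINE_KEPT
        elif g_ref == 0 and g_raw in (1, 2):
            status = CallStatus.DISCORDANT_ERROR_CANDIDATE
        else:
            status = CallStatus.DISCORDANT_OTHER
        call = RefinedCall(
            site_index=i,
            gl=gl,
            gp=gp,
            genotype_raw=g_raw,
            genotype_refined=g_ref,
            status=status,
            p_alt_on_hap1=float(ph),
        )
        if status is CallStatus.GERMLINE_KEPT:
            germline.append(call)
        elif status is CallStatus.DISCORDANT_ERROR_CANDIDATE:
            error_loci.append(call)
    return germline, error_loci
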