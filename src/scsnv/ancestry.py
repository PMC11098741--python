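"""Global ancestry by PCA projection with projection Procrustes.

A study sample genotyped at a sparse set of loci is placed on the
principal-component map of a reference population panel: PCA coordinates
are obtained by eigendecomposition of the genetic relationship matrix
(GRM) R R^T, once for the reference alone (Y, n x K) and once for the
reference plus the study sample (Ỹ, (n+1) x K' with K' >= K). Projection
Procrustes then finds an orthonormal projection A (K' x K) and isotropic
scaling rho minimising ||rho Ỹ A - Y||_F^2 over the shared reference
rows, and the study sample's coordinates are y = rho ỹ A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "grm",
    "pca_coords",
    "AncestryProjection",
    "procrustes_project",
    "AncestryProjector",
]


def grm(
    genotype_matrix, center: bool = True, standardize: bool = False
) -> np.ndarray:
    """Genetic relationship matrix R_c R_c^T from 0/1/2 genotypes.

    Missing entries (NaN) are imputed to the column mean; all-missing
    columns are dropped with a warning. Columns are mean-centered by
    default (without centering, allele-frequency offsets dominate PC1);
    ``standardize`` additionally scales columns to unit variance.
    """
    G = np.array(genotype_matrix, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (samples x loci)")
    col_mean = np.nanmean(G, axis=0)
    all_missing = np.isnan(col_mean)
    if all_missing.any():
        warnings.warn(f"dropping {all_missing.sum()} all-missing genotype columns")
        G = G[:, ~all_missing]
        col_mean = col_mean[~all_missing]
    nan_mask = np.isnan(G)
    if nan_mask.any():
        G[nan_mask] = np.broadcast_to(col_mean, G.shape)[nan_mask]
    if center:
        G = G - col_mean
    if standardize:
        sd = G.std(axis=0)
        keep = sd > 0
        G = G[:, keep] / sd[keep]
    return G @ G.T


def pca_coords(grm_matrix, K: int) -> np.ndarray:
    """Top-K eigenvector coordinates scaled by sqrt(eigenvalue).

    The sign of each component is fixed so its largest-magnitude entry is
    positive. K must not exceed the numerical rank of the GRM.
    """
    R = np.asarray(grm_matrix, dtype=float)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(R.shape) * np.finfo(float).eps * max(vals.max(), 0.0)
    rank = int(np.sum(vals > tol))
    if K > rank:
        raise ValueError(f"K={K} exceeds the GRM rank ({rank})")
    coords = vecs[:, :K] * np.sqrt(vals[:K])
    for k in range(K):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


@dataclass
class AncestryProjection:
    """Solution of the projection Procrustes problem."""

    A: np.ndarray  # (K', K), orthonormal columns
    rho: float
    error: float  # minimised ||rho Ỹ A - Y||_F^2
    projected: np.ndarray  # (n_new, K) coordinates of the new sample(s)
    reference: np.ndarray  # (n, K) reference coordinates Y


def procrustes_project(
    Y_ref: np.ndarray, Y_combined: np.ndarray, n_new: int = 1
) -> AncestryProjection:
    """Fit (A, rho) on the shared rows and project the trailing rows.

    ``Y_combined`` holds the combined-PCA coordinates whose first
    ``n - n_new`` rows correspond 1:1 to ``Y_ref``'s rows and whose last
    ``n_new`` rows are the new sample(s).
    """
    Y = np.asarray(Y_ref, dtype=float)
    Yt = np.asarray(Y_combined, dtype=float)
    if Yt.shape[0] != Y.shape[0] + n_new:
        raise ValueError("Y_combined must be Y_ref's rows plus the new sample rows")
    if Yt.shape[1] < Y.shape[1]:
        raise ValueError("combined coordinates need K' >= K")
    Z = Yt[: Y.shape[0]]  # reference rows in the combined space
    if float(np.sum(Z * Z)) == 0:
        raise ValueError("degenerate combined coordinates")
    A, rho = _solve_projection_procrustes(Z, Y)
    error = float(np.sum((rho * Z @ A - Y) ** 2))
    projected = rho * Yt[Y.shape[0]:] @ A
    return AncestryProjection(A=A, rho=rho, error=error, projected=projected, reference=Y)


def _solve_projection_procrustes(Z, Y, max_iter=2000, tol=1e-14):
    """Minimise ||rho Z A - Y||_F^2 over orthonormal-column A and rho.

    With K' > K the quadratic term tr(A' Z'Z A) depends on A, so unlike
    the rotation case there is no single-SVD solution; a majorisation-
    minimisation iteration is used (the concave quadratic is linearised
    at the current A, each subproblem is an orthogonal Procrustes solved
    by polar decomposition), initialised at the rotation-case optimum.
    """
    M = Z.T @ Y
    N = Z.T @ Z
    lam = float(np.linalg.eigvalsh(N)[-1])
    U, svals, Vt = np.linalg.svd(M, full_matrices=False)
    A = U @ Vt

    def rho_for(A):
        denom = float(np.sum((Z @ A) ** 2))
        return float(np.trace(A.T @ M)) / denom if denom > 0 else 0.0

    def objective(A, rho):
        return float(np.sum((rho * Z @ A - Y) ** 2))

    rho = rho_for(A)
    prev = objective(A, rho)
    for _ in range(max_iter):
        G = rho * M - rho * rho * (N - lam * np.eye(N.shape[0])) @ A
        Ug, _, Vgt = np.linalg.svd(G, full_matrices=False)
        A = Ug @ Vgt
        rho = rho_for(A)
        cur = objective(A, rho)
        if prev - cur < tol * max(prev, 1.0):
            break
        prev = cur
    return A, rho


class AncestryProjector(BaseEstimator):
    """Reference-panel PCA with Procrustes projection of new samples.

    Parameters
    ----------
    K : dimensionality of the reference map.
    K_prime : dimensionality of the combined PCA (>= K).
    center, standardize : GRM column treatment (see :func:`grm`).
    """

    def __init__(self, K: int = 2, K_prime: int = 4, center: bool = True,
                 standardize: bool = False):
        self.K = K
        self.K_prime = K_prime
        self.center = center
        self.standardize = standardize

    def fit(self, reference_genotypes):
        if self.K_prime < self.K:
            raise ValueError("K_prime must be >= K")
        R = np.asarray(reference_genotypes, dtype=float)
        self.reference_genotypes_ = R
        self.reference_coords_ = pca_coords(
            grm(R, center=self.center, standardize=self.standardize), self.K
        )
        return self

    def transform(self, sample_genotypes):
        """Project one or more samples (rows) onto the reference map."""
        if not hasattr(self, "reference_coords_"):
            raise RuntimeError("AncestryProjector is not fitted")
        g = np.atleast_2d(np.asarray(sample_genotypes, dtype=float))
        combined = np.vstack([self.reference_genotypes_, g])
        Yt = pca_coords(
            grm(combined, center=self.center, standardize=self.standardize),
            self.K_prime,
        )
        proj = procrustes_project(self.reference_coords_, Yt, n_new=g.shape[0])
        self.projection_ = proj
        return proj.projected
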