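"""Quantitative-genetics kernel: GRM construction, single-component REML
heritability of CpG methylation, and pairwise LD.

The heritability model is the usual animal model with one genomic random
effect,

    y = 1*mu + u + e,    u ~ N(0, G*sigma_u^2),  e ~ N(0, I*sigma_e^2),

with G the genomic relationship matrix. REML is solved exactly by a
spectral decomposition: project y onto an orthonormal basis of the space
orthogonal to the intercept, rotate by the eigenvectors of the projected
GRM, and profile the restricted likelihood over the heritability ratio
h2 = sigma_u^2 / (sigma_u^2 + sigma_e^2) in one dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .io import GenotypeSet

__all__ = ["GRM", "VarianceComponents", "compute_grm", "RemlSolver", "reml_h2", "ld_r2"]


@dataclass
class GRM:
    """Symmetric individuals x individuals genomic relationship matrix."""

    matrix: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match GRM")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM not symmetric within 1e-10")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def subset(self, idx: np.ndarray) -> "GRM":
        return GRM(
            matrix=self.matrix[np.ix_(idx, idx)],
            individual_ids=[self.individual_ids[i] for i in np.flatnonzero(np.asarray(idx))]
            if np.asarray(idx).dtype == bool
            else [self.individual_ids[i] for i in idx],
        )


@dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    h2: float
    loglik: float
    converged: bool


def compute_grm(genotypes: GenotypeSet) -> GRM:
    """GCTA-style standardized GRM.

    Entry (j,k) = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    over the m variants polymorphic in this sample, with p_i the in-sample
    alternate-allele frequency. Monomorphic variants are skipped.
    """
    x = genotypes.dosage
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 1:
        raise ValueError("all variants monomorphic; GRM undefined")
    xs = (x[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    g = xs @ xs.T / poly.sum()
    g = (g + g.T) / 2.0  # enforce exact symmetry
    return GRM(matrix=g, individual_ids=list(genotypes.individual_ids))


class RemlSolver:
    """Exact REML for ``y = 1 mu + u + e`` sharing one eigendecomposition.

    The decomposition of the intercept-projected GRM is computed once per
    missingness pattern and reused across CpGs; construct one solver per
    GRM (or GRM subset) and call :meth:`fit` per phenotype vector.
    """

    def __init__(self, grm: GRM):
        n = grm.n
        if n < 2:
            raise ValueError("need at least 2 individuals")
        # orthonormal basis of the space orthogonal to the intercept
        q, _ = np.linalg.qr(np.hstack([np.ones((n, 1)) / np.sqrt(n), np.eye(n, n - 1)]))
        self._q = q[:, 1:]  # n x (n-1)
        m = self._q.T @ grm.matrix @ self._q
        lam, vec = linalg.eigh((m + m.T) / 2.0)
        if lam.min() < -1e-8 * max(1.0, lam.max()):
            raise ValueError("GRM not positive semidefinite within tolerance")
        self.eigenvalues = np.maximum(lam, 0.0)
        self._rot = self._q @ vec  # n x (n-1): maps y -> z
        self.n = n
        # flat spectrum (e.g. identity GRM) makes the ratio unidentifiable
        self.identifiable = (self.eigenvalues.max() - self.eigenvalues.min()) > 1e-8

    def profile_loglik(self, h2: float, y: np.ndarray) -> float:
        """Restricted log-likelihood at heritability ``h2``, profiled over
        the total variance (additive constants dropped)."""
        z2 = (self._rot.T @ y) ** 2
        v = h2 * self.eigenvalues + (1.0 - h2)
        k = self.n - 1
        s2 = np.mean(z2 / v)
        return -0.5 * (k * (np.log(s2) + 1.0) + np.log(v).sum())

    def fit(self, y: np.ndarray, grid_points: int = 21, tol: float = 1e-8) -> VarianceComponents:
        y = np.asarray(y, dtype=float)
        if len(y) != self.n:
            raise ValueError("phenotype length does not match GRM")
        if np.ptp(y) == 0:
            raise ValueError("phenotype is constant; REML undefined")
        z2 = (self._rot.T @ y) ** 2
        lam = self.eigenvalues
        k = self.n - 1

        def negll(h: float) -> float:
            v = h * lam + (1.0 - h)
            s2 = np.mean(z2 / v)
            return 0.5 * (k * (np.log(s2) + 1.0) + np.log(v).sum())

        if not self.identifiable:
            s2 = z2.mean()
            return VarianceComponents(0.0, s2, 0.0, -negll(0.0), converged=False)

        hi = 1.0 - 1e-9
        grid = np.linspace(1e-9, hi, grid_points)
        vals = [negll(h) for h in grid]
        j = int(np.argmin(vals))
        lo, up = grid[max(j - 1, 0)], grid[min(j + 1, grid_points - 1)]
        res = optimize.minimize_scalar(negll, bounds=(lo, up), method="bounded",
                                       options={"xatol": tol})
        h = float(res.x)
        # allow exact boundary solutions
        for hb in (1e-12, hi):
            if negll(hb) < res.fun:
                h = hb
                res.fun = negll(hb)
        h = min(max(h, 0.0), 1.0)
        if h < 1e-8:
            h = 0.0
        elif h > 1.0 - 1e-8:
            h = 1.0
        v = h * lam + (1.0 - h)
        s2 = float(np.mean(z2 / np.maximum(v, 1e-300)))
        return VarianceComponents(
            sigma_u2=h * s2,
            sigma_e2=(1.0 - h) * s2,
            h2=h,
            loglik=-float(res.fun),
            converged=True,
        )


def reml_h2(y: np.ndarray, grm: GRM, warn_n: int = 30) -> VarianceComponents:
    """REML heritability of one phenotype vector.

    Missing values (NaN) are handled by case-wise deletion with matching
    GRM subsetting. For many phenotypes sharing a missingness pattern,
    build a :class:`RemlSolver` once instead.
    """
    import logging

    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    if mask.sum() < len(y):
        grm = grm.subset(mask)
        y = y[mask]
    if len(y) < warn_n:
        logging.getLogger(__name__).warning("reml_h2: only %d individuals", len(y))
    return RemlSolver(grm).fit(y)


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have the same length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
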