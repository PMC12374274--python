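"""Mixed-linear-model meQTL scan with genomic control and cis/trans
classification.

Per CpG the model is

    y = 1*mu + x*b + u + e,   u ~ N(0, G*sigma_u2),  e ~ N(0, I*sigma_e2),

with the variance components estimated once from the no-SNP null model
and then held fixed while each variant is tested (the documented
behaviour of GCTA's ``mlma`` mode). With V = sigma_u2*G + sigma_e2*I
fixed, the per-variant effect is the generalized-least-squares estimate
with the intercept absorbed; the Wald statistic b^2/Var(b) is chi-square
with 1 df. Computationally, y, the intercept and every dosage column are
rotated once by the eigenvectors of G (per missingness pattern), after
which each variant costs O(n).

Genomic-control adjustment divides every chi-square by
lambda_gc = median(chi2) / 0.4549... and is applied unconditionally,
also when lambda_gc < 1.

Classification: |variant - CpG| <= 1 Mb on the same chromosome is cis;
different chromosomes or > 2 Mb is trans; the intermediate 1-2 Mb band
is excluded as a buffer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import GRM, RemlSolver, VarianceComponents
from .io import ASSOCIATION_COLUMNS, GenotypeSet

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_CIS",
    "CLASS_TRANS",
    "CLASS_BUFFER",
    "CLASS_LONGRANGE",
    "CLASS_SPURIOUS",
    "ScanSummary",
    "MlmaScanner",
    "mlma_scan",
    "genomic_control",
    "classify_pair",
    "classify_distance",
    "top_snp",
]

CLASS_CIS = "cis"
CLASS_TRANS = "trans"
CLASS_BUFFER = "buffer_excluded"
CLASS_LONGRANGE = "longrange_cis_excluded"
CLASS_SPURIOUS = "spurious_excluded"

CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...

CIS_WINDOW = 1_000_000
BUFFER_WINDOW = 2_000_000


@dataclass
class ScanSummary:
    cpg_id: str
    lambda_gc: float
    n_tests: int
    sigma_u2_null: float
    sigma_e2_null: float


def classify_distance(same_chrom: np.ndarray, distance: np.ndarray,
                      cis_window: int = CIS_WINDOW,
                      buffer_window: int = BUFFER_WINDOW) -> np.ndarray:
    """Vectorized cis/buffer/trans labels from signed distances."""
    out = np.full(len(same_chrom), CLASS_TRANS, dtype=object)
    absd = np.abs(distance)
    out[same_chrom & (absd <= cis_window)] = CLASS_CIS
    out[same_chrom & (absd > cis_window) & (absd <= buffer_window)] = CLASS_BUFFER
    return out


def classify_pair(cpg: tuple[str, int], variant: tuple[str, int],
                  cis_window: int = CIS_WINDOW,
                  buffer_window: int = BUFFER_WINDOW) -> str:
    """Class of one CpG-variant pair given (chrom, pos) tuples."""
    if cpg[0] != variant[0]:
        return CLASS_TRANS
    return classify_distance(
        np.array([True]), np.array([variant[1] - cpg[1]]), cis_window, buffer_window
    )[0]


class MlmaScanner:
    """Scan many CpGs against one genotype set under a fixed GRM.

    The eigendecomposition of the (subsetted) GRM and the rotated dosage
    matrix are cached per missingness pattern, so scanning a matrix with
    complete data costs one decomposition in total.
    """

    def __init__(self, genotypes: GenotypeSet, grm: GRM):
        if list(genotypes.individual_ids) != list(grm.individual_ids):
            raise ValueError("genotypes and GRM must index the same individuals")
        self.genotypes = genotypes
        self.grm = grm
        self._cache_key: bytes | None = None
        self._cache: dict = {}

    # -- internals ----------------------------------------------------------

    def _pattern(self, mask: np.ndarray) -> dict:
        key = np.packbits(mask).tobytes()
        if key != self._cache_key:
            idx = np.flatnonzero(mask)
            g = self.grm.matrix[np.ix_(idx, idx)]
            lam, u = np.linalg.eigh((g + g.T) / 2.0)
            self._cache = {
                "idx": idx,
                "lam": lam,
                "u": u,
                "ones_r": u.T @ np.ones(len(idx)),
                "g": g,
            }
            self._cache_key = key
        c = self._cache
        return c

    def _reml(self, c: dict) -> RemlSolver:
        if "reml" not in c:
            ids = [self.grm.individual_ids[i] for i in c["idx"]]
            c["reml"] = RemlSolver(GRM(c["g"], ids))
        return c["reml"]

    def _rotated_dosage(self, c: dict) -> None:
        # rotating every dosage column is the dominant cost; do it only
        # when a scan (not just a null-model fit) needs it
        if "xr" not in c:
            xr = c["u"].T @ self.genotypes.dosage[c["idx"]]
            c["xr"] = xr
            c["xr2"] = xr * xr

    def null_model(self, y: np.ndarray) -> VarianceComponents:
        """REML fit of the no-SNP model on the non-missing subset of y."""
        mask = np.isfinite(np.asarray(y, dtype=float))
        c = self._pattern(mask)
        return self._reml(c).fit(np.asarray(y, dtype=float)[mask])

    def scan_arrays(
        self, y: np.ndarray, null_vc: VarianceComponents | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, VarianceComponents]:
        """Per-variant (beta, se, chi2, tested-mask) for one phenotype."""
        y = np.asarray(y, dtype=float)
        mask = np.isfinite(y)
        if mask.sum() < 3:
            raise ValueError("fewer than 3 non-missing individuals")
        c = self._pattern(mask)
        self._rotated_dosage(c)
        if null_vc is None:
            null_vc = self._reml(c).fit(y[mask])
        w = 1.0 / (null_vc.sigma_u2 * c["lam"] + null_vc.sigma_e2)
        yr = c["u"].T @ y[mask]
        onesr = c["ones_r"]
        a = float(w @ (onesr * onesr))
        w1 = w * onesr
        sx1 = c["xr"].T @ w1
        sy1 = float(yr @ w1)
        sxy = c["xr"].T @ (w * yr) - sx1 * sy1 / a
        sxx = c["xr2"].T @ w - sx1 * sx1 / a
        tested = sxx > 1e-10 * mask.sum()
        beta = np.full(len(sxx), np.nan)
        se = np.full(len(sxx), np.nan)
        chi2 = np.full(len(sxx), np.nan)
        beta[tested] = sxy[tested] / sxx[tested]
        se[tested] = np.sqrt(1.0 / sxx[tested])
        chi2[tested] = beta[tested] ** 2 * sxx[tested]
        n_skip = int((~tested).sum())
        if n_skip:
            logger.debug("scan: skipped %d constant variants", n_skip)
        return beta, se, chi2, tested, null_vc

    # -- public API ---------------------------------------------------------

    def scan(
        self,
        y: np.ndarray,
        cpg_id: str,
        cpg_chrom: str,
        cpg_pos: int,
        null_vc: VarianceComponents | None = None,
        gc_adjust: bool = True,
    ) -> tuple[pd.DataFrame, ScanSummary]:
        """Full association table for one CpG against all variants."""
        beta, se, chi2, tested, null_vc = self.scan_arrays(y, null_vc)
        g = self.genotypes
        same = g.chrom == cpg_chrom
        dist = np.where(same, g.pos - cpg_pos, np.nan).astype(float)
        records = pd.DataFrame(
            {
                "cpg_id": cpg_id,
                "variant_id": g.variant_id,
                "beta": beta,
                "se": se,
                "chi2": chi2,
                "p_raw": stats.chi2.sf(chi2, 1),
                "p_adj": np.nan,
                "distance": dist,
                "class": classify_distance(same, np.nan_to_num(dist, nan=np.inf)),
            }
        )[ASSOCIATION_COLUMNS]
        records = records[tested].reset_index(drop=True)
        if gc_adjust:
            records, lam_gc = genomic_control(records)
        else:
            records["p_adj"] = records["p_raw"]
            lam_gc = 1.0
        summary = ScanSummary(
            cpg_id=cpg_id,
            lambda_gc=lam_gc,
            n_tests=int(tested.sum()),
            sigma_u2_null=null_vc.sigma_u2,
            sigma_e2_null=null_vc.sigma_e2,
        )
        return records, summary

    def scan_minima(
        self,
        y: np.ndarray,
        cpg_chrom: str,
        cpg_pos: int,
        null_vc: VarianceComponents | None = None,
        cis_window: int = CIS_WINDOW,
        buffer_window: int = BUFFER_WINDOW,
    ) -> tuple[float, float, float]:
        """(min cis p_adj, min trans p_adj, lambda_gc) for one CpG.

        Fast path used by the permutation calibration: the lowest
        genomic-control-adjusted p within +-1 Mb and the lowest outside
        the cis/buffer window, without materializing a table.
        """
        _, _, chi2, tested, _ = self.scan_arrays(y, null_vc)
        chi2 = chi2[tested]
        lam = max(float(np.median(chi2)) / CHI2_NULL_MEDIAN, 1e-12)
        g = self.genotypes
        same = (g.chrom == cpg_chrom)[tested]
        absd = np.abs(g.pos[tested] - cpg_pos)
        cis = same & (absd <= cis_window)
        trans = ~same | (absd > buffer_window)
        p_adj = stats.chi2.sf(chi2 / lam, 1)
        min_cis = float(p_adj[cis].min()) if cis.any() else np.nan
        min_trans = float(p_adj[trans].min()) if trans.any() else np.nan
        return min_cis, min_trans, lam


def mlma_scan(
    y: np.ndarray,
    genotypes: GenotypeSet,
    grm: GRM,
    null_vc: VarianceComponents | None = None,
    cpg_id: str = "cpg",
    cpg_chrom: str = "",
    cpg_pos: int = 0,
    gc_adjust: bool = True,
) -> tuple[pd.DataFrame, ScanSummary]:
    """One-shot scan of a single CpG (see :class:`MlmaScanner`)."""
    return MlmaScanner(genotypes, grm).scan(
        y, cpg_id, cpg_chrom, cpg_pos, null_vc=null_vc, gc_adjust=gc_adjust
    )


def genomic_control(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Divide chi-squares by lambda_gc = median(chi2)/median(chi2_1df).

    Applied unconditionally (also deflating when lambda_gc < 1); p_adj is
    recomputed from the adjusted chi-square.
    """
    if len(records) == 0:
        raise ValueError("genomic_control: empty record set")
    if len(records) < 100:
        logger.warning("genomic_control: only %d tests; lambda_gc unstable", len(records))
    lam = float(np.median(records["chi2"])) / CHI2_NULL_MEDIAN
    lam = max(lam, 1e-12)
    out = records.copy()
    out["chi2"] = records["chi2"] / lam
    out["p_adj"] = stats.chi2.sf(out["chi2"], 1)
    return out, lam


def top_snp(
    records: pd.DataFrame,
    class_filter: str = CLASS_CIS,
    p_max: float | None = None,
    variant_pos: pd.Series | None = None,
) -> pd.Series | None:
    """The record of the given class with the lowest adjusted p.

    Ties are broken by smaller |distance|, then by lower genomic position
    (when ``variant_pos``, a variant_id -> position mapping, is given).
    Returns None when no record qualifies.
    """
    sub = records[records["class"] == class_filter]
    if p_max is not None:
        sub = sub[sub["p_adj"] < p_max]
    if len(sub) == 0:
        return None
    sub = sub.copy()
    sub["_absd"] = sub["distance"].abs().fillna(np.inf)
    sub["_pos"] = (
        sub["variant_id"].map(variant_pos) if variant_pos is not None else np.arange(len(sub))
    )
    sub = sub.sort_values(["p_adj", "_absd", "_pos"], kind="mergesort")
    return sub.iloc[0][ASSOCIATION_COLUMNS]
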