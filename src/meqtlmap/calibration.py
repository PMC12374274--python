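"""Permutation-based significance thresholds at a target empirical
false-positive rate.

Genotype rows are randomly reassigned to individuals while the GRM used
by the mixed model stays the original one: population-structure
correction is preserved while the genotype-phenotype link is broken.
Each permutation scans a fresh random subset of CpGs (default 10%) and
retains, per CpG, the lowest adjusted p within +-1 Mb (cis) and the
lowest outside the cis/buffer window (trans). The per-CpG minima pooled
over all permutations approximate the null distribution of the best cis
and trans signal per CpG; their ``fpr``-quantile is the significance
threshold, giving an empirical per-CpG false-positive rate of ``fpr``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .association import BUFFER_WINDOW, CIS_WINDOW, MlmaScanner
from .genetics import GRM
from .io import GenotypeSet
from .preprocess import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = ["ThresholdSet", "permute_assignment", "derive_thresholds"]


@dataclass
class ThresholdSet:
    cis_p: float
    trans_p: float
    fpr_target: float
    n_permutations: int
    cpg_fraction: float
    null_minima_cis: list[float] = field(default_factory=list)
    null_minima_trans: list[float] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        return cls(**json.loads(Path(path).read_text()))


def permute_assignment(genotypes: GenotypeSet, seed: int) -> GenotypeSet:
    """Reassign genotype rows to individuals uniformly at random.

    The individual ids (and hence the GRM used downstream) keep their
    original order; per-variant MAFs are invariant.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(genotypes.n_individuals)
    return GenotypeSet(
        variant_id=genotypes.variant_id,
        chrom=genotypes.chrom,
        pos=genotypes.pos,
        dosage=genotypes.dosage[perm],
        maf=genotypes.maf,
        individual_ids=list(genotypes.individual_ids),
    )


def derive_thresholds(
    matrix: MethylationMatrix,
    genotypes: GenotypeSet,
    grm: GRM,
    fpr: float = 0.05,
    n_perm: int = 10,
    cpg_fraction: float = 0.10,
    seed: int = 0,
    cis_window: int = CIS_WINDOW,
    buffer_window: int = BUFFER_WINDOW,
) -> ThresholdSet:
    """Empirical cis and trans significance thresholds.

    Per permutation, a random ``cpg_fraction`` of CpGs is scanned against
    permuted genotypes (unpermuted GRM); per CpG the minimum adjusted p
    within the cis window and the genome-wide minimum outside the
    cis/buffer window are recorded. Thresholds are the ``fpr``-quantile
    of the pooled minima. All minima are retained for audit.
    """
    if not 0 < fpr < 1:
        raise ValueError("fpr must be in (0, 1)")
    if matrix.n_cpgs < 1:
        raise ValueError("empty methylation matrix")
    master = np.random.SeedSequence(seed)
    perm_seeds = master.spawn(n_perm)
    n_sub = max(1, int(round(cpg_fraction * matrix.n_cpgs)))

    # null variance components depend only on (y, GRM): cache across perms
    base_scanner = MlmaScanner(genotypes, grm)
    null_vcs: dict[int, object] = {}

    minima_cis: list[float] = []
    minima_trans: list[float] = []
    for k, seq in enumerate(perm_seeds):
        rng = np.random.default_rng(seq)
        permuted = permute_assignment(genotypes, seed=int(rng.integers(2**31)))
        scanner = MlmaScanner(permuted, grm)
        subset = rng.choice(matrix.n_cpgs, size=n_sub, replace=False)
        for j in subset:
            j = int(j)
            y = matrix.values[:, j]
            if j not in null_vcs:
                null_vcs[j] = base_scanner.null_model(y)
            mc, mt, _ = scanner.scan_minima(
                y, matrix.chrom[j], int(matrix.pos[j]), null_vc=null_vcs[j],
                cis_window=cis_window, buffer_window=buffer_window,
            )
            if np.isfinite(mc):
                minima_cis.append(mc)
            if np.isfinite(mt):
                minima_trans.append(mt)
        logger.info("permutation %d/%d: %d CpGs scanned", k + 1, n_perm, n_sub)

    if min(len(minima_cis), len(minima_trans)) < 20:
        raise ValueError(
            f"only {len(minima_cis)} cis / {len(minima_trans)} trans null minima; "
            "quantile unstable (need >= 20)"
        )
    return ThresholdSet(
        cis_p=float(np.quantile(minima_cis, fpr)),
        trans_p=float(np.quantile(minima_trans, fpr)),
        fpr_target=fpr,
        n_permutations=n_perm,
        cpg_fraction=cpg_fraction,
        null_minima_cis=[float(v) for v in minima_cis],
        null_minima_trans=[float(v) for v in minima_trans],
        seed=seed,
    )
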