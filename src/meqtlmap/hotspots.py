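"""Trans-meQTL hotspot detection and characterization.

A hotspot is a variant associated with many (default >= 30) distant
CpGs, together with the interval spanned by the variants in high LD
(r2 > 0.8) with it inside a +-2 Mb window. Selection is greedy: the
variant with the most associated trans-CpGs becomes a lead, its LD
interval is claimed (variants inside leave the candidate pool), and the
search repeats while a candidate still meets the threshold, so hotspot
intervals from one run are pairwise disjoint.

Also here: effect-direction summaries, independent trans-CpG counting,
100-bp window construction around hotspot CpGs for motif-scanning
export, and genotype-stratified cross-tissue concordance of hotspot
effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import CLASS_TRANS
from .genetics import ld_r2
from .io import GenotypeSet
from .preprocess import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Hotspot",
    "WindowSet",
    "ConcordanceResult",
    "find_hotspots",
    "direction_summary",
    "count_independent_trans",
    "tfbs_windows",
    "cross_tissue_concordance",
    "hotspot_table",
]


@dataclass
class Hotspot:
    hotspot_id: str
    lead_variant: str
    lead_chrom: str
    lead_pos: int
    interval_start: int
    interval_end: int
    trans_cpg_ids: list[str]
    betas: np.ndarray  # lead-variant allele effect per trans-CpG
    n_trans: int = 0
    pct_opposite: float = 0.0
    n_independent: int | None = None

    def __post_init__(self) -> None:
        self.n_trans = len(self.trans_cpg_ids)
        if not self.interval_start <= self.lead_pos <= self.interval_end:
            raise ValueError("hotspot interval must contain the lead variant")


@dataclass
class WindowSet:
    hotspot_id: str
    windows: pd.DataFrame  # chrom, start, end (1-based inclusive)
    n_sequences: int = 0
    retained: bool = True

    def __post_init__(self) -> None:
        self.n_sequences = len(self.windows)


@dataclass
class ConcordanceResult:
    hotspot_id: str
    shared_fraction: float
    skipped: bool
    effect_correlation: float | None = None
    sign_agreement: float | None = None
    stratified_means: pd.DataFrame | None = None


def find_hotspots(
    records: pd.DataFrame,
    genotypes: GenotypeSet,
    min_cpgs: int = 30,
    ld_window: int = 2_000_000,
    ld_r2_threshold: float = 0.8,
) -> list[Hotspot]:
    """Greedy detection of trans-meQTL hotspots from significant records.

    ``records`` should contain the final significant associations; only
    rows with class ``trans`` are used. ``min_cpgs`` is inclusive (a
    variant with exactly 30 trans-CpGs qualifies).
    """
    trans = records[records["class"] == CLASS_TRANS]
    hotspots: list[Hotspot] = []
    if len(trans) == 0:
        return hotspots
    vindex = pd.Series(np.arange(genotypes.n_variants), index=genotypes.variant_id)
    counts = trans.groupby("variant_id")["cpg_id"].nunique()
    available = set(counts.index)

    while True:
        live = counts[counts.index.isin(available)]
        if len(live) == 0 or live.max() < min_cpgs:
            break
        # most CpGs; ties by genomic order for determinism
        best = live[live == live.max()]
        lead = min(best.index, key=lambda v: int(vindex[v]))
        li = int(vindex[lead])
        lead_chrom, lead_pos = genotypes.chrom[li], int(genotypes.pos[li])
        lead_dos = genotypes.dosage[:, li]

        near = np.flatnonzero(
            (genotypes.chrom == lead_chrom)
            & (np.abs(genotypes.pos - lead_pos) <= ld_window)
        )
        in_ld = [li]
        for j in near:
            if j == li or np.ptp(genotypes.dosage[:, j]) == 0:
                continue
            if ld_r2(lead_dos, genotypes.dosage[:, j]) > ld_r2_threshold:
                in_ld.append(int(j))
        start = int(genotypes.pos[in_ld].min())
        end = int(genotypes.pos[in_ld].max())

        sub = trans[trans["variant_id"] == lead].drop_duplicates("cpg_id")
        betas = sub["beta"].to_numpy()
        hs = Hotspot(
            hotspot_id=f"H{len(hotspots) + 1}",
            lead_variant=lead,
            lead_chrom=str(lead_chrom),
            lead_pos=lead_pos,
            interval_start=start,
            interval_end=end,
            trans_cpg_ids=list(sub["cpg_id"]),
            betas=betas,
        )
        hs.pct_opposite = direction_summary(betas)
        hotspots.append(hs)
        # variants inside the claimed interval leave the candidate pool
        claimed = (genotypes.chrom == lead_chrom) & (genotypes.pos >= start) & (
            genotypes.pos <= end
        )
        available -= set(genotypes.variant_id[claimed])

    logger.info("find_hotspots: %d hotspots at min_cpgs=%d", len(hotspots), min_cpgs)
    return hotspots


def direction_summary(betas: np.ndarray) -> float:
    """Percent of trans-CpGs whose effect sign opposes the majority.

    Exact zeros count with the majority; an even split resolves to a
    positive majority by convention. Result is in [0, 50].
    """
    betas = np.asarray(betas, dtype=float)
    n = len(betas)
    if n == 0:
        return 0.0
    n_zero = int((betas == 0).sum())
    if n_zero:
        logger.info("direction_summary: %d zero effects counted with majority", n_zero)
    pos, neg = int((betas > 0).sum()), int((betas < 0).sum())
    minority = neg if pos >= neg else pos
    return 100.0 * minority / n


def count_independent_trans(
    hotspot: Hotspot, matrix: MethylationMatrix, r2_threshold: float = 0.25
) -> int:
    """Number of independent trans-CpGs of a hotspot.

    Adjacent (genomically ordered) trans-CpGs with methylation r2 at or
    above ``r2_threshold`` chain into one cluster; the count is the
    number of clusters. At the default 0.25 this matches collapsing at
    |R| > 0.5.
    """
    idx = pd.Series(np.arange(matrix.n_cpgs), index=matrix.cpg_ids)
    j = idx.loc[hotspot.trans_cpg_ids].to_numpy()
    order = np.lexsort((matrix.pos[j], matrix.chrom[j]))
    j = j[order]
    n_clusters = 0
    prev = None
    for k in j:
        linked = False
        if prev is not None and matrix.chrom[prev] == matrix.chrom[k]:
            a, b = matrix.values[:, prev], matrix.values[:, k]
            shared = np.isfinite(a) & np.isfinite(b)
            if shared.sum() >= 3 and np.ptp(a[shared]) > 0 and np.ptp(b[shared]) > 0:
                r = np.corrcoef(a[shared], b[shared])[0, 1]
                linked = r * r >= r2_threshold
        if not linked:
            n_clusters += 1
        prev = k
    return n_clusters


def tfbs_windows(
    cpg_positions: pd.DataFrame,
    min_sequences: int = 21,
    hotspot_id: str = "",
    half_width: int = 50,
    merge_gap: int = 100,
) -> WindowSet:
    """100-bp windows centred on CpGs, merged when CpGs are < 100 bp apart.

    A run of CpGs with consecutive gaps below ``merge_gap`` yields one
    window from ``half_width`` before the first to ``half_width`` after
    the last CpG. Windows never extend past position 1. The set is
    flagged not-retained when fewer than ``min_sequences`` windows remain
    (strictly more than 20 by default).
    """
    rows = []
    for chrom, grp in cpg_positions.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy())
        run_id = np.concatenate([[0], np.cumsum(np.diff(pos) >= merge_gap)])
        for r in np.unique(run_id):
            p = pos[run_id == r]
            start = int(p[0]) - half_width
            if start < 1:
                logger.warning("tfbs_windows: window truncated at chromosome start")
                start = 1
            rows.append({"chrom": chrom, "start": start, "end": int(p[-1]) + half_width - 1})
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)
    ws = WindowSet(hotspot_id=hotspot_id, windows=windows)
    ws.retained = ws.n_sequences >= min_sequences
    return ws


def cross_tissue_concordance(
    hotspot: Hotspot,
    sperm: MethylationMatrix,
    other: MethylationMatrix,
    genotypes: GenotypeSet,
    min_shared: float = 0.5,
    min_cpgs: int = 3,
) -> ConcordanceResult:
    """Compare a hotspot's per-CpG lead-variant effects across tissues.

    For trans-CpGs with data in both tissues, the per-tissue allele
    effect is the slope of methylation on lead-variant dosage over the
    shared individuals; reported are the Pearson correlation of the two
    effect vectors and their sign-agreement fraction, plus
    genotype-stratified group means for plotting. Hotspots sharing fewer
    than ``min_shared`` of their trans-CpGs (or < ``min_cpgs``) are
    skipped with the fraction reported.
    """
    li = int(np.flatnonzero(genotypes.variant_id == hotspot.lead_variant)[0])
    sperm_idx = pd.Series(np.arange(sperm.n_cpgs), index=sperm.cpg_ids)
    other_idx = pd.Series(np.arange(other.n_cpgs), index=other.cpg_ids)
    shared_ids = [
        c for c in hotspot.trans_cpg_ids if c in sperm_idx.index and c in other_idx.index
    ]
    frac = len(shared_ids) / max(hotspot.n_trans, 1)
    if frac < min_shared or len(shared_ids) < min_cpgs:
        return ConcordanceResult(hotspot.hotspot_id, frac, skipped=True)

    gmap = pd.Series(np.arange(genotypes.n_individuals), index=genotypes.individual_ids)

    def effects(mat: MethylationMatrix, idx: pd.Series) -> np.ndarray:
        rows = [b for b in mat.bull_ids if b in gmap.index]
        dos = genotypes.dosage[gmap.loc[rows].to_numpy(), li]
        v = mat.values[[mat.bull_ids.index(b) for b in rows]]
        out = np.empty(len(shared_ids))
        for k, c in enumerate(shared_ids):
            y = v[:, int(idx[c])]
            ok = np.isfinite(y)
            if ok.sum() < 3 or np.ptp(dos[ok]) == 0:
                out[k] = np.nan
                continue
            out[k] = np.polyfit(dos[ok], y[ok], 1)[0]
        return out

    eff_sperm = effects(sperm, sperm_idx)
    eff_other = effects(other, other_idx)
    ok = np.isfinite(eff_sperm) & np.isfinite(eff_other)
    if ok.sum() < min_cpgs:
        return ConcordanceResult(hotspot.hotspot_id, frac, skipped=True)
    corr = float(np.corrcoef(eff_sperm[ok], eff_other[ok])[0, 1])
    agree = float((np.sign(eff_sperm[ok]) == np.sign(eff_other[ok])).mean())

    # genotype-stratified means (rounded dosage classes 0/1/2) per tissue
    strat_rows = []
    for tissue, mat, idx in (("sperm", sperm, sperm_idx), ("other", other, other_idx)):
        rows = [b for b in mat.bull_ids if b in gmap.index]
        dos = np.rint(genotypes.dosage[gmap.loc[rows].to_numpy(), li]).astype(int)
        v = mat.values[[mat.bull_ids.index(b) for b in rows]]
        for g in (0, 1, 2):
            sel = dos == g
            if not sel.any():
                continue
            for c in shared_ids:
                y = v[sel, int(idx[c])]
                if np.isfinite(y).any():
                    strat_rows.append(
                        {"tissue": tissue, "genotype": g, "cpg_id": c,
                         "mean_meth": float(np.nanmean(y))}
                    )
    return ConcordanceResult(
        hotspot.hotspot_id, frac, skipped=False,
        effect_correlation=corr, sign_agreement=agree,
        stratified_means=pd.DataFrame(strat_rows),
    )


def hotspot_table(hotspots: list[Hotspot]) -> pd.DataFrame:
    """Summary table: one row per hotspot (lead, interval, counts, directionality)."""
    return pd.DataFrame(
        [
            {
                "hotspot": h.hotspot_id,
                "chrom": h.lead_chrom,
                "interval_start": h.interval_start,
                "interval_end": h.interval_end,
                "lead_variant": h.lead_variant,
                "lead_pos": h.lead_pos,
                "n_trans_cpgs": h.n_trans,
                "pct_opposite": h.pct_opposite,
                "n_independent": h.n_independent,
            }
            for h in hotspots
        ],
        columns=[
            "hotspot", "chrom", "interval_start", "interval_end", "lead_variant",
            "lead_pos", "n_trans_cpgs", "pct_opposite", "n_independent",
        ],
    )
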