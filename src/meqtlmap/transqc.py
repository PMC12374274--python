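"""Quality control of significant trans associations.

Two artifact classes are handled:

* **long-range cis contamination** — intrachromosomal trans pairs at
  2-20 Mb whose CpG also carries a cis signal are relabelled
  ``longrange_cis_excluded`` (extended LD, not a distinct trans
  mechanism); a strict mode drops the whole 2-20 Mb stratum;
* **assembly artifacts** — a tight CpG cluster (a few hundred bp to a
  few kb) almost exclusively associated with variants clustered in one
  distant region suggests the CpG sequence is misplaced in the
  reference. Such region pairs are nominated here and confirmed against
  external alignment evidence (BLAST tabular / PAF): when the cluster
  sequence aligns into or near its partner variant region, all its trans
  records become ``spurious_excluded``. Pairs without qualifying
  evidence are retained and reported for manual review.

Record counts are conserved: every input record leaves with exactly one
final class label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import CLASS_CIS, CLASS_LONGRANGE, CLASS_SPURIOUS, CLASS_TRANS
from .io import GenotypeSet
from .preprocess import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SuspiciousRegionPair",
    "exclude_longrange_cis",
    "detect_suspicious_pairs",
    "apply_alignment_filter",
    "review_report",
    "query_manifest",
]

LONGRANGE_MAX = 20_000_000
BUFFER_WINDOW = 2_000_000


@dataclass
class SuspiciousRegionPair:
    cpg_chrom: str
    cpg_start: int
    cpg_end: int
    cpg_ids: list[str]
    variant_chrom: str
    variant_start: int
    variant_end: int
    variant_ids: list[str]
    n_cpgs: int
    status: str = "pending"  # pending | confirmed_artifact | retained
    best_hit: dict = field(default_factory=dict)


def exclude_longrange_cis(
    records: pd.DataFrame,
    cis_cpgs: set[str] | None = None,
    strict: bool = False,
    buffer_window: int = BUFFER_WINDOW,
    longrange_max: int = LONGRANGE_MAX,
) -> pd.DataFrame:
    """Relabel 2-20 Mb intrachromosomal trans records as long-range cis.

    By default only records whose CpG is in ``cis_cpgs`` (CpGs with at
    least one significant cis record; derived from ``records`` when not
    given) are relabelled; ``strict=True`` drops the entire 2-20 Mb
    stratum regardless. Idempotent.
    """
    if cis_cpgs is None:
        cis_cpgs = set(records.loc[records["class"] == CLASS_CIS, "cpg_id"])
    out = records.copy()
    absd = out["distance"].abs()
    in_band = (
        (out["class"] == CLASS_TRANS)
        & out["distance"].notna()
        & (absd > buffer_window)
        & (absd <= longrange_max)
    )
    if not strict:
        in_band &= out["cpg_id"].isin(cis_cpgs)
    out.loc[in_band, "class"] = CLASS_LONGRANGE
    n = int(in_band.sum())
    if n:
        logger.info("exclude_longrange_cis: relabelled %d records", n)
    return out


def _cluster_positions(pos: np.ndarray, gap: int) -> np.ndarray:
    """Single-linkage cluster ids for sorted positions (gap rule)."""
    if len(pos) == 0:
        return np.array([], dtype=int)
    return np.concatenate([[0], np.cumsum(np.diff(pos) > gap)])


def detect_suspicious_pairs(
    records: pd.DataFrame,
    matrix: MethylationMatrix,
    genotypes: GenotypeSet,
    min_cpgs: int = 10,
    cpg_gap: int = 10_000,
    snp_gap: int = 1_000_000,
    exclusivity: float = 0.8,
) -> list[SuspiciousRegionPair]:
    """Nominate CpG-cluster / variant-region pairs with artifact signature.

    Significant trans records are grouped by single-linkage clustering of
    CpG positions (gap <= ``cpg_gap``); per CpG cluster, the partner
    variant positions are clustered with gap <= ``snp_gap`` and the pair
    is emitted when one variant region captures at least ``exclusivity``
    of the cluster's trans records and involves >= ``min_cpgs`` CpGs.
    """
    trans = records[records["class"] == CLASS_TRANS]
    if len(trans) == 0:
        return []
    cpg_coord = pd.DataFrame(
        {"chrom": matrix.chrom, "pos": matrix.pos}, index=matrix.cpg_ids
    )
    var_coord = pd.DataFrame(
        {"chrom": genotypes.chrom, "pos": genotypes.pos}, index=genotypes.variant_id
    )
    t = trans.merge(
        cpg_coord.add_prefix("cpg_"), left_on="cpg_id", right_index=True
    ).merge(var_coord.add_prefix("var_"), left_on="variant_id", right_index=True)

    pairs: list[SuspiciousRegionPair] = []
    for chrom, grp in t.groupby("cpg_chrom"):
        cpgs = grp[["cpg_id", "cpg_pos"]].drop_duplicates().sort_values("cpg_pos")
        cluster_of = dict(
            zip(cpgs["cpg_id"], _cluster_positions(cpgs["cpg_pos"].to_numpy(), cpg_gap))
        )
        grp = grp.assign(_cl=grp["cpg_id"].map(cluster_of))
        for _, sub in grp.groupby("_cl"):
            if sub["cpg_id"].nunique() < min_cpgs:
                continue
            for vchrom, vsub in sub.groupby("var_chrom"):
                vpos = np.sort(vsub["var_pos"].unique())
                vcl = _cluster_positions(vpos, snp_gap)
                region_of = dict(zip(vpos, vcl))
                vsub = vsub.assign(_vcl=vsub["var_pos"].map(region_of))
                counts = vsub.groupby("_vcl").size()
                best = counts.idxmax()
                if counts[best] / len(sub) < exclusivity:
                    continue
                reg = vsub[vsub["_vcl"] == best]
                if reg["cpg_id"].nunique() < min_cpgs:
                    continue
                pairs.append(
                    SuspiciousRegionPair(
                        cpg_chrom=str(chrom),
                        cpg_start=int(reg["cpg_pos"].min()),
                        cpg_end=int(reg["cpg_pos"].max()),
                        cpg_ids=sorted(reg["cpg_id"].unique()),
                        variant_chrom=str(vchrom),
                        variant_start=int(reg["var_pos"].min()),
                        variant_end=int(reg["var_pos"].max()),
                        variant_ids=sorted(reg["variant_id"].unique()),
                        n_cpgs=int(reg["cpg_id"].nunique()),
                    )
                )
    logger.info("detect_suspicious_pairs: %d pending pairs", len(pairs))
    return pairs


def apply_alignment_filter(
    records: pd.DataFrame,
    pairs: list[SuspiciousRegionPair],
    hits: pd.DataFrame,
    min_identity: float = 98.0,
    min_coverage: float = 90.0,
    proximity: int = 1_000_000,
) -> tuple[pd.DataFrame, list[SuspiciousRegionPair]]:
    """Confirm or clear suspicious pairs against alignment evidence.

    A pending pair is a confirmed artifact when some hit maps its CpG
    cluster into (or within ``proximity`` of) its variant region with
    identity >= ``min_identity`` and query coverage >= ``min_coverage``;
    the trans records of confirmed pairs are relabelled
    ``spurious_excluded``. Pairs with no qualifying hit are retained for
    manual review.
    """
    out = records.copy()
    pairs = [SuspiciousRegionPair(**{**p.__dict__}) for p in pairs]
    for pair in pairs:
        qualifying = None
        for hit in hits.itertuples(index=False):
            if hit.query_chrom != pair.cpg_chrom:
                continue
            if hit.query_end < pair.cpg_start or hit.query_start > pair.cpg_end:
                continue
            if hit.subject_chrom != pair.variant_chrom:
                continue
            if (
                hit.subject_end < pair.variant_start - proximity
                or hit.subject_start > pair.variant_end + proximity
            ):
                continue
            if hit.identity >= min_identity and hit.query_coverage >= min_coverage:
                qualifying = hit
                break
        if qualifying is not None:
            pair.status = "confirmed_artifact"
            pair.best_hit = qualifying._asdict()
            drop = (
                (out["class"] == CLASS_TRANS)
                & out["cpg_id"].isin(pair.cpg_ids)
                & out["variant_id"].isin(pair.variant_ids)
            )
            out.loc[drop, "class"] = CLASS_SPURIOUS
        else:
            pair.status = "retained"
    n_conf = sum(p.status == "confirmed_artifact" for p in pairs)
    logger.info(
        "apply_alignment_filter: %d confirmed, %d retained for review",
        n_conf, len(pairs) - n_conf,
    )
    return out, pairs


def review_report(pairs: list[SuspiciousRegionPair]) -> pd.DataFrame:
    """Tabular report of suspicious region pairs and their status."""
    return pd.DataFrame(
        [
            {
                "cpg_region": f"{p.cpg_chrom}:{p.cpg_start}-{p.cpg_end}",
                "variant_region": f"{p.variant_chrom}:{p.variant_start}-{p.variant_end}",
                "n_cpgs": p.n_cpgs,
                "status": p.status,
            }
            for p in pairs
        ],
        columns=["cpg_region", "variant_region", "n_cpgs", "status"],
    )


def query_manifest(pairs: list[SuspiciousRegionPair]) -> pd.DataFrame:
    """BED-ready query regions (one per pending pair) for external aligners.

    Query names follow the ``chrom:start-end`` convention expected by the
    BLAST/PAF readers.
    """
    return pd.DataFrame(
        [
            {
                "chrom": p.cpg_chrom,
                "start": p.cpg_start,
                "end": p.cpg_end,
                "label": f"{p.cpg_chrom}:{p.cpg_start}-{p.cpg_end}",
            }
            for p in pairs
            if p.status == "pending"
        ],
        columns=["chrom", "start", "end", "label"],
    )
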