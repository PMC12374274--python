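"""Genomic annotation with priority resolution, independent-CpG
collapsing, and enrichment statistics.

Two enrichment routes are provided:

* :func:`fisher_enrichment` — two-sided Fisher exact tests of an
  interest set against its universe, per label, with Benjamini-Hochberg
  adjustment across all labels jointly (used for heritable CpGs);
* :func:`resampled_enrichment` — odds ratios against resampled
  background sets of the same size, optionally stratified to match the
  interest set's MAF (and distance-to-CpG) class histogram exactly,
  repeated (default 1,000 times) to give a mean OR, a percentile 95% CI
  and an empirical two-sided p (used for top meQTL SNPs and CpGs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTrack",
    "DEFAULT_TRACK_SCHEMES",
    "MAF_CLASS_EDGES",
    "DISTANCE_CLASS_EDGES",
    "assign_label",
    "assign_labels",
    "collapse_independent",
    "fisher_enrichment",
    "resampled_enrichment",
    "maf_class",
    "distance_class",
]

# label priority (first wins) and fallback per category
DEFAULT_TRACK_SCHEMES = {
    "genomic_feature": (
        ["TSS200", "TSS1500", "5UTR", "first_exon", "3UTR", "body"],
        "intergenic",
    ),
    "cgi_landscape": (["CGI", "CGI_shore", "CGI_shelf"], "open_sea"),
    "te": (["LTR", "SINE", "LINE", "DNA"], "no_TE"),
    "atac": (["ATAC_peak"], "no_peak"),
}

ENRICHMENT_COLUMNS = [
    "label", "or_mean", "ci_low", "ci_high", "p",
    "n_interest", "n_background", "n_replicates",
]

# MAF class edges: [0.03,0.05), [0.05,0.1), [0.1,0.2), [0.2,0.5]
MAF_CLASS_EDGES = [0.03, 0.05, 0.1, 0.2, 0.5]
# signed distance classes (bp): [-1Mb,-500kb), ..., [500kb,1Mb]
DISTANCE_CLASS_EDGES = [-1_000_000, -500_000, -100_000, -10_000, 10_000, 100_000, 500_000, 1_000_000]


@dataclass
class AnnotationTrack:
    """One annotation category: labelled intervals plus a priority order.

    Every position resolves to exactly one label: the highest-priority
    overlapping label, or ``fallback`` when nothing overlaps.
    """

    category: str
    intervals: pd.DataFrame  # chrom, start, end, label (1-based inclusive)
    priority_order: list[str]
    fallback: str

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for chrom, grp in self.intervals.groupby("chrom"):
            # intervaltree is half-open; +1 makes [start, end] inclusive
            self._trees[str(chrom)] = IntervalTree.from_tuples(
                (int(s), int(e) + 1, lab)
                for s, e, lab in zip(grp["start"], grp["end"], grp["label"])
            )
        self._rank = {lab: i for i, lab in enumerate(self.priority_order)}

    def lookup(self, chrom: str, pos: int) -> str:
        tree = self._trees.get(str(chrom))
        if tree is None:
            return self.fallback
        hits = [iv.data for iv in tree.at(int(pos)) if iv.data in self._rank]
        if not hits:
            return self.fallback
        return min(hits, key=self._rank.__getitem__)


def assign_label(position: tuple[str, int], track: AnnotationTrack) -> str:
    """Label of one (chrom, pos) under the track's priority order."""
    chrom, pos = position
    if str(chrom) not in track._trees:
        logger.warning("assign_label: chromosome %s absent from track %s",
                       chrom, track.category)
    return track.lookup(chrom, pos)


def assign_labels(positions: pd.DataFrame, track: AnnotationTrack) -> pd.Series:
    """Vectorized labelling of a (chrom, pos) frame; index is preserved."""
    return pd.Series(
        [track.lookup(c, p) for c, p in zip(positions["chrom"], positions["pos"])],
        index=positions.index,
        name=track.category,
    )


def collapse_independent(
    matrix: MethylationMatrix, r_threshold: float = 0.5, min_shared: int = 3
) -> tuple[np.ndarray, pd.DataFrame]:
    """Chain-link adjacent correlated CpGs into clusters of one representative.

    Walking each chromosome in genomic order, consecutive CpGs join a
    cluster when their methylation correlation over shared non-missing
    bulls exceeds ``r_threshold``; the representative is the middle CpG
    by rank (lower middle for even sizes). Returns the representative ids
    and a cpg_id -> cluster/representative map.
    """
    order = np.lexsort((matrix.pos, matrix.chrom))
    cluster = np.empty(matrix.n_cpgs, dtype=int)
    cid = -1
    prev_chrom = None
    prev_j = None
    for j in order:
        new = prev_chrom != matrix.chrom[j]
        if not new:
            a, b = matrix.values[:, prev_j], matrix.values[:, j]
            shared = np.isfinite(a) & np.isfinite(b)
            r = 0.0
            if shared.sum() >= min_shared and np.ptp(a[shared]) > 0 and np.ptp(b[shared]) > 0:
                r = np.corrcoef(a[shared], b[shared])[0, 1]
            new = not (r > r_threshold)
        if new:
            cid += 1
        cluster[j] = cid
        prev_chrom, prev_j = matrix.chrom[j], j

    rows = []
    reps = []
    for c in range(cid + 1):
        members = order[cluster[order] == c]
        rep = members[(len(members) - 1) // 2]  # lower middle
        reps.append(matrix.cpg_ids[rep])
        for m in members:
            rows.append((matrix.cpg_ids[m], c, matrix.cpg_ids[rep]))
    cmap = pd.DataFrame(rows, columns=["cpg_id", "cluster", "representative"])
    return np.array(reps, dtype=object), cmap


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """OR of a 2x2 table with Haldane 0.5 correction when any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_enrichment(
    interest: set, universe: set, labels: pd.Series
) -> pd.DataFrame:
    """Per-label two-sided Fisher exact enrichment of interest vs universe.

    ``labels`` maps every universe member to its label. The 2x2 table
    compares the interest set against the whole universe (so an interest
    set equal to its universe has OR exactly 1 for every label). The
    odds ratio uses the Haldane correction for zero cells (the exact p
    does not); p values are Benjamini-Hochberg adjusted across all
    labels jointly.
    """
    if not interest:
        raise ValueError("empty interest set")
    if not interest <= universe:
        raise ValueError("interest must be a subset of the universe")
    lab = labels.loc[list(universe)]
    in_interest = lab.index.isin(interest)
    n_int, n_uni = int(in_interest.sum()), len(lab)
    rows = []
    for label in sorted(lab.unique()):
        has = (lab == label).to_numpy()
        a = int((has & in_interest).sum())
        b = n_int - a
        c = int(has.sum())
        d = n_uni - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {"label": label, "odds_ratio": _odds_ratio(a, b, c, d), "p_raw": p,
             "n_interest_label": a, "n_universe_label": c}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


def maf_class(maf: np.ndarray) -> np.ndarray:
    """MAF class index; values outside [0.03, 0.5] raise."""
    maf = np.asarray(maf, dtype=float)
    if (maf < MAF_CLASS_EDGES[0] - 1e-12).any() or (maf > 0.5 + 1e-12).any():
        raise ValueError("MAF outside [0.03, 0.5]")
    # right-open classes except the last, which is closed
    return np.minimum(
        np.searchsorted(MAF_CLASS_EDGES[1:], maf, side="right"),
        len(MAF_CLASS_EDGES) - 2,
    )


def distance_class(distance: np.ndarray) -> np.ndarray:
    """Signed cis-distance class index over the seven standard bins."""
    d = np.asarray(distance, dtype=float)
    if (d < DISTANCE_CLASS_EDGES[0]).any() or (d > DISTANCE_CLASS_EDGES[-1]).any():
        raise ValueError("distance outside [-1 Mb, 1 Mb]")
    return np.minimum(
        np.searchsorted(DISTANCE_CLASS_EDGES[1:], d, side="right"),
        len(DISTANCE_CLASS_EDGES) - 2,
    )


def resampled_enrichment(
    interest: pd.DataFrame,
    pool: pd.DataFrame,
    labels: pd.Series,
    matching: str = "none",
    n_rep: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Matched-background resampling enrichment.

    Per replicate a background of the interest set's size is drawn
    without replacement from ``pool``; with ``matching='maf'`` or
    ``'maf_distance'`` the draw is stratified so the background's joint
    class histogram equals the interest set's exactly (``interest`` and
    ``pool`` then need ``maf`` and, for the joint scheme, ``distance``
    columns). ``labels`` maps ids (the frames' ``id`` column) to labels.
    Returns one row per label with the mean OR, percentile 95% CI and an
    empirical two-sided p floored at 1/n_rep.
    """
    if matching not in {"none", "maf", "maf_distance"}:
        raise ValueError(f"unknown matching scheme {matching!r}")
    rng = np.random.default_rng(seed)
    n = len(interest)
    if n == 0:
        raise ValueError("empty interest set")

    def strata(df: pd.DataFrame) -> np.ndarray:
        if matching == "none":
            return np.zeros(len(df), dtype=int)
        key = maf_class(df["maf"].to_numpy())
        if matching == "maf_distance":
            key = key * 10 + distance_class(df["distance"].to_numpy())
        return key

    int_strata = strata(interest)
    pool_strata = strata(pool)
    need = pd.Series(int_strata).value_counts()
    pool_idx_by_stratum = {
        s: np.flatnonzero(pool_strata == s) for s in need.index
    }
    for s, k in need.items():
        if len(pool_idx_by_stratum[s]) < k:
            raise ValueError(
                f"stratum {s}: pool has {len(pool_idx_by_stratum[s])} < {k} required"
            )

    interest_labels = labels.loc[interest["id"]].to_numpy()
    pool_labels = labels.loc[pool["id"]].to_numpy()
    all_labels = sorted(set(interest_labels) | set(pool_labels))
    lab_index = {lab: i for i, lab in enumerate(all_labels)}
    n_lab = len(all_labels)
    int_counts = np.bincount(
        [lab_index[lab] for lab in interest_labels], minlength=n_lab
    )
    pool_codes = np.array([lab_index[lab] for lab in pool_labels])

    ors = np.empty((n_rep, n_lab))
    for rep in range(n_rep):
        bg = np.concatenate(
            [
                rng.choice(pool_idx_by_stratum[s], size=k, replace=False)
                for s, k in need.items()
            ]
        )
        bg_counts = np.bincount(pool_codes[bg], minlength=n_lab)
        for i in range(n_lab):
            ors[rep, i] = _odds_ratio(
                int(int_counts[i]), n - int(int_counts[i]),
                int(bg_counts[i]), n - int(bg_counts[i]),
            )

    rows = []
    for i, lab in enumerate(all_labels):
        col = ors[:, i]
        p = 2.0 * min((col <= 1.0).mean(), (col >= 1.0).mean())
        rows.append(
            {
                "label": lab,
                "or_mean": float(col.mean()),
                "ci_low": float(np.percentile(col, 2.5)),
                "ci_high": float(np.percentile(col, 97.5)),
                "p": float(min(max(p, 1.0 / n_rep), 1.0)),
                "n_interest": n,
                "n_background": n,
                "n_replicates": n_rep,
            }
        )
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
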