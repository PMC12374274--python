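"""From per-sample CpG read counts to the per-bull analysis matrix.

Steps, in the order they are applied:

1. per-sample entries below the read-depth floor (default 10) are dropped;
2. per bull and CpG, methylation percentages are averaged weighted by read
   depth;
3. CpGs are filtered: present in >= 80% of bulls, not overlapping a known
   variant, methylation s.d. strictly > 5%;
4. methylation is corrected for age at collection using four age classes
   (< 500 d; [500, 750] d; (750, 1000] d; > 1000 d) by class-mean centering
   with grand-mean restoration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import validate_sample_meta

logger = logging.getLogger(__name__)

__all__ = [
    "MethylationMatrix",
    "methylation_percent",
    "aggregate_bull",
    "select_variable_cpgs",
    "assign_age_class",
    "correct_for_age",
]

DEFAULT_AGE_BOUNDS = (500, 750, 1000)


@dataclass
class MethylationMatrix:
    """Bulls x CpGs methylation percentages with depth weights.

    ``values`` holds %methylation in [0, 100] with NaN for missing; the
    parallel ``depth_weights`` matrix holds the summed read depth behind
    each entry (0 where missing).
    """

    bull_ids: list[str]
    cpg_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    values: np.ndarray
    depth_weights: np.ndarray
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cpg_ids = np.asarray(self.cpg_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.depth_weights = np.asarray(self.depth_weights, dtype=float)
        if self.values.shape != (len(self.bull_ids), len(self.cpg_ids)):
            raise ValueError("values shape does not match bull_ids x cpg_ids")
        if self.depth_weights.shape != self.values.shape:
            raise ValueError("depth_weights shape mismatch")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 100 + 1e-9):
            raise ValueError("methylation values outside [0, 100]")

    @property
    def n_bulls(self) -> int:
        return len(self.bull_ids)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def sd_per_cpg(self) -> np.ndarray:
        """Population s.d. (divide by n) over non-missing bulls, per CpG."""
        with np.errstate(invalid="ignore"):
            return np.nanstd(self.values, axis=0, ddof=0)

    @property
    def presence(self) -> np.ndarray:
        return np.isfinite(self.values).mean(axis=0)

    def subset_cpgs(self, mask: np.ndarray) -> "MethylationMatrix":
        return MethylationMatrix(
            bull_ids=list(self.bull_ids),
            cpg_ids=self.cpg_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            values=self.values[:, mask],
            depth_weights=self.depth_weights[:, mask],
            filter_log=dict(self.filter_log),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=self.bull_ids)
        df.insert(0, "pos", self.pos)
        df.insert(0, "chrom", self.chrom)
        df.insert(0, "cpg_id", self.cpg_ids)
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA",
                               float_format="%.6g")


def methylation_percent(count_meth: int, count_unmeth: int) -> float:
    """Percentage of methylated reads: 100 * C / (C + T)."""
    depth = count_meth + count_unmeth
    if depth <= 0:
        raise ValueError("methylation percentage undefined at zero depth")
    return 100.0 * count_meth / depth


def aggregate_bull(
    samples: pd.DataFrame, meta: pd.DataFrame, min_depth: int = 10
) -> MethylationMatrix:
    """Collapse per-sample CpG counts into a per-bull matrix.

    Per-sample entries with depth < ``min_depth`` are discarded before
    averaging; the per-bull value is the depth-weighted mean of the
    remaining sample percentages, and ``depth_weights`` is their summed
    depth. A bull with no surviving sample at a CpG is missing there.
    """
    validate_sample_meta(meta)
    unknown = set(samples["sample_id"]) - set(meta["sample_id"])
    if unknown:
        raise ValueError(f"samples absent from metadata: {sorted(unknown)[:5]}")
    df = samples.merge(meta[["sample_id", "bull_id"]], on="sample_id")
    df["depth"] = df["count_meth"] + df["count_unmeth"]
    n_low = int((df["depth"] < min_depth).sum())
    if n_low:
        logger.info("aggregate_bull: dropped %d entries below depth %d", n_low, min_depth)
    df = df[df["depth"] >= min_depth]
    df["meth_reads"] = df["count_meth"].astype(float)

    agg = df.groupby(["chrom", "pos", "bull_id"], sort=True).agg(
        meth=("meth_reads", "sum"), depth=("depth", "sum")
    )
    agg["pct"] = 100.0 * agg["meth"] / agg["depth"]
    wide_v = agg["pct"].unstack("bull_id")
    wide_d = agg["depth"].unstack("bull_id")

    bulls = sorted(meta.loc[meta["sample_id"].isin(samples["sample_id"]), "bull_id"].unique())
    wide_v = wide_v.reindex(columns=bulls)
    wide_d = wide_d.reindex(columns=bulls)
    chrom = np.array([c for c, _ in wide_v.index], dtype=object)
    pos = np.array([p for _, p in wide_v.index], dtype=np.int64)
    return MethylationMatrix(
        bull_ids=bulls,
        cpg_ids=np.array([f"{c}:{p}" for c, p in zip(chrom, pos)], dtype=object),
        chrom=chrom,
        pos=pos,
        values=wide_v.to_numpy(dtype=float).T,
        depth_weights=np.nan_to_num(wide_d.to_numpy(dtype=float).T),
    )


def select_variable_cpgs(
    matrix: MethylationMatrix,
    variant_positions: set[tuple[str, int]] | None = None,
    min_presence: float = 0.8,
    sd_min: float = 5.0,
) -> MethylationMatrix:
    """Apply the presence, variant-overlap and variability filters.

    Order follows the pipeline convention: presence >= ``min_presence``,
    then removal of CpGs at known variant positions, then s.d. strictly
    greater than ``sd_min`` (a CpG at exactly the threshold is removed).
    Per-rule removal counts are recorded in ``filter_log``.
    """
    n0 = matrix.n_cpgs
    keep = matrix.presence >= min_presence
    n_presence = int(n0 - keep.sum())

    if variant_positions:
        at_variant = np.array(
            [(c, p) in variant_positions for c, p in zip(matrix.chrom, matrix.pos)]
        )
        n_variant = int((keep & at_variant).sum())
        keep &= ~at_variant
    else:
        n_variant = 0

    low_sd = matrix.sd_per_cpg <= sd_min
    n_sd = int((keep & low_sd).sum())
    keep &= ~low_sd

    if not keep.any():
        raise ValueError("no CpGs survive the presence/variant/s.d. filters")
    out = matrix.subset_cpgs(keep)
    out.filter_log.update(
        {"input": n0, "removed_presence": n_presence, "removed_variant_overlap": n_variant,
         "removed_low_sd": n_sd, "retained": int(keep.sum())}
    )
    logger.info("select_variable_cpgs: %s", out.filter_log)
    return out


def assign_age_class(age_days: np.ndarray, class_bounds=DEFAULT_AGE_BOUNDS) -> np.ndarray:
    """Age class index with boundary conventions <b0; [b0,b1]; (b1,b2]; >b2."""
    b0, b1, b2 = class_bounds
    age = np.asarray(age_days)
    out = np.full(age.shape, 3, dtype=int)
    out[age < b0] = 0
    out[(age >= b0) & (age <= b1)] = 1
    out[(age > b1) & (age <= b2)] = 2
    return out


def correct_for_age(
    matrix: MethylationMatrix,
    meta: pd.DataFrame,
    class_bounds=DEFAULT_AGE_BOUNDS,
) -> MethylationMatrix:
    """Remove age-class means per CpG, restoring the grand mean.

    Equivalent to fitting a fixed age-class factor per CpG and keeping the
    residual plus intercept; values stay on the %methylation scale but may
    be clipped back to [0, 100] after shifting. Classes with fewer than 2
    bulls are merged with the nearest lower class (with a warning).
    """
    validate_sample_meta(meta)
    bull_age = meta.drop_duplicates("bull_id").set_index("bull_id")["age_days"]
    missing = [b for b in matrix.bull_ids if b not in bull_age.index]
    if missing:
        raise ValueError(f"bulls without metadata: {missing[:5]}")
    cls = assign_age_class(bull_age.loc[matrix.bull_ids].to_numpy(), class_bounds)

    # merge undersized classes into the nearest populated neighbour
    for c in range(4):
        if 0 < (cls == c).sum() < 2:
            others = [d for d in range(4) if d != c and (cls == d).sum() >= 2]
            if not others:
                continue
            target = min(others, key=lambda d: abs(d - c))
            logger.warning("correct_for_age: class %d has <2 bulls; merged with %d", c, target)
            cls[cls == c] = target

    v = matrix.values.copy()
    with np.errstate(invalid="ignore"):
        grand = np.nanmean(v, axis=0)
        for c in np.unique(cls):
            rows = cls == c
            class_mean = np.nanmean(v[rows], axis=0)
            # CpGs where this class has no data keep their values
            shift = np.where(np.isfinite(class_mean), class_mean - grand, 0.0)
            v[rows] -= shift
    v = np.clip(v, 0.0, 100.0)
    return MethylationMatrix(
        bull_ids=list(matrix.bull_ids),
        cpg_ids=matrix.cpg_ids,
        chrom=matrix.chrom,
        pos=matrix.pos,
        values=v,
        depth_weights=matrix.depth_weights,
        filter_log=dict(matrix.filter_log),
    )
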