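"""Readers and writers for the file formats used across the pipeline.

Formats handled here:

* genotypes — VCF (GT or DS fields, via :mod:`cyvcf2`) or a plain dosage
  table (``variant_id  chrom  pos  <one column per individual>``);
* per-sample CpG methylation — Bismark-coverage-style tables;
* association tables, BED annotation tracks, and alignment evidence
  (BLAST tabular ``outfmt 6`` or PAF).

Coordinate convention: every in-memory position is 1-based inclusive.
BED files on disk are 0-based half-open; the BED reader/writer are the
only places where offsets change.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeSet",
    "read_genotypes",
    "write_dosage_table",
    "read_methylation_tables",
    "write_coverage_table",
    "SAMPLE_META_COLUMNS",
    "read_sample_meta",
    "write_sample_meta",
    "ASSOCIATION_COLUMNS",
    "write_association_table",
    "read_association_table",
    "read_bed",
    "write_bed",
    "ALIGNMENT_COLUMNS",
    "read_blast_tab",
    "read_paf",
    "write_alignment_table",
    "read_alignment_table",
    "export_fasta_windows",
]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSet:
    """Diploid dosage matrix with variant coordinates and in-sample MAF.

    ``dosage`` is individuals x variants with values in [0, 2] (imputed,
    possibly fractional, dosages are accepted and used as continuous
    values downstream).
    """

    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    maf: np.ndarray
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        self.validate()

    # -- properties ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def variants(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "maf": self.maf,
            }
        )

    def validate(self) -> None:
        n, m = self.dosage.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        for arr, name in (
            (self.variant_id, "variant_id"),
            (self.chrom, "chrom"),
            (self.pos, "pos"),
            (self.maf, "maf"),
        ):
            if len(arr) != m:
                raise ValueError(f"{name} length does not match dosage columns")
        if m and (self.maf.min() < -1e-12 or self.maf.max() > 0.5 + 1e-12):
            raise ValueError("maf outside [0, 0.5]")
        if self.dosage.size and (
            np.nanmin(self.dosage) < -1e-9 or np.nanmax(self.dosage) > 2 + 1e-9
        ):
            raise ValueError("dosage values outside [0, 2]")
        ids, counts = np.unique(self.variant_id, return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate variant_id {dup!r}")
        # positions strictly increasing within chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    def subset_variants(self, mask: np.ndarray) -> "GenotypeSet":
        return GenotypeSet(
            variant_id=self.variant_id[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            dosage=self.dosage[:, mask],
            maf=self.maf[mask],
            individual_ids=list(self.individual_ids),
        )


def _allele_freq(dosage: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per variant, ignoring missing entries."""
    return np.nanmean(dosage, axis=0) / 2.0


def compute_maf(dosage: np.ndarray) -> np.ndarray:
    p = _allele_freq(dosage)
    return np.minimum(p, 1.0 - p)


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_dosage_table(path: Path) -> GenotypeSet:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed dosage table {path}: {exc}") from exc
    required = ["variant_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"dosage table {path} must start with columns {required}, "
            f"got {list(df.columns[:3])}"
        )
    ind_cols = list(df.columns[3:])
    if not ind_cols:
        raise ValueError(f"dosage table {path} has no individual columns")
    dosage = df[ind_cols].to_numpy(dtype=float).T
    # order variants by (chrom, pos)
    order = np.lexsort((df["pos"].to_numpy(), df["chrom"].astype(str).to_numpy()))
    return GenotypeSet(
        variant_id=df["variant_id"].to_numpy()[order],
        chrom=df["chrom"].astype(str).to_numpy()[order],
        pos=df["pos"].to_numpy()[order],
        dosage=dosage[:, order],
        maf=compute_maf(dosage[:, order]),
        individual_ids=ind_cols,
    )


def _read_vcf(path: Path) -> GenotypeSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    vid, chrom, pos, rows = [], [], [], []
    for i, var in enumerate(vcf):
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan  # missing call
            d = gt.sum(axis=1)
        if np.isnan(d).any():
            # mean-impute missing genotype calls (kept within [0, 2])
            d = np.where(np.isnan(d), np.nanmean(d), d)
        vid.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        rows.append(d)
    if not rows:
        raise ValueError(f"VCF {path} contains no variants")
    dosage = np.stack(rows, axis=1)
    return GenotypeSet(
        variant_id=np.asarray(vid, dtype=object),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        dosage=dosage,
        maf=compute_maf(dosage),
        individual_ids=individual_ids,
    )


def read_genotypes(path: str | Path, maf_min: float = 0.03) -> GenotypeSet:
    """Read genotypes from a VCF or a dosage table and apply the MAF filter.

    Variants with in-sample MAF below ``maf_min`` are removed and the MAF is
    recomputed from the retained individuals. The default 3% threshold, at
    405 diploid individuals, guarantees at least ceil(0.03*810) = 25 copies
    of the rare allele.
    """
    path = Path(path)
    with _open_text(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix in {".vcf", ".bcf"} or str(
        path
    ).endswith(".vcf.gz"):
        gset = _read_vcf(path)
    else:
        gset = _read_dosage_table(path)
    keep = gset.maf >= maf_min - 1e-12
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("read_genotypes: removed %d variants with MAF < %g", n_removed, maf_min)
    if not keep.any():
        raise ValueError(f"all {gset.n_variants} variants removed by MAF >= {maf_min}")
    return gset.subset_variants(keep)


def write_dosage_table(gset: GenotypeSet, path: str | Path) -> Path:
    """Write a GenotypeSet as the plain dosage table read_genotypes accepts."""
    path = Path(path)
    df = pd.DataFrame(gset.dosage.T, columns=gset.individual_ids)
    df.insert(0, "pos", gset.pos)
    df.insert(0, "chrom", gset.chrom)
    df.insert(0, "variant_id", gset.variant_id)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# Methylation sample tables (Bismark-coverage-style)
# ---------------------------------------------------------------------------

METH_COLUMNS = ["chrom", "pos", "count_meth", "count_unmeth", "sample_id"]


def _merge_strand_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Merge both-strand rows at pos and pos+1 onto the forward-strand C.

    CpGs on the same strand are >= 2 bp apart, so adjacent rows 1 bp apart
    are the two strands of one CpG; their counts are summed at the lower
    position.
    """
    df = df.sort_values(["sample_id", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    same_block = (
        (df["chrom"] == df["chrom"].shift())
        & (df["sample_id"] == df["sample_id"].shift())
        & (df["pos"] - df["pos"].shift() == 1)
    ).to_numpy()
    # greedy pairing: a row merges into its predecessor only if that
    # predecessor was not itself merged
    merge_into_prev = np.zeros(len(df), dtype=bool)
    for i in np.flatnonzero(same_block):
        if not merge_into_prev[i - 1]:
            merge_into_prev[i] = True
    if not merge_into_prev.any():
        return df
    key = np.arange(len(df))
    key[merge_into_prev] = key[merge_into_prev] - 1
    out = df.groupby(key, sort=False).agg(
        chrom=("chrom", "first"),
        pos=("pos", "first"),
        count_meth=("count_meth", "sum"),
        count_unmeth=("count_unmeth", "sum"),
        sample_id=("sample_id", "first"),
    )
    return out.reset_index(drop=True)


def read_methylation_tables(
    paths: Iterable[str | Path],
    sample_ids: Sequence[str] | None = None,
    merge_strands: bool = True,
) -> pd.DataFrame:
    """Read Bismark-coverage-style files into one long per-sample table.

    Accepted layouts (no header): 6 columns
    ``chrom  start  end  %meth  count_meth  count_unmeth`` (classic
    coverage file; ``start`` is taken as the 1-based C position) or 5
    columns without ``end``. A headered TSV with the output columns
    (``chrom pos count_meth count_unmeth [sample_id]``) is also accepted.

    Rows with zero depth are dropped (counted in the log); methylation
    percentages outside [0, 100] raise a validation error.
    """
    paths = [Path(p) for p in paths]
    if sample_ids is None:
        sample_ids = [p.name.split(".")[0] for p in paths]
    frames = []
    n_zero = 0
    for path, sid in zip(paths, sample_ids):
        with _open_text(path) as fh:
            first = fh.readline()
        if not first.strip():
            logger.warning("read_methylation_tables: %s is empty", path)
            continue
        if first.split("\t")[0] == "chrom":  # headered
            df = pd.read_csv(path, sep="\t")
            if "sample_id" not in df.columns:
                df["sample_id"] = sid
        else:
            raw = pd.read_csv(path, sep="\t", header=None)
            if raw.shape[1] == 6:
                raw.columns = ["chrom", "pos", "end", "pct", "count_meth", "count_unmeth"]
            elif raw.shape[1] == 5:
                raw.columns = ["chrom", "pos", "pct", "count_meth", "count_unmeth"]
            elif raw.shape[1] == 4:
                # percentage + depth only: reconstruct counts
                raw.columns = ["chrom", "pos", "pct", "depth"]
                raw["count_meth"] = np.rint(raw["pct"] * raw["depth"] / 100.0).astype(int)
                raw["count_unmeth"] = raw["depth"].astype(int) - raw["count_meth"]
            else:
                raise ValueError(
                    f"{path}: expected 4-6 columns in headerless coverage file, got {raw.shape[1]}"
                )
            if "pct" in raw.columns:
                bad = raw[(raw["pct"] < 0) | (raw["pct"] > 100)]
                if len(bad):
                    raise ValueError(
                        f"{path}: methylation percentage outside [0,100] at line {bad.index[0] + 1}"
                    )
            df = raw[["chrom", "pos", "count_meth", "count_unmeth"]].copy()
            df["sample_id"] = sid
        if (df[["count_meth", "count_unmeth"]] < 0).to_numpy().any():
            raise ValueError(f"{path}: negative read counts")
        depth = df["count_meth"] + df["count_unmeth"]
        n_zero += int((depth == 0).sum())
        frames.append(df[depth > 0])
    if n_zero:
        logger.info("read_methylation_tables: dropped %d zero-depth rows", n_zero)
    if not frames:
        logger.warning("read_methylation_tables: no data rows in any input")
        return pd.DataFrame(columns=METH_COLUMNS)
    out = pd.concat(frames, ignore_index=True)[METH_COLUMNS]
    out["chrom"] = out["chrom"].astype(str)
    out["pos"] = out["pos"].astype(np.int64)
    if merge_strands:
        out = _merge_strand_rows(out)
    return out


def write_coverage_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write one sample's rows as a 6-column Bismark-style coverage file."""
    path = Path(path)
    depth = table["count_meth"] + table["count_unmeth"]
    out = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "pos": table["pos"],
            "end": table["pos"],
            "pct": 100.0 * table["count_meth"] / depth,
            "count_meth": table["count_meth"],
            "count_unmeth": table["count_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

SAMPLE_META_COLUMNS = ["sample_id", "bull_id", "age_days", "tissue"]


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    if (meta["age_days"] <= 0).any():
        raise ValueError("age_days must be > 0")
    bad = set(meta["tissue"]) - {"sperm", "pbmc"}
    if bad:
        raise ValueError(f"unknown tissue values {sorted(bad)}")
    return meta


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    return validate_sample_meta(pd.read_csv(path, sep="\t"))


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> Path:
    validate_sample_meta(meta).to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------

ASSOCIATION_COLUMNS = [
    "cpg_id",
    "variant_id",
    "beta",
    "se",
    "chi2",
    "p_raw",
    "p_adj",
    "distance",
    "class",
]


def write_association_table(records: pd.DataFrame, path: str | Path) -> Path:
    """Write association records as TSV (one row per CpG-variant pair).

    ``distance`` is the signed variant-minus-CpG distance, empty for
    interchromosomal pairs. Round-trips losslessly through
    :func:`read_association_table`.
    """
    path = Path(path)
    missing = [c for c in ASSOCIATION_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"association records missing columns {missing}")
    records[ASSOCIATION_COLUMNS].to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )
    return path


def read_association_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("beta", "se", "chi2", "p_raw", "p_adj", "distance"):
        df[col] = df[col].astype(float)
    for col in ("cpg_id", "variant_id", "class"):
        df[col] = df[col].astype(str)
    return df[ASSOCIATION_COLUMNS]


# ---------------------------------------------------------------------------
# BED annotation tracks
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file into 1-based inclusive intervals (chrom, start, end, label)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(np.int64) + 1,  # 0-based half-open -> 1-based inclusive
            "end": df[2].astype(np.int64),
            "label": df[3].astype(str) if df.shape[1] > 3 else ".",
        }
    )
    if (out["start"] > out["end"]).any():
        raise ValueError(f"{path}: interval with start > end")
    return out


def write_bed(intervals: pd.DataFrame, path: str | Path) -> Path:
    out = pd.DataFrame(
        {
            "chrom": intervals["chrom"],
            "start": intervals["start"].astype(np.int64) - 1,
            "end": intervals["end"].astype(np.int64),
            "label": intervals.get("label", "."),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Alignment evidence (BLAST outfmt 6 / PAF)
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = [
    "query_chrom",
    "query_start",
    "query_end",
    "subject_chrom",
    "subject_start",
    "subject_end",
    "identity",
    "query_coverage",
]


def _parse_region(name: str) -> tuple[str, int, int]:
    """Parse a region name of the form 'chrom:start-end' (1-based inclusive)."""
    try:
        chrom, rng = name.rsplit(":", 1)
        start, end = rng.split("-")
        return chrom, int(start.replace(",", "")), int(end.replace(",", ""))
    except ValueError as exc:
        raise ValueError(
            f"query name {name!r} is not of the form chrom:start-end"
        ) from exc


def _finish_alignment(df: pd.DataFrame) -> pd.DataFrame:
    bad = df[(df["identity"] < 0) | (df["identity"] > 100)]
    if len(bad):
        raise ValueError("alignment identity outside [0,100]")
    df = df.copy()
    for col in ("query_chrom", "subject_chrom"):
        df[col] = df[col].astype(str)
    for col in ("query_start", "query_end", "subject_start", "subject_end"):
        df[col] = df[col].astype(np.int64)
    df["identity"] = df["identity"].astype(float)
    df["query_coverage"] = df["query_coverage"].astype(float).clip(upper=100.0)
    return df[ALIGNMENT_COLUMNS].reset_index(drop=True)


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read BLAST tabular (outfmt 6) hits whose query names encode regions.

    Queries must be named ``chrom:start-end`` (the manifest written by the
    trans-QC module uses this convention); query coverage is the aligned
    query length over the region length, in percent.
    """
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    regions = [_parse_region(q) for q in df["qseqid"]]
    qchrom = [r[0] for r in regions]
    qstart = np.array([r[1] for r in regions], dtype=np.int64)
    qend = np.array([r[2] for r in regions], dtype=np.int64)
    qlen = qend - qstart + 1
    sstart = np.minimum(df["sstart"], df["send"]).to_numpy()
    send = np.maximum(df["sstart"], df["send"]).to_numpy()
    out = pd.DataFrame(
        {
            "query_chrom": qchrom,
            "query_start": qstart + np.minimum(df["qstart"], df["qend"]).to_numpy() - 1,
            "query_end": qstart + np.maximum(df["qstart"], df["qend"]).to_numpy() - 1,
            "subject_chrom": df["sseqid"].astype(str),
            "subject_start": sstart,
            "subject_end": send,
            "identity": df["pident"].astype(float),
            "query_coverage": 100.0 * (np.abs(df["qend"] - df["qstart"]) + 1) / qlen,
        }
    )
    return _finish_alignment(out)


def read_paf(path: str | Path) -> pd.DataFrame:
    """Read PAF alignments; identity = matches/alignment-length in percent."""
    rows = []
    with _open_text(Path(path)) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: PAF line with fewer than 12 fields")
            qchrom, qs, qe = _parse_region(f[0])
            qlen, qstart, qend = int(f[1]), int(f[2]), int(f[3])
            rows.append(
                {
                    "query_chrom": qchrom,
                    "query_start": qs + qstart,  # PAF query start is 0-based
                    "query_end": qs + qend - 1,
                    "subject_chrom": f[5],
                    "subject_start": int(f[7]) + 1,
                    "subject_end": int(f[8]),
                    "identity": 100.0 * int(f[9]) / max(int(f[10]), 1),
                    "query_coverage": 100.0 * (qend - qstart) / qlen,
                }
            )
    return _finish_alignment(pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS))


def write_alignment_table(hits: pd.DataFrame, path: str | Path) -> Path:
    hits[ALIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def read_alignment_table(path: str | Path) -> pd.DataFrame:
    return _finish_alignment(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# FASTA window export
# ---------------------------------------------------------------------------

def export_fasta_windows(
    windows: pd.DataFrame, genome_fasta: str | Path, path: str | Path
) -> Path:
    """Write window sequences (chrom, start, end; 1-based inclusive) as FASTA."""
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta))
    path = Path(path)
    with open(path, "w") as out:
        for row in windows.itertuples(index=False):
            seq = genome[row.chrom][row.start - 1 : row.end].seq
            out.write(f">{row.chrom}:{row.start}-{row.end}\n{seq}\n")
    return path
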