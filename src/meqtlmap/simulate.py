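"""Synthetic genotype-methylome generator with a known planted architecture.

The generator emulates the statistical structure of a bull sperm
methylome study: a few hundred diploid individuals, LD-structured
variants with MAF >= 0.03, CpG methylation percentages whose polygenic
heritability averages ~0.26, cis effects within 1 Mb, trans
master-regulator hotspots each driving >= 30 CpGs, per-CpG read depth
with median ~27, age-class shifts, and (optionally) planted
assembly-misplacement artifacts whose CpG clusters are driven by a
distant locus while their reported coordinates stay at a decoy region.

Everything is deterministic under the spec seed, and the full planted
truth (causal pairs, hotspot targets, per-CpG h2, the latent methylation
matrix, synthetic alignment evidence for misassemblies) is returned so
downstream stages can be tested for recovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import compute_grm
from .io import ALIGNMENT_COLUMNS, GenotypeSet

logger = logging.getLogger(__name__)

__all__ = [
    "HotspotSpec",
    "MisassemblySpec",
    "ArchitectureSpec",
    "TruthTable",
    "simulate_genotypes",
    "simulate_methylome",
    "simulate_annotations",
]


@dataclass
class HotspotSpec:
    """A planted trans master regulator: the lead variant is the common
    variant nearest ``pos`` and drives ``n_target_cpgs`` distant CpGs."""

    chrom: str
    pos: int
    n_target_cpgs: int = 40
    effect_mean: float = 5.5  # %meth per allele, as for the strongest real hotspot
    effect_sd: float = 1.0


@dataclass
class MisassemblySpec:
    """A decoy CpG cluster whose true driving locus lies elsewhere.

    The cluster's CpGs are reported at ``decoy_chrom:decoy_start..+span``
    but their methylation is driven by the variant nearest
    ``true_chrom:true_pos``; the matching synthetic alignment hit links
    the decoy region to the true locus.
    """

    decoy_chrom: str
    decoy_start: int
    true_chrom: str
    true_pos: int
    n_cpgs: int = 19
    span: int = 1152
    beta: float = 15.0
    identity: float = 99.74
    coverage: float = 100.0


@dataclass
class ArchitectureSpec:
    """Study conditions for one synthetic dataset.

    Defaults follow the emulated design: 405 bulls, MAF in [0.03, 0.5],
    mean heritability 0.26, median read depth 27 with negative-binomial
    dispersion 0.3, four age classes, cis effects within 1 Mb.
    ``causal_maf_min`` restricts planted causal variants to common
    alleles so that planted effects are well powered at these sample
    sizes.
    """

    n_individuals: int = 405
    n_variants: int = 5000
    n_cpgs: int = 1000
    chrom_layout: tuple = (("1", 50_000_000), ("2", 50_000_000))
    maf_range: tuple = (0.03, 0.5)
    ld_decay: float = 50_000.0  # bp at which latent haplotype r2 halves
    frac_cis_cpgs: float = 0.0
    cis_beta_sd: float = 6.0
    cis_beta_min: float = 0.0
    hotspot_specs: tuple = ()
    misassembly_specs: tuple = ()
    h2_mean: float = 0.26
    h2_sd: float = 0.15
    latent_sd: float = 7.0  # sqrt(sigma_u2 + sigma_e2), %meth
    baseline_range: tuple = (20.0, 80.0)
    age_effect_sd: float = 1.0
    age_class_bounds: tuple = (500, 750, 1000)
    depth_median: int = 27
    depth_dispersion: float = 0.3
    causal_maf_min: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_cis_cpgs <= 1:
            raise ValueError("frac_cis_cpgs must be in [0,1]")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        for h in self.hotspot_specs:
            if h.n_target_cpgs < 1:
                raise ValueError("hotspot n_target_cpgs must be >= 1")


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside a simulated methylome."""

    cis_pairs: pd.DataFrame  # cpg_id, variant_id, beta
    hotspots: list  # dicts: lead_variant, lead_chrom, lead_pos, target_cpg_ids, betas
    h2: np.ndarray  # per-CpG planted heritability
    misassemblies: list  # dicts: cpg_ids, decoy region, true variant, beta
    alignment_hits: pd.DataFrame  # synthetic evidence for the misassemblies
    latent: pd.DataFrame  # bulls x CpGs latent %meth (pre-sampling)
    polygenic: pd.DataFrame  # bulls x CpGs planted polygenic component
    residual: pd.DataFrame  # bulls x CpGs planted residual component
    age_class: np.ndarray


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(spec: ArchitectureSpec) -> GenotypeSet:
    """Hardy-Weinberg dosages with distance-decaying LD.

    Haplotypes are generated from a latent Gaussian AR(1) process along
    each chromosome (correlation ``2^(-d / (2*ld_decay))`` between
    adjacent sites, so the latent r2 halves every ``ld_decay`` bp) and
    thresholded at the drawn allele frequency, which preserves the
    marginal MAF exactly while inducing LD that decays with distance.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = np.array([ln for _, ln in spec.chrom_layout], dtype=float)
    n_per_chrom = np.maximum(
        np.round(spec.n_variants * lengths / lengths.sum()).astype(int), 2
    )
    if (n_per_chrom < 2).any():
        raise ValueError("need at least 2 variants per chromosome")

    vid, chroms, poss, dos, mafs = [], [], [], [], []
    n_hap = 2 * spec.n_individuals
    for (name, length), m in zip(spec.chrom_layout, n_per_chrom):
        pos = np.sort(rng.choice(np.arange(1, int(length)), size=m, replace=False))
        maf = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
        # alternate allele is the minor one half of the time
        p_alt = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)
        rho = np.exp2(-np.diff(pos) / (2.0 * spec.ld_decay)) if spec.ld_decay > 0 else np.zeros(m - 1)
        z = np.empty((n_hap, m))
        z[:, 0] = rng.standard_normal(n_hap)
        eps = rng.standard_normal((n_hap, m - 1))
        for i in range(1, m):
            r = rho[i - 1]
            z[:, i] = r * z[:, i - 1] + np.sqrt(1.0 - r * r) * eps[:, i - 1]
        alleles = (z < stats.norm.ppf(p_alt)).astype(float)
        dosage = alleles[0::2] + alleles[1::2]
        vid.extend(f"{name}:{p}" for p in pos)
        chroms.extend([name] * m)
        poss.append(pos)
        dos.append(dosage)
        mafs.append(np.minimum(p_alt, 1.0 - p_alt))

    return GenotypeSet(
        variant_id=np.array(vid, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.concatenate(poss),
        dosage=np.concatenate(dos, axis=1),
        maf=np.concatenate(mafs),
        individual_ids=[f"bull{i:04d}" for i in range(spec.n_individuals)],
    )


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def _draw_h2(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Per-CpG heritability: moment-matched Beta, or constant when sd=0."""
    if sd <= 0 or mean <= 0 or mean >= 1:
        return np.full(size, float(np.clip(mean, 0.0, 1.0)))
    var = min(sd * sd, 0.95 * mean * (1.0 - mean))
    k = mean * (1.0 - mean) / var - 1.0
    return rng.beta(mean * k, (1.0 - mean) * k, size=size)

def _nb_mean_for_median(target: int, dispersion: float) -> float:
    """Negative-binomial mean whose median is closest to ``target``."""
    r = 1.0 / dispersion
    grid = np.linspace(max(target * 0.5, 1.0), target * 2.5, 400)
    med = np.array([stats.nbinom.ppf(0.5, r, r / (r + mu)) for mu in grid])
    return float(grid[np.argmin(np.abs(med - target) + 1e-9 * grid)])


def _nearest_common_variant(genotypes: GenotypeSet, chrom: str, pos: int, maf_min: float) -> int:
    ok = (genotypes.chrom == chrom) & (genotypes.maf >= maf_min)
    if not ok.any():
        raise ValueError(f"no variant with MAF >= {maf_min} on chromosome {chrom}")
    idx = np.flatnonzero(ok)
    return int(idx[np.argmin(np.abs(genotypes.pos[idx] - pos))])


def _place_cpgs(spec: ArchitectureSpec, genotypes: GenotypeSet, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random CpG coordinates avoiding variant positions, 1-bp adjacency and
    the misassembly decoy windows (those slots are filled separately)."""
    lengths = np.array([ln for _, ln in spec.chrom_layout], dtype=float)
    n_per = np.maximum(np.round(spec.n_cpgs * lengths / lengths.sum()).astype(int), 1)
    taken = {(c, p) for c, p in zip(genotypes.chrom, genotypes.pos)}
    decoys = [
        (ms.decoy_chrom, ms.decoy_start - 2, ms.decoy_start + ms.span + 2)
        for ms in spec.misassembly_specs
    ]
    chroms, poss = [], []
    for (name, length), m in zip(spec.chrom_layout, n_per):
        got: list[int] = []
        while len(got) < m:
            cand = rng.integers(100, int(length) - 100, size=2 * (m - len(got)))
            for p in np.sort(cand):
                p = int(p)
                if (name, p) in taken or (name, p + 1) in taken or (name, p - 1) in taken:
                    continue
                if any(c == name and lo <= p <= hi for c, lo, hi in decoys):
                    continue
                taken.update({(name, p), (name, p + 1), (name, p - 1)})
                got.append(p)
                if len(got) == m:
                    break
        chroms.extend([name] * m)
        poss.extend(sorted(got))
    order = np.lexsort((np.array(poss), np.array(chroms, dtype=object)))
    return (np.array(chroms, dtype=object)[order], np.array(poss, dtype=np.int64)[order])


def simulate_methylome(
    genotypes: GenotypeSet, spec: ArchitectureSpec
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate per-sample CpG counts with the planted architecture.

    The latent %methylation of CpG c is

        baseline_c + sum(cis beta * dosage) + sum(hotspot beta * dosage(lead))
        + u_c + age_shift + e_c,

    with ``u_c ~ N(0, G sigma_u2)`` drawn from the GRM of the simulated
    genotypes so that the planted ``h2 = sigma_u2/(sigma_u2+sigma_e2)``
    is recoverable by REML. Values are clipped to [0, 100] (a warning is
    emitted if clipping touches more than 5% of entries); observed counts
    are binomial at a negative-binomially distributed per-entry depth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = genotypes.n_individuals
    bulls = list(genotypes.individual_ids)

    cpg_chrom, cpg_pos = _place_cpgs(spec, genotypes, rng)

    # planted misassembly clusters replace some of the CpG slots
    mis_records = []
    mis_cpg_idx: dict[int, tuple[int, float]] = {}  # cpg index -> (variant idx, beta)
    hit_rows = []
    next_slot = 0
    for ms in spec.misassembly_specs:
        vi = _nearest_common_variant(genotypes, ms.true_chrom, ms.true_pos, spec.causal_maf_min)
        positions = ms.decoy_start + np.unique(
            np.linspace(0, ms.span - 1, ms.n_cpgs).astype(int)
        )
        slots = np.arange(next_slot, next_slot + len(positions))
        next_slot += len(positions)
        if next_slot > len(cpg_pos):
            raise ValueError("too many misassembly CpGs for n_cpgs")
        cpg_chrom[slots] = ms.decoy_chrom
        cpg_pos[slots] = positions
        for s in slots:
            mis_cpg_idx[int(s)] = (vi, ms.beta)
        mis_records.append(
            {
                "decoy_chrom": ms.decoy_chrom,
                "decoy_start": int(positions[0]),
                "decoy_end": int(positions[-1]),
                "true_variant": genotypes.variant_id[vi],
                "true_chrom": ms.true_chrom,
                "true_pos": int(genotypes.pos[vi]),
                "cpg_slots": slots,
                "beta": ms.beta,
            }
        )
        half = ms.span // 2
        hit_rows.append(
            {
                "query_chrom": ms.decoy_chrom,
                "query_start": int(positions[0]),
                "query_end": int(positions[0]) + ms.span - 1,
                "subject_chrom": ms.true_chrom,
                "subject_start": int(genotypes.pos[vi]) - half,
                "subject_end": int(genotypes.pos[vi]) + half,
                "identity": ms.identity,
                "query_coverage": ms.coverage,
            }
        )
    order = np.lexsort((cpg_pos, cpg_chrom))
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    cpg_chrom, cpg_pos = cpg_chrom[order], cpg_pos[order]
    mis_cpg_idx = {int(inv[i]): v for i, v in mis_cpg_idx.items()}
    for rec in mis_records:
        rec["cpg_slots"] = np.sort(inv[rec["cpg_slots"]])
    cpg_ids = np.array([f"{c}:{p}" for c, p in zip(cpg_chrom, cpg_pos)], dtype=object)
    n_cpgs = len(cpg_ids)

    # hotspots: lead variants and distant target CpGs
    free = np.ones(n_cpgs, dtype=bool)
    for idx in mis_cpg_idx:
        free[idx] = False
    hot_records = []
    for hs in spec.hotspot_specs:
        vi = _nearest_common_variant(genotypes, hs.chrom, hs.pos, spec.causal_maf_min)
        lead_chrom, lead_pos = genotypes.chrom[vi], int(genotypes.pos[vi])
        distant = free & (
            (cpg_chrom != lead_chrom) | (np.abs(cpg_pos - lead_pos) > 20_000_000)
        )
        cand = np.flatnonzero(distant)
        if len(cand) < hs.n_target_cpgs:
            raise ValueError("not enough distant CpGs for hotspot targets")
        targets = np.sort(rng.choice(cand, size=hs.n_target_cpgs, replace=False))
        free[targets] = False
        betas = hs.effect_mean + hs.effect_sd * rng.standard_normal(hs.n_target_cpgs)
        hot_records.append(
            {
                "lead_variant": genotypes.variant_id[vi],
                "lead_idx": vi,
                "lead_chrom": lead_chrom,
                "lead_pos": lead_pos,
                "target_cpg_ids": cpg_ids[targets],
                "target_idx": targets,
                "betas": betas,
            }
        )

    # cis pairs on a fraction of the remaining CpGs
    cis_rows = []
    n_cis = int(round(spec.frac_cis_cpgs * n_cpgs))
    cis_candidates = np.flatnonzero(free)
    rng.shuffle(cis_candidates)
    for ci in cis_candidates:
        if len(cis_rows) >= n_cis:
            break
        near = (
            (genotypes.chrom == cpg_chrom[ci])
            & (np.abs(genotypes.pos - cpg_pos[ci]) <= 1_000_000)
            & (genotypes.maf >= spec.causal_maf_min)
        )
        near_idx = np.flatnonzero(near)
        if not len(near_idx):
            continue
        vi = int(rng.choice(near_idx))
        beta = rng.standard_normal() * spec.cis_beta_sd
        if spec.cis_beta_min > 0:
            beta = np.sign(beta or 1.0) * (spec.cis_beta_min + abs(rng.standard_normal())
                                           * spec.cis_beta_sd)
        cis_rows.append({"cpg_id": cpg_ids[ci], "cpg_idx": ci,
                         "variant_id": genotypes.variant_id[vi], "variant_idx": vi,
                         "beta": float(beta)})

    # latent methylation
    h2 = _draw_h2(rng, spec.h2_mean, spec.h2_sd, n_cpgs)
    sigma_tot2 = spec.latent_sd**2
    grm = compute_grm(genotypes)
    chol = np.linalg.cholesky(grm.matrix + 1e-6 * np.eye(n))
    baseline = rng.uniform(*spec.baseline_range, size=n_cpgs)
    age_class = rng.integers(0, 4, size=n)
    age_shift = rng.standard_normal((4, n_cpgs)) * spec.age_effect_sd

    latent = np.empty((n, n_cpgs))
    u = np.sqrt(h2 * sigma_tot2)[None, :] * (chol @ rng.standard_normal((n, n_cpgs)))
    e = np.sqrt((1.0 - h2) * sigma_tot2)[None, :] * rng.standard_normal((n, n_cpgs))
    latent[:] = baseline[None, :] + u + e + age_shift[age_class, :]
    for row in cis_rows:
        latent[:, row["cpg_idx"]] += row["beta"] * genotypes.dosage[:, row["variant_idx"]]
    for rec in hot_records:
        latent[:, rec["target_idx"]] += np.outer(
            genotypes.dosage[:, rec["lead_idx"]], rec["betas"]
        )
    for ci, (vi, beta) in mis_cpg_idx.items():
        latent[:, ci] += beta * genotypes.dosage[:, vi]

    clipped = ((latent < 0) | (latent > 100)).mean()
    if clipped > 0.05:
        warnings.warn(
            f"simulate_methylome: {clipped:.1%} of latent values clipped to [0,100]",
            stacklevel=2,
        )
    latent = np.clip(latent, 0.0, 100.0)

    # observed counts: NB depth, binomial methylated reads
    r = 1.0 / spec.depth_dispersion
    mu = _nb_mean_for_median(spec.depth_median, spec.depth_dispersion)
    depth = rng.negative_binomial(r, r / (r + mu), size=(n, n_cpgs))
    meth = rng.binomial(depth, latent / 100.0)

    bull_rep = np.repeat(np.arange(n), n_cpgs)
    cpg_rep = np.tile(np.arange(n_cpgs), n)
    d_flat, m_flat = depth.ravel(), meth.ravel()
    keep = d_flat > 0
    samples = pd.DataFrame(
        {
            "chrom": cpg_chrom[cpg_rep[keep]],
            "pos": cpg_pos[cpg_rep[keep]],
            "count_meth": m_flat[keep],
            "count_unmeth": d_flat[keep] - m_flat[keep],
            "sample_id": np.array([f"{bulls[i]}_s1" for i in range(n)], dtype=object)[
                bull_rep[keep]
            ],
        }
    )

    bin_edges = spec.age_class_bounds
    lo = np.array([300, bin_edges[0], bin_edges[1] + 1, bin_edges[2] + 1])
    hi = np.array([bin_edges[0] - 1, bin_edges[1], bin_edges[2], 1600])
    ages = rng.integers(lo[age_class], hi[age_class] + 1)
    meta = pd.DataFrame(
        {
            "sample_id": [f"{b}_s1" for b in bulls],
            "bull_id": bulls,
            "age_days": ages,
            "tissue": "sperm",
        }
    )

    truth = TruthTable(
        cis_pairs=pd.DataFrame(
            cis_rows, columns=["cpg_id", "cpg_idx", "variant_id", "variant_idx", "beta"]
        ),
        hotspots=hot_records,
        h2=h2,
        misassemblies=[
            {**rec, "cpg_ids": cpg_ids[rec["cpg_slots"]]} for rec in mis_records
        ],
        alignment_hits=pd.DataFrame(hit_rows, columns=ALIGNMENT_COLUMNS),
        latent=pd.DataFrame(latent, index=bulls, columns=cpg_ids),
        polygenic=pd.DataFrame(u, index=bulls, columns=cpg_ids),
        residual=pd.DataFrame(e, index=bulls, columns=cpg_ids),
        age_class=age_class,
    )
    _check_truth(truth, genotypes, set(cpg_ids))
    return samples, meta, truth


def _check_truth(truth: TruthTable, genotypes: GenotypeSet, cpg_ids: set) -> None:
    vids = set(genotypes.variant_id)
    for _, row in truth.cis_pairs.iterrows():
        if row["variant_id"] not in vids or row["cpg_id"] not in cpg_ids:
            raise AssertionError("truth table references unknown id")
    for rec in truth.hotspots:
        if rec["lead_variant"] not in vids:
            raise AssertionError("truth table references unknown lead variant")


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

def simulate_annotations(
    spec: ArchitectureSpec,
    planted_or: float,
    target_positions: pd.DataFrame,
    enriched_label: tuple[str, str] = ("cgi_landscape", "CGI"),
    background_coverage: float = 0.2,
    interval_size: int = 500,
):
    """Interval tracks in which ``target_positions`` overlap one label at
    ``planted_or``-fold the background odds.

    Background intervals of the enriched label are placed away from the
    targets to give genome coverage ``background_coverage``; each target
    is then covered with probability p such that odds(p) = planted_or x
    odds(background_coverage). Other labels are placed at random. Returns
    a dict of :class:`~meqtlmap.enrichment.AnnotationTrack` by category.
    """
    from .enrichment import AnnotationTrack, DEFAULT_TRACK_SCHEMES

    if planted_or <= 0:
        raise ValueError("planted_or must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    chrom_len = dict(spec.chrom_layout)
    for row in target_positions.itertuples(index=False):
        if row.chrom not in chrom_len or not (1 <= row.pos <= chrom_len[row.chrom]):
            raise ValueError(f"target position {row.chrom}:{row.pos} outside chromosomes")

    q = background_coverage
    odds = planted_or * q / (1.0 - q)
    p_target = odds / (1.0 + odds)

    target_by_chrom = {
        c: np.sort(g["pos"].to_numpy()) for c, g in target_positions.groupby("chrom")
    }

    def random_intervals(label: str, avoid_targets: bool) -> list[tuple]:
        rows = []
        for chrom, length in spec.chrom_layout:
            n_iv = int(q * length / interval_size)
            starts = rng.integers(1, length - interval_size, size=n_iv)
            tp = target_by_chrom.get(chrom, np.array([], dtype=int))
            for s in starts:
                if avoid_targets and len(tp):
                    j = np.searchsorted(tp, s - interval_size)
                    if j < len(tp) and tp[j] <= s + 2 * interval_size:
                        continue
                rows.append((chrom, int(s), int(s) + interval_size - 1, label))
        return rows

    tracks: dict[str, "AnnotationTrack"] = {}
    for category, (labels, fallback) in DEFAULT_TRACK_SCHEMES.items():
        rows = []
        for label in labels:
            planted_here = (category, label) == enriched_label
            rows.extend(random_intervals(label, avoid_targets=planted_here))
            if planted_here and len(target_positions):
                covered = rng.random(len(target_positions)) < p_target
                for hit, row in zip(covered, target_positions.itertuples(index=False)):
                    if hit:
                        half = interval_size // 2
                        rows.append(
                            (row.chrom, max(1, row.pos - half), row.pos + half, label)
                        )
        tracks[category] = AnnotationTrack(
            category=category,
            intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]),
            priority_order=list(labels),
            fallback=fallback,
        )
    return tracks
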