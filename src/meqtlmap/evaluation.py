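"""Monte-Carlo validation experiments on the synthetic generator.

These experiments exercise the full pipeline on datasets with a known
planted architecture and measure how well each stage recovers it:

* :func:`null_fpr_experiment` — does the permutation-derived cis
  threshold attain its nominal per-CpG false-positive rate on held-out
  null CpGs?
* :func:`heritability_recovery_experiment` — does per-CpG REML recover
  the planted mean heritability?
* :func:`planted_recovery_experiment` — are planted cis pairs, trans
  hotspots and assembly artifacts recovered/removed by the scan, the
  hotspot finder and the trans-QC stage?
* :func:`maf_rare_allele_copies` — the rare-allele copy count guaranteed
  by a MAF threshold at a given sample size.

Every experiment consumes one integer seed and is deterministic.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .association import CLASS_CIS, CLASS_TRANS, MlmaScanner
from .calibration import derive_thresholds
from .genetics import RemlSolver, compute_grm, ld_r2
from .hotspots import find_hotspots
from .preprocess import aggregate_bull, correct_for_age, select_variable_cpgs
from .simulate import (
    ArchitectureSpec,
    HotspotSpec,
    MisassemblySpec,
    simulate_genotypes,
    simulate_methylome,
)
from .transqc import apply_alignment_filter, detect_suspicious_pairs, exclude_longrange_cis

logger = logging.getLogger(__name__)

__all__ = [
    "maf_rare_allele_copies",
    "null_fpr_experiment",
    "heritability_recovery_experiment",
    "planted_recovery_experiment",
]


def maf_rare_allele_copies(n_individuals: int = 405, maf_min: float = 0.03) -> int:
    """Minimum rare-allele copies implied by a MAF floor.

    A diploid sample of n individuals carries 2n alleles; MAF >= maf_min
    forces at least ceil(2n * maf_min) copies of the rarer allele (25
    copies at the 3% threshold with 405 individuals).
    """
    return math.ceil(2 * n_individuals * maf_min)


def _prepare(spec: ArchitectureSpec):
    """Simulate and preprocess one dataset; returns (genotypes, matrix,
    grm, truth) with the observed (count-sampled) methylation matrix."""
    genotypes = simulate_genotypes(spec)
    samples, meta, truth = simulate_methylome(genotypes, spec)
    matrix = aggregate_bull(samples, meta, min_depth=10)
    variant_positions = {(c, int(p)) for c, p in zip(genotypes.chrom, genotypes.pos)}
    matrix = select_variable_cpgs(matrix, variant_positions)
    matrix = correct_for_age(matrix, meta)
    return genotypes, matrix, compute_grm(genotypes), truth


def null_fpr_experiment(
    seed: int,
    n_individuals: int = 200,
    n_variants: int = 5000,
    n_cpgs: int = 1000,
    n_calibration: int = 500,
    n_heldout: int = 500,
    fpr: float = 0.05,
    n_perm: int = 10,
    cpg_fraction: float = 0.10,
) -> dict:
    """Empirical FPR of the permutation-calibrated cis threshold.

    Simulates null methylation (polygenic + noise, no planted meQTL),
    derives the cis threshold from ``n_calibration`` CpGs via the
    permutation procedure, and counts how many of ``n_heldout`` held-out
    null CpGs have their minimum cis-window adjusted p below it.
    """
    spec = ArchitectureSpec(
        n_individuals=n_individuals, n_variants=n_variants, n_cpgs=n_cpgs, seed=seed
    )
    genotypes, matrix, grm, _ = _prepare(spec)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    order = rng.permutation(matrix.n_cpgs)
    calib_idx = np.sort(order[:n_calibration])
    held_idx = np.sort(order[n_calibration : n_calibration + n_heldout])

    calib = matrix.subset_cpgs(np.isin(np.arange(matrix.n_cpgs), calib_idx))
    thresholds = derive_thresholds(
        calib, genotypes, grm, fpr=fpr, n_perm=n_perm, cpg_fraction=cpg_fraction,
        seed=seed,
    )

    scanner = MlmaScanner(genotypes, grm)
    n_sig = 0
    n_eval = 0
    for j in held_idx:
        j = int(j)
        mc, _, _ = scanner.scan_minima(
            matrix.values[:, j], matrix.chrom[j], int(matrix.pos[j])
        )
        if np.isfinite(mc):
            n_eval += 1
            n_sig += mc < thresholds.cis_p
    return {
        "fpr_pct": 100.0 * n_sig / n_eval,
        "fpr_target_pct": 100.0 * fpr,
        "cis_threshold": thresholds.cis_p,
        "trans_threshold": thresholds.trans_p,
        "n_heldout": n_eval,
        "n_significant": n_sig,
    }


def heritability_recovery_experiment(
    seed: int,
    n_individuals: int = 400,
    n_variants: int = 2000,
    n_cpgs: int = 500,
    h2_mean: float = 0.26,
) -> dict:
    """Mean REML heritability across CpGs with planted mean ``h2_mean``.

    Estimation runs on the latent methylation scale (the generator's
    truth table), where the planted polygenic/residual decomposition is
    defined; read-count sampling would attenuate observed-scale
    estimates by the binomial measurement variance.
    """
    spec = ArchitectureSpec(
        n_individuals=n_individuals, n_variants=n_variants, n_cpgs=n_cpgs,
        h2_mean=h2_mean, seed=seed,
    )
    genotypes = simulate_genotypes(spec)
    _, _, truth = simulate_methylome(genotypes, spec)
    grm = compute_grm(genotypes)
    solver = RemlSolver(grm)
    latent = truth.latent.to_numpy()
    est = np.array([solver.fit(latent[:, j]).h2 for j in range(latent.shape[1])])
    return {
        "mean_h2_estimated": float(est.mean()),
        "mean_h2_planted": float(np.mean(truth.h2)),
        "h2_target": h2_mean,
        "n_cpgs": int(latent.shape[1]),
    }


def planted_recovery_experiment(
    seed: int,
    n_individuals: int = 400,
    n_variants: int = 2500,
    n_cpgs: int = 300,
    n_perm: int = 10,
    cis_beta_min: float = 8.0,
) -> dict:
    """End-to-end recovery of a planted cis/hotspot/misassembly architecture.

    Reports the fraction of planted cis pairs (|beta| >= ``cis_beta_min``)
    whose causal variant is significant at the permutation-calibrated
    cis threshold, the fraction of planted hotspots recovered with the
    true lead or an r2 > 0.8 proxy, the fraction of planted-misassembly
    trans pairs removed by trans-QC, and the retention of genuine
    (hotspot-target) trans pairs.
    """
    spec = ArchitectureSpec(
        n_individuals=n_individuals,
        n_variants=n_variants,
        n_cpgs=n_cpgs,
        frac_cis_cpgs=0.3,
        cis_beta_sd=2.0,
        cis_beta_min=cis_beta_min,
        hotspot_specs=(
            HotspotSpec(chrom="1", pos=10_000_000, n_target_cpgs=40, effect_mean=6.0,
                        effect_sd=0.5),
            HotspotSpec(chrom="2", pos=35_000_000, n_target_cpgs=40, effect_mean=6.0,
                        effect_sd=0.5),
        ),
        misassembly_specs=(
            MisassemblySpec(decoy_chrom="1", decoy_start=40_000_000,
                            true_chrom="2", true_pos=10_000_000),
        ),
        seed=seed,
    )
    genotypes, matrix, grm, truth = _prepare(spec)
    thresholds = derive_thresholds(
        matrix, genotypes, grm, n_perm=n_perm, seed=seed
    )
    scanner = MlmaScanner(genotypes, grm)
    cpg_index = {c: j for j, c in enumerate(matrix.cpg_ids)}

    import pandas as pd

    sig_frames = []
    for j in range(matrix.n_cpgs):
        rec, _ = scanner.scan(
            matrix.values[:, j], matrix.cpg_ids[j], matrix.chrom[j], int(matrix.pos[j])
        )
        keep = ((rec["class"] == CLASS_CIS) & (rec["p_adj"] < thresholds.cis_p)) | (
            (rec["class"] == CLASS_TRANS) & (rec["p_adj"] < thresholds.trans_p)
        )
        if keep.any():
            sig_frames.append(rec[keep])
    records = pd.concat(sig_frames, ignore_index=True)

    # --- planted cis detection -------------------------------------------
    cis_pairs = truth.cis_pairs[truth.cis_pairs["beta"].abs() >= cis_beta_min]
    sig_cis = set(
        zip(records.loc[records["class"] == CLASS_CIS, "cpg_id"],
            records.loc[records["class"] == CLASS_CIS, "variant_id"])
    )
    detected = [
        (row.cpg_id, row.variant_id) in sig_cis and row.cpg_id in cpg_index
        for row in cis_pairs.itertuples(index=False)
    ]
    cis_rate = float(np.mean(detected)) if detected else float("nan")

    # --- trans QC ---------------------------------------------------------
    records = exclude_longrange_cis(records)
    pairs = detect_suspicious_pairs(records, matrix, genotypes)
    records, pairs = apply_alignment_filter(records, pairs, truth.alignment_hits)

    mis = truth.misassemblies[0]
    mis_cpgs = set(mis["cpg_ids"])
    near_true = set(
        genotypes.variant_id[
            (genotypes.chrom == mis["true_chrom"])
            & (np.abs(genotypes.pos - mis["true_pos"]) <= 2_000_000)
        ]
    )
    mis_records = records[
        records["cpg_id"].isin(mis_cpgs) & records["variant_id"].isin(near_true)
    ]
    n_mis = len(mis_records)
    mis_removed = (
        float((mis_records["class"] == "spurious_excluded").mean()) if n_mis else float("nan")
    )

    genuine = []
    for hs in truth.hotspots:
        lead = hs["lead_variant"]
        sub = records[(records["variant_id"] == lead)
                      & records["cpg_id"].isin(set(hs["target_cpg_ids"]))]
        genuine.append(sub)
    genuine = pd.concat(genuine, ignore_index=True)
    trans_retained = float((genuine["class"] == CLASS_TRANS).mean())

    # --- hotspot recovery -------------------------------------------------
    found = find_hotspots(records, genotypes, min_cpgs=30)
    vidx = {v: j for j, v in enumerate(genotypes.variant_id)}
    recovered = 0
    for hs in truth.hotspots:
        true_dos = genotypes.dosage[:, vidx[hs["lead_variant"]]]
        for f in found:
            if f.lead_variant == hs["lead_variant"] or ld_r2(
                genotypes.dosage[:, vidx[f.lead_variant]], true_dos
            ) > 0.8:
                recovered += 1
                break
    return {
        "cis_detection_rate": cis_rate,
        "n_cis_pairs": int(len(cis_pairs)),
        "hotspot_recovery_rate": recovered / len(truth.hotspots),
        "misassembly_removed_rate": mis_removed,
        "n_misassembly_pairs": n_mis,
        "genuine_trans_retention": trans_retained,
        "n_genuine_trans_pairs": int(len(genuine)),
        "cis_threshold": thresholds.cis_p,
        "trans_threshold": thresholds.trans_p,
        "n_hotspots_found": len(found),
    }
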