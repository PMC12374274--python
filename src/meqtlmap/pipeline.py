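"""End-to-end orchestration: simulate -> preprocess -> heritability ->
calibrate -> scan -> trans-QC -> hotspots (-> enrichment), with one
config object, deterministic seeding and a manifest of every parameter.

The stage parameters default to the emulated study's values: depth
floor 10 reads, presence >= 80%, s.d. > 5%, MAF >= 3%, cis within 1 Mb,
buffer to 2 Mb, long-range cis to 20 Mb, 5% empirical FPR from 10
permutations at a 10% CpG fraction, hotspots at >= 30 trans-CpGs with
LD r2 > 0.8, 1,000 resampling replicates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import CLASS_CIS, CLASS_TRANS, MlmaScanner, top_snp
from .calibration import derive_thresholds
from .enrichment import collapse_independent, fisher_enrichment, assign_labels
from .genetics import compute_grm
from .hotspots import count_independent_trans, find_hotspots, hotspot_table
from .io import (
    read_genotypes,
    read_methylation_tables,
    read_sample_meta,
    write_association_table,
    write_alignment_table,
    write_dosage_table,
    write_sample_meta,
    read_alignment_table,
)
from .preprocess import aggregate_bull, correct_for_age, select_variable_cpgs
from .simulate import (
    ArchitectureSpec,
    HotspotSpec,
    MisassemblySpec,
    simulate_annotations,
    simulate_genotypes,
    simulate_methylome,
)
from .transqc import (
    apply_alignment_filter,
    detect_suspicious_pairs,
    exclude_longrange_cis,
    review_report,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_run"]


@dataclass
class PipelineConfig:
    """All stage parameters with the study defaults (see module docstring)."""

    # synthetic dataset
    n_individuals: int = 200
    n_variants: int = 2000
    n_cpgs: int = 300
    chrom_lengths: tuple = (50_000_000, 50_000_000)
    frac_cis_cpgs: float = 0.0
    cis_beta_sd: float = 6.0
    n_hotspots: int = 0
    hotspot_n_targets: int = 40
    hotspot_effect_mean: float = 5.5
    n_misassemblies: int = 0
    h2_mean: float = 0.26
    seed: int = 0
    # preprocessing
    min_depth: int = 10
    min_presence: float = 0.8
    sd_min: float = 5.0
    maf_min: float = 0.03
    # association / classification
    cis_window: int = 1_000_000
    buffer_window: int = 2_000_000
    longrange_max: int = 20_000_000
    # calibration
    fpr: float = 0.05
    n_perm: int = 10
    cpg_fraction: float = 0.10
    # hotspots
    min_cpgs_hotspot: int = 30
    ld_r2: float = 0.8
    # enrichment
    n_rep: int = 1000
    h2_enrich_threshold: float = 0.1
    # stage toggles
    run_enrichment: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "chrom_lengths" in d:
            d["chrom_lengths"] = tuple(d["chrom_lengths"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_architecture_spec(self) -> ArchitectureSpec:
        layout = tuple(
            (str(i + 1), ln) for i, ln in enumerate(self.chrom_lengths)
        )
        rng = np.random.default_rng(self.seed)
        hotspots = tuple(
            HotspotSpec(
                chrom=layout[i % len(layout)][0],
                pos=int(rng.integers(5_000_000, layout[i % len(layout)][1] - 5_000_000)),
                n_target_cpgs=self.hotspot_n_targets,
                effect_mean=self.hotspot_effect_mean,
            )
            for i in range(self.n_hotspots)
        )
        mis = tuple(
            MisassemblySpec(
                decoy_chrom=layout[0][0],
                decoy_start=int(rng.integers(2_000_000, layout[0][1] - 2_000_000)),
                true_chrom=layout[-1][0],
                true_pos=int(rng.integers(2_000_000, layout[-1][1] - 2_000_000)),
            )
            for _ in range(self.n_misassemblies)
        )
        return ArchitectureSpec(
            n_individuals=self.n_individuals,
            n_variants=self.n_variants,
            n_cpgs=self.n_cpgs,
            chrom_layout=layout,
            frac_cis_cpgs=self.frac_cis_cpgs,
            cis_beta_sd=self.cis_beta_sd,
            hotspot_specs=hotspots,
            misassembly_specs=mis,
            h2_mean=self.h2_mean,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages into ``out_dir``; returns the run directory.

    Every output is a text table or JSON; the manifest records the
    package version, all parameters and the checksum of every file, so
    re-running an identical config reproduces identical checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        spec = config.to_architecture_spec()
        genotypes = simulate_genotypes(spec)
        samples, meta, truth = simulate_methylome(genotypes, spec)
        write_dosage_table(genotypes, out / "genotypes.tsv")
        samples.to_csv(out / "methylation_samples.tsv", sep="\t", index=False)
        write_sample_meta(meta, out / "sample_meta.tsv")
        write_alignment_table(truth.alignment_hits, out / "alignment_hits.tsv")
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "cis_pairs": truth.cis_pairs[["cpg_id", "variant_id", "beta"]]
                    .to_dict("records"),
                    "hotspot_leads": [h["lead_variant"] for h in truth.hotspots],
                    "h2_mean_planted": float(np.mean(truth.h2)),
                    "misassemblies": [
                        {
                            "decoy": f"{m['decoy_chrom']}:{m['decoy_start']}-{m['decoy_end']}",
                            "true_variant": m["true_variant"],
                        }
                        for m in truth.misassemblies
                    ],
                },
                indent=1,
            )
        )

        stage = "preprocess"
        genotypes = read_genotypes(out / "genotypes.tsv", maf_min=config.maf_min)
        samples = read_methylation_tables([out / "methylation_samples.tsv"])
        meta = read_sample_meta(out / "sample_meta.tsv")
        matrix = aggregate_bull(samples, meta, min_depth=config.min_depth)
        variant_positions = {(c, int(p)) for c, p in zip(genotypes.chrom, genotypes.pos)}
        matrix = select_variable_cpgs(
            matrix, variant_positions, min_presence=config.min_presence,
            sd_min=config.sd_min,
        )
        matrix = correct_for_age(matrix, meta)
        matrix.write(out / "methylation_matrix.tsv")

        stage = "heritability"
        grm = compute_grm(genotypes)
        scanner = MlmaScanner(genotypes, grm)
        vcs = [scanner.null_model(matrix.values[:, j]) for j in range(matrix.n_cpgs)]
        pd.DataFrame(
            {
                "cpg_id": matrix.cpg_ids,
                "sigma_u2": [v.sigma_u2 for v in vcs],
                "sigma_e2": [v.sigma_e2 for v in vcs],
                "h2": [v.h2 for v in vcs],
                "converged": [v.converged for v in vcs],
            }
        ).to_csv(out / "heritability.tsv", sep="\t", index=False)

        stage = "calibrate"
        thresholds = derive_thresholds(
            matrix, genotypes, grm, fpr=config.fpr, n_perm=config.n_perm,
            cpg_fraction=config.cpg_fraction, seed=config.seed,
            cis_window=config.cis_window, buffer_window=config.buffer_window,
        )
        thresholds.to_json(out / "thresholds.json")

        stage = "scan"
        sig_frames, summaries = [], []
        for j in range(matrix.n_cpgs):
            rec, summ = scanner.scan(
                matrix.values[:, j], matrix.cpg_ids[j], matrix.chrom[j],
                int(matrix.pos[j]), null_vc=vcs[j],
            )
            keep = ((rec["class"] == CLASS_CIS) & (rec["p_adj"] < thresholds.cis_p)) | (
                (rec["class"] == CLASS_TRANS) & (rec["p_adj"] < thresholds.trans_p)
            )
            if keep.any():
                sig_frames.append(rec[keep])
            summaries.append(summ.__dict__)
        from .io import ASSOCIATION_COLUMNS

        records = (
            pd.concat(sig_frames, ignore_index=True)
            if sig_frames
            else pd.DataFrame(columns=ASSOCIATION_COLUMNS)
        )
        pd.DataFrame(summaries).to_csv(out / "scan_summaries.tsv", sep="\t", index=False)

        stage = "trans_qc"
        records = exclude_longrange_cis(
            records, buffer_window=config.buffer_window,
            longrange_max=config.longrange_max,
        )
        pairs = detect_suspicious_pairs(records, matrix, genotypes)
        hits = read_alignment_table(out / "alignment_hits.tsv")
        records, pairs = apply_alignment_filter(records, pairs, hits)
        write_association_table(records, out / "associations.tsv")
        review_report(pairs).to_csv(out / "suspicious_pairs.tsv", sep="\t", index=False)

        stage = "hotspots"
        hotspots = find_hotspots(
            records, genotypes, min_cpgs=config.min_cpgs_hotspot,
            ld_r2_threshold=config.ld_r2,
        )
        for h in hotspots:
            h.n_independent = count_independent_trans(h, matrix)
        hotspot_table(hotspots).to_csv(out / "hotspots.tsv", sep="\t", index=False)

        if config.run_enrichment:
            stage = "enrichment"
            reps, _ = collapse_independent(matrix)
            tracks = simulate_annotations(
                spec, planted_or=1.0,
                target_positions=pd.DataFrame({"chrom": matrix.chrom, "pos": matrix.pos}),
            )
            h2_by_cpg = pd.Series([v.h2 for v in vcs], index=matrix.cpg_ids)
            heritable = {c for c in reps if h2_by_cpg[c] > config.h2_enrich_threshold}
            coords = pd.DataFrame(
                {"chrom": matrix.chrom, "pos": matrix.pos}, index=matrix.cpg_ids
            )
            if heritable:
                fisher = fisher_enrichment(
                    heritable, set(reps),
                    assign_labels(coords, tracks["cgi_landscape"]),
                )
                fisher.to_csv(out / "enrichment_heritable.tsv", sep="\t", index=False)

        stage = "summary"
        _write_summary(out, config, matrix, vcs, thresholds, records, hotspots)
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "parameters": dataclasses.asdict(config),
            "files": {
                p.name: _sha256(p) for p in sorted(out.glob("*")) if p.is_file()
                and p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _write_summary(out, config, matrix, vcs, thresholds, records, hotspots) -> None:
    sig = records[records["class"].isin([CLASS_CIS, CLASS_TRANS])]
    cis_cpgs = set(sig.loc[sig["class"] == CLASS_CIS, "cpg_id"])
    trans_cpgs = set(sig.loc[sig["class"] == CLASS_TRANS, "cpg_id"])
    n = matrix.n_cpgs
    top_dist = []
    for c in cis_cpgs:
        rec = top_snp(records[records["cpg_id"] == c], CLASS_CIS, p_max=thresholds.cis_p)
        if rec is not None and np.isfinite(rec["distance"]):
            top_dist.append(abs(rec["distance"]))
    summary = {
        "n_cpgs_analyzed": n,
        "pct_cis_only": 100.0 * len(cis_cpgs - trans_cpgs) / n,
        "pct_trans_only": 100.0 * len(trans_cpgs - cis_cpgs) / n,
        "pct_both": 100.0 * len(cis_cpgs & trans_cpgs) / n,
        "mean_h2": float(np.mean([v.h2 for v in vcs])),
        "cis_threshold": thresholds.cis_p,
        "trans_threshold": thresholds.trans_p,
        "mean_abs_top_cis_distance_bp": float(np.mean(top_dist)) if top_dist else None,
        "n_hotspots": len(hotspots),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))


REQUIRED_OUTPUTS = {
    "preprocess": "methylation_matrix.tsv",
    "heritability": "heritability.tsv",
    "calibrate": "thresholds.json",
    "scan+qc": "associations.tsv",
    "hotspots": "hotspots.tsv",
    "summary": "summary.json",
}


def summarize_run(run_dir: str | Path) -> dict:
    """Summary report of a completed run directory.

    Raises with the list of missing stages when the run is incomplete.
    """
    run_dir = Path(run_dir)
    missing = [s for s, f in REQUIRED_OUTPUTS.items() if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing stages: {missing}")
    report = json.loads((run_dir / "summary.json").read_text())
    report["hotspots"] = pd.read_csv(run_dir / "hotspots.tsv", sep="\t").to_dict("records")
    return report
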