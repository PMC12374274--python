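"""Simulate a genotype-methylome dataset with a known planted architecture.

Generates 150 bulls x 1,000 LD-structured variants x 200 CpGs with 20%
of CpGs carrying a cis effect and one trans hotspot, then prints what
was planted. The truth table is what downstream examples test recovery
against.
"""

import numpy as np

from meqtlmap import ArchitectureSpec, HotspotSpec, simulate_genotypes, simulate_methylome

spec = ArchitectureSpec(
    n_individuals=150,
    n_variants=1000,
    n_cpgs=200,
    frac_cis_cpgs=0.2,
    hotspot_specs=(HotspotSpec(chrom="1", pos=25_000_000, n_target_cpgs=35),),
    seed=42,
)
genotypes = simulate_genotypes(spec)
samples, meta, truth = simulate_methylome(genotypes, spec)

depth = samples["count_meth"] + samples["count_unmeth"]
print(f"variants: {genotypes.n_variants}, MAF in "
      f"[{genotypes.maf.min():.3f}, {genotypes.maf.max():.3f}]")
print(f"per-sample CpG records: {len(samples)}, median read depth: {depth.median():.0f}")
print(f"planted cis pairs: {len(truth.cis_pairs)} "
      f"(|beta| mean {truth.cis_pairs['beta'].abs().mean():.1f} %meth/allele)")
hs = truth.hotspots[0]
print(f"planted hotspot lead: {hs['lead_variant']} driving {len(hs['target_cpg_ids'])} "
      f"distant CpGs (mean effect {np.mean(hs['betas']):.1f} %meth/allele)")
print(f"planted mean heritability: {truth.h2.mean():.3f}")
# The median depth sits near 27 reads and planted h2 near 0.26 — the
# statistical regime the generator is built to emulate.
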