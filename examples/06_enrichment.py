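"""Annotation assignment and matched-background enrichment.

Simulates annotation tracks in which a target set of positions overlaps
CpG islands at twice the background odds, then recovers that odds ratio
with the 1,000-replicate resampling procedure (and shows a null set for
contrast).
"""

import numpy as np
import pandas as pd

from meqtlmap import ArchitectureSpec, resampled_enrichment, simulate_annotations
from meqtlmap.enrichment import assign_labels

rng = np.random.default_rng(5)
spec = ArchitectureSpec(n_individuals=10, n_variants=100, n_cpgs=10, seed=5)

# a pool of genomic positions; the first 600 are the "interest" set
pool_pos = pd.DataFrame({
    "chrom": rng.choice(["1", "2"], size=6000),
    "pos": rng.integers(10_000, 49_000_000, size=6000),
})
interest_pos = pool_pos.iloc[:600]

tracks = simulate_annotations(
    spec, planted_or=2.0, target_positions=interest_pos,
    enriched_label=("cgi_landscape", "CGI"),
)
labels = assign_labels(pool_pos, tracks["cgi_landscape"])
labels.index = [f"p{i}" for i in range(len(pool_pos))]

pool = pd.DataFrame({"id": labels.index})
interest = pool.iloc[:600]
out = resampled_enrichment(interest, pool, labels, n_rep=1000, seed=1)
row = out.set_index("label").loc["CGI"]
print(f"planted OR = 2.0 -> recovered mean OR {row['or_mean']:.2f} "
      f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}], p = {row['p']:.3g}")

null_interest = pool.sample(600, random_state=2)
null_row = (
    resampled_enrichment(null_interest, pool, labels, n_rep=1000, seed=3)
    .set_index("label").loc["CGI"]
)
print(f"random interest     -> mean OR {null_row['or_mean']:.2f} "
      f"[{null_row['ci_low']:.2f}, {null_row['ci_high']:.2f}], p = {null_row['p']:.3g}")
# The planted 2-fold enrichment is recovered with a CI excluding 1; the
# random subset sits at OR ~ 1 with a CI covering 1.
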