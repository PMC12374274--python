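# Methods

## Statistical model and estimation

Per CpG, methylation percentages across individuals follow
`y = 1μ + xb + u + e` with a genomic random effect `u ~ N(0, G σu²)`
and residual `e ~ N(0, I σe²)`. The GRM uses the per-variant
standardized (GCTA-style) form, `G_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik −
2p_i) / (2 p_i (1 − p_i))`, over variants polymorphic in-sample;
monomorphic variants are skipped.

**REML.** With a single random effect the restricted likelihood is
exact after one spectral decomposition: project onto an orthonormal
basis of the intercept's orthogonal complement, rotate by the
eigenvectors of the projected GRM, and the transformed data are
independent with variances `σ²(h λ_i + 1 − h)` where `h = σu²/σ²`. The
profile likelihood over `h ∈ [0,1]` is minimized by a 21-point grid
followed by bounded scalar refinement (tolerance 1e-8), with boundary
solutions (h = 0 or 1) admitted and reported as converged. A flat GRM
spectrum (e.g. an identity GRM) makes the ratio unidentifiable; such
fits are flagged `converged=False`. Missing phenotypes use case-wise
deletion with matching GRM subsetting; one decomposition is cached per
missingness pattern and reused across CpGs.

**Association scan.** Null-model variance components are estimated
once per CpG and held fixed, so `V = σu² G + σe² I` is known during
the scan. Every dosage column, the intercept and `y` are rotated once
by the eigenvectors of (the subsetted) `G`; each variant then costs
O(n) for the GLS effect `b`, its standard error, and the Wald
`χ² = b²/Var(b)` with p from the 1-df upper tail. When `σu² = 0` the
scan is per-variant least-squares regression with the fixed null
residual variance as error variance (betas identical to OLS; standard
errors use the fixed σe², as implied by the fixed-components scheme).
Constant variants in the analyzed subset are skipped and logged.

**Genomic control.** `λ_gc = median(χ²) / 0.4549…` per scan; all χ²
are divided by λ_gc and p recomputed, unconditionally — also when
λ_gc < 1, a deliberate reading of the adjustment rule since the source
procedure does not state an exception.

**Classification.** Same chromosome and |variant − CpG| ≤ 1 Mb is cis;
different chromosome or > 2 Mb is trans; the 1–2 Mb band is a buffer
excluded from both. Intrachromosomal trans records at 2–20 Mb whose
CpG also has a significant cis record are relabelled long-range cis
(extended LD); a strict mode drops the whole 2–20 Mb stratum — both
readings of the exclusion rule are exposed because the narrative and
the procedural descriptions of it differ.

## Permutation calibration

Per permutation, genotype rows are reassigned to individuals uniformly
at random while the GRM stays the original one: structure correction
is preserved, the genotype–phenotype link is broken. A fresh random
10% of CpGs is scanned per permutation (10 permutations by default);
per CpG the minimum adjusted p within ±1 Mb (cis) and the genome-wide
minimum outside the cis/buffer window (trans) are kept. Thresholds are
the 5% quantile of the minima pooled across permutations — the
standard min-p construction, chosen because the aggregation across
permutations is otherwise underdetermined; all minima are retained in
the output for audit. Null variance components are cached across
permutations (they depend only on y and the unpermuted GRM).

## Preprocessing

Methylation percentage is `100·C/(C+T)` per CpG and sample; per-sample
entries under 10 reads are dropped before aggregation; per bull the
value is the depth-weighted mean across samples. CpG filters, in
order: presence in ≥ 80% of bulls, removal of CpGs at known variant
positions, population s.d. strictly > 5% (a CpG at exactly 5 is
removed; the population estimator was fixed by choice — at these
sample sizes the n vs n−1 distinction cannot move a CpG across the
threshold by more than ~0.3%, and the convention is documented).
Age correction subtracts each age-class mean and restores the grand
mean per CpG, using four classes (< 500 d; [500, 750]; (750, 1000];
> 1000 d, with exactly these boundary conventions); this is equivalent
to a fixed age-class factor for a single balanced factor and was
chosen over regression residualization as the simpler interpretation
of "corrected for age by class". Classes with fewer than two bulls
merge into the nearest populated class. Both-strand coverage rows at
positions p and p+1 are summed onto the forward-strand C.

## Trans-QC

Suspicious region pairs are nominated from significant trans records
by single-linkage clustering of CpG positions (gap ≤ 10 kb) and of
their partner variant positions (gap ≤ 1 Mb); a pair is emitted when
one variant region captures ≥ 80% of a CpG cluster's trans records and
involves ≥ 10 CpGs. The gap and exclusivity parameters are
operational choices (the motivating observation was qualitative:
tightly clustered CpGs almost exclusively associated with one distant
region) and are configurable. Confirmation is external: the package
emits a BED query manifest (query names `chrom:start-end`) and
consumes BLAST tabular or PAF alignments; a pending pair becomes a
confirmed artifact when a hit maps its CpG cluster into or within 1 Mb
of its variant region at ≥ 98% identity and ≥ 90% query coverage, and
its trans records are relabelled `spurious_excluded`. Pairs without
qualifying evidence stay in a review report — deliberately not
auto-discarded, since one such real case turned out to be a genuine
structural variant found only by pangenome analysis. Record counts
are conserved through all relabelling.

## Enrichment

Positions resolve to exactly one label per annotation category via a
priority order with a fallback (intergenic / open_sea / no_TE /
no_peak). Adjacent CpGs correlating above R = 0.5 chain into clusters
represented by their middle CpG (lower middle for even sizes — the tie
rule had to be fixed by choice). Fisher enrichment compares an
interest set against its full universe per label (so interest =
universe gives OR exactly 1), two-sided exact p, Haldane 0.5
correction for zero cells in the OR only, Benjamini–Hochberg across
all labels jointly (the adjustment method was unnamed in the source
procedure; BH is reported alongside raw p). Resampled enrichment
draws, per replicate, a background of the interest set's size without
replacement from a pool, stratified to match the interest's MAF class
histogram ([0.03, 0.05), [0.05, 0.1), [0.1, 0.2), [0.2, 0.5]) and
optionally the joint MAF × signed-distance histogram (seven cis bins
from −1 Mb to +1 Mb) exactly; 1,000 replicates give the mean OR, the
percentile 95% CI, and an empirical two-sided p floored at 1/n_rep
(the significance rule is an interpretation; the source marked stars
without defining the test).

## Hotspots

A hotspot is a variant with ≥ 30 (inclusive) associated trans-CpGs;
selection is greedy — the best candidate becomes a lead, variants with
LD r² > 0.8 inside ±2 Mb define its interval (min..max position of the
retained variants), variants inside a claimed interval leave the
candidate pool — so intervals are pairwise disjoint. Per hotspot:
percent of trans-CpGs whose lead-effect sign opposes the majority
(zeros count with the majority, even splits resolve positive), and the
independent trans-CpG count from chaining genomically adjacent
trans-CpGs at methylation r² ≥ 0.25. Motif-scanning export builds
100-bp windows centred on CpGs, merging runs of CpGs < 100 bp apart
into one window from 50 bp before the first to 50 bp after the last;
sets with ≤ 20 windows are flagged not-retained. Cross-tissue
concordance regresses per-CpG methylation on lead dosage in each
tissue over shared individuals and reports the correlation and
sign-agreement of the two effect vectors plus genotype-stratified
means; hotspots sharing < 50% of their trans-CpGs (or < 3) are
skipped. The quantitative concordance statistics replace what was
originally a visual judgement; no hard shared/not-shared cutoff is
built in.

## Synthetic data generator

The generator emulates the statistical regime of a bull sperm RRBS
study: defaults of 405 diploid individuals, MAF uniform on
[0.03, 0.5], mean planted heritability 0.26 (Beta-distributed, s.d.
0.15), read depth negative-binomial with median 27 and dispersion 0.3
(no floor — the depth filter is exercised downstream), four uniform
age classes with N(0, 1 %meth) class shifts, and a latent total
genetic-plus-residual s.d. of 7 %meth (so simulated CpGs clear the
5% variability filter even before measurement noise; the value is a
modelling choice, not an emulated statistic). Haplotypes come from a
latent Gaussian AR(1) thresholded at the drawn allele frequency —
marginals are exact and LD decays with distance, with the half-distance
nominal on the latent scale. The polygenic term is drawn per CpG from
N(0, G σu²) using the GRM of the simulated genotypes, which makes REML
recovery well-posed. Methylation is simulated on the linear %meth
scale and clipped to [0, 100] (clipping beyond 5% of entries warns);
observed counts are binomial at the simulated depth. Planted causal
variants (cis and hotspot leads) are restricted to MAF ≥ 0.15: the
recovery guarantees this package is tested against (strong cis effects
detected at ~90%+, hotspots recovered fully at n = 400) presuppose
well-powered common-variant effects, and rare-variant power is not the
generator's subject. Misassembly artifacts plant a tight decoy CpG
cluster (19 CpGs over 1,152 bp by default) whose methylation is driven
by a distant locus, together with the matching synthetic alignment hit
(99.74% identity) that the trans-QC stage consumes.

What the generator does **not** emulate: realistic recombination maps
or haplotype block structure, sequence context (CpG density, MspI
fragment bias of RRBS), bisulfite conversion error, batch effects, or
shared environmental covariance between relatives. Passing tests
therefore demonstrate the correctness and calibration of the
statistical machinery under the stated generative model, not
robustness to every artifact of real RRBS data.

## Validation scale and numerical choices

Heritability recovery is evaluated on the latent methylation scale
(the truth table exposes the latent matrix): binomial read sampling at
depth ~27 adds ~`p(1−p)/depth·10⁴` %²-units of measurement variance,
which mechanically attenuates observed-scale h² below the latent
target — an attenuation real designs counter with depth filtering and
replicate averaging rather than something estimation should undo.
The calibration experiment uses 200 individuals × 5,000 variants ×
1,000 null CpGs (500 calibration / 500 held-out); planted-architecture
recovery uses 400 individuals × 2,500 variants × 300 CpGs — sizes at
which the Monte-Carlo error of the checked rates is a small fraction
of their tolerances. Numerical details: eigendecompositions are
symmetrized and eigenvalues floored at 0 (PSD tolerance −1e-8);
quantiles use linear interpolation; per-permutation seeds derive from
the master seed via `SeedSequence.spawn`; scan ties in top-SNP
selection break by smaller |distance|, then lower genomic position.

## Known limitations

- Multi-component and dominance models are out of scope; one genomic
  variance component only.
- The scan holds null variance components fixed (no per-variant
  re-estimation and no leave-one-chromosome-out GRM), so effect sizes
  at variants in strong LD with large polygenic contributors can be
  slightly conservative.
- Fisher enrichment against an overlapping universe follows the
  field's convention but is not a strictly independent 2×2 design.
- Window export truncates at position 1 but has no chromosome-length
  registry, so right-edge truncation is the caller's responsibility.
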