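import numpy as np
import pandas as pd
import pytest

from meqtlmap.simulate import (
    ArchitectureSpec,
    HotspotSpec,
    MisassemblySpec,
    simulate_annotations,
    simulate_genotypes,
    simulate_methylome,
)


def test_genotypes_deterministic_under_seed():
    spec = ArchitectureSpec(n_individuals=50, n_variants=200, seed=5)
    a = simulate_genotypes(spec)
    b = simulate_genotypes(spec)
    np.testing.assert_array_equal(a.dosage, b.dosage)
    np.testing.assert_array_equal(a.pos, b.pos)


def test_methylome_deterministic_under_seed():
    spec = ArchitectureSpec(n_individuals=40, n_variants=150, n_cpgs=30, seed=6)
    g = simulate_genotypes(spec)
    s1, m1, t1 = simulate_methylome(g, spec)
    s2, m2, t2 = simulate_methylome(g, spec)
    pd.testing.assert_frame_equal(s1, s2)
    pd.testing.assert_frame_equal(m1, m2)
    pd.testing.assert_frame_equal(t1.latent, t2.latent)


def test_degenerate_maf_range():
    spec = ArchitectureSpec(
        n_individuals=30, n_variants=50, maf_range=(0.5, 0.5), seed=1
    )
    assert (simulate_genotypes(spec).maf == 0.5).all()


def test_no_ld_limit_matches_independence():
    # with ld_decay -> 0, adjacent-variant r2 has the independence
    # expectation E[r2] = 1/n
    n = 200
    spec = ArchitectureSpec(n_individuals=n, n_variants=400, ld_decay=0.0, seed=2)
    g = simulate_genotypes(spec)
    r2 = []
    for j in range(g.n_variants - 1):
        if g.chrom[j] != g.chrom[j + 1]:
            continue
        a, b = g.dosage[:, j], g.dosage[:, j + 1]
        if a.std() == 0 or b.std() == 0:
            continue
        r2.append(np.corrcoef(a, b)[0, 1] ** 2)
    assert np.mean(r2) == pytest.approx(1.0 / n, abs=2.5 / n)


def test_ld_decays_with_distance():
    spec = ArchitectureSpec(n_individuals=200, n_variants=400, ld_decay=200_000, seed=2)
    g = simulate_genotypes(spec)
    r2, dist = [], []
    for j in range(g.n_variants - 1):
        if g.chrom[j] != g.chrom[j + 1]:
            continue
        a, b = g.dosage[:, j], g.dosage[:, j + 1]
        if a.std() == 0 or b.std() == 0:
            continue
        r2.append(np.corrcoef(a, b)[0, 1] ** 2)
        dist.append(g.pos[j + 1] - g.pos[j])
    r2, dist = np.array(r2), np.array(dist)
    near = r2[dist < 100_000].mean()
    far = r2[dist > 400_000].mean()
    assert near > 3 * far  # strong decay
    assert near > 0.2


def test_zero_signal_leaves_binomial_sampling_variance_only():
    spec = ArchitectureSpec(
        n_individuals=120, n_variants=100, n_cpgs=60, h2_mean=0.0, h2_sd=0.0,
        latent_sd=0.0, age_effect_sd=0.0, seed=3,
    )
    g = simulate_genotypes(spec)
    samples, meta, truth = simulate_methylome(g, spec)
    samples["depth"] = samples["count_meth"] + samples["count_unmeth"]
    samples["pct"] = 100 * samples["count_meth"] / samples["depth"]
    obs = samples.groupby(["chrom", "pos"])["pct"].var(ddof=1)
    # binomial variance of the percentage at depth d: p(1-p)/d * 100^2
    p = truth.latent.iloc[0].to_numpy() / 100.0  # constant per CpG across bulls
    lat = pd.Series(p, index=truth.latent.columns)
    expected = []
    for (chrom, pos), grp in samples.groupby(["chrom", "pos"]):
        pc = lat[f"{chrom}:{pos}"]
        expected.append((100**2 * pc * (1 - pc) / grp["depth"]).mean())
    ratio = obs.to_numpy() / np.array(expected)
    assert np.mean(ratio) == pytest.approx(1.0, abs=0.15)


def test_planted_cis_effect_shifts_genotype_groups(small_dataset):
    spec, genotypes, samples, meta, truth = small_dataset
    latent = truth.latent.to_numpy()
    slopes, betas = [], []
    for row in truth.cis_pairs.itertuples(index=False):
        y = latent[:, int(row.cpg_idx)]
        x = genotypes.dosage[:, int(row.variant_idx)]
        slopes.append(np.polyfit(x, y, 1)[0])
        betas.append(row.beta)
    np.testing.assert_allclose(slopes, betas, atol=2.5)
    assert np.corrcoef(slopes, betas)[0, 1] > 0.95


def test_realized_h2_matches_spec_mean():
    spec = ArchitectureSpec(n_individuals=150, n_variants=300, n_cpgs=500, seed=4)
    g = simulate_genotypes(spec)
    _, _, truth = simulate_methylome(g, spec)
    u = truth.polygenic.to_numpy()
    e = truth.residual.to_numpy()
    realized = u.var(axis=0) / (u.var(axis=0) + e.var(axis=0))
    assert realized.mean() == pytest.approx(spec.h2_mean, abs=0.03)


def test_depth_median_near_target():
    spec = ArchitectureSpec(n_individuals=100, n_variants=100, n_cpgs=100, seed=5)
    g = simulate_genotypes(spec)
    samples, _, _ = simulate_methylome(g, spec)
    depth = samples["count_meth"] + samples["count_unmeth"]
    assert abs(np.median(depth) - spec.depth_median) <= 2


def test_misassembly_cluster_and_alignment_evidence():
    spec = ArchitectureSpec(
        n_individuals=80, n_variants=300, n_cpgs=60, seed=6,
        misassembly_specs=(
            MisassemblySpec(decoy_chrom="1", decoy_start=30_000_000,
                            true_chrom="2", true_pos=20_000_000),
        ),
    )
    g = simulate_genotypes(spec)
    _, _, truth = simulate_methylome(g, spec)
    mis = truth.misassemblies[0]
    assert len(mis["cpg_ids"]) == 19
    assert mis["decoy_end"] - mis["decoy_start"] <= 1152
    hit = truth.alignment_hits.iloc[0]
    assert hit["identity"] == pytest.approx(99.74)
    assert hit["query_chrom"] == "1" and hit["subject_chrom"] == "2"
    # driving variant is at the distant true locus
    assert mis["true_chrom"] == "2"


def test_hotspot_targets_are_distant(small_dataset):
    spec = ArchitectureSpec(
        n_individuals=60, n_variants=200, n_cpgs=80, seed=7,
        hotspot_specs=(HotspotSpec(chrom="1", pos=25_000_000, n_target_cpgs=30),),
    )
    g = simulate_genotypes(spec)
    _, _, truth = simulate_methylome(g, spec)
    hs = truth.hotspots[0]
    assert len(hs["target_cpg_ids"]) == 30
    for cpg in hs["target_cpg_ids"]:
        chrom, pos = cpg.split(":")
        assert chrom != hs["lead_chrom"] or abs(int(pos) - hs["lead_pos"]) > 20_000_000


def test_annotations_null_and_bounds():
    spec = ArchitectureSpec(n_individuals=10, n_variants=50, n_cpgs=10, seed=8)
    targets = pd.DataFrame({"chrom": ["1"] * 5, "pos": [10**6 * k for k in range(1, 6)]})
    tracks = simulate_annotations(spec, planted_or=1.0, target_positions=targets)
    assert set(tracks) == {"genomic_feature", "cgi_landscape", "te", "atac"}
    with pytest.raises(ValueError, match="outside"):
        simulate_annotations(
            spec, 1.0, pd.DataFrame({"chrom": ["1"], "pos": [10**9]})
        )
    with pytest.raises(ValueError, match="planted_or"):
        simulate_annotations(spec, 0.0, targets)


def test_empty_target_set_gives_background_tracks():
    spec = ArchitectureSpec(n_individuals=10, n_variants=50, n_cpgs=10, seed=9)
    tracks = simulate_annotations(
        spec, 2.0, pd.DataFrame({"chrom": [], "pos": []})
    )
    assert len(tracks["cgi_landscape"].intervals) > 0
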