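import numpy as np
import pandas as pd
import pytest

from meqtlmap.association import CLASS_TRANS
from meqtlmap.hotspots import (
    Hotspot,
    count_independent_trans,
    cross_tissue_concordance,
    direction_summary,
    find_hotspots,
    hotspot_table,
    tfbs_windows,
)
from meqtlmap.io import GenotypeSet
from meqtlmap.preprocess import MethylationMatrix


def _gset(dosage, pos, chrom=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    p = dosage.mean(axis=0) / 2
    return GenotypeSet(
        variant_id=np.array([f"v{i}" for i in range(m)], dtype=object),
        chrom=np.array(chrom or ["1"] * m, dtype=object),
        pos=np.asarray(pos),
        dosage=dosage,
        maf=np.minimum(p, 1 - p),
        individual_ids=[f"b{i}" for i in range(n)],
    )


def _trans_records(variant_id, cpg_ids, betas=None):
    betas = betas if betas is not None else np.ones(len(cpg_ids))
    return pd.DataFrame(
        {
            "cpg_id": cpg_ids, "variant_id": variant_id, "beta": betas,
            "se": 0.1, "chi2": 40.0, "p_raw": 1e-10, "p_adj": 1e-10,
            "distance": np.nan, "class": CLASS_TRANS,
        }
    )


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

@pytest.fixture()
def ld_block_genotypes(rng):
    """Lead variant v1 with proxies v0/v2 in perfect LD; v3 independent."""
    n = 50
    lead = rng.binomial(2, 0.4, size=n).astype(float)
    other = rng.binomial(2, 0.3, size=n).astype(float)
    dosage = np.column_stack([lead, lead, lead, other])
    return _gset(dosage, pos=[1_000_000, 1_050_000, 1_100_000, 40_000_000])


def test_hotspot_interval_spans_ld_block(ld_block_genotypes):
    cpgs = [f"2:{i * 1000}" for i in range(35)]
    records = _trans_records("v1", cpgs)
    found = find_hotspots(records, ld_block_genotypes, min_cpgs=30)
    assert len(found) == 1
    hs = found[0]
    assert hs.lead_variant == "v1"
    assert (hs.interval_start, hs.interval_end) == (1_000_000, 1_100_000)
    assert hs.n_trans == 35


def test_min_cpgs_is_inclusive_threshold(ld_block_genotypes):
    records = _trans_records("v1", [f"2:{i}" for i in range(29)])
    assert find_hotspots(records, ld_block_genotypes, min_cpgs=30) == []
    records = _trans_records("v1", [f"2:{i}" for i in range(30)])
    assert len(find_hotspots(records, ld_block_genotypes, min_cpgs=30)) == 1


def test_two_hotspots_disjoint_and_greedy(ld_block_genotypes):
    records = pd.concat(
        [
            _trans_records("v1", [f"2:{i}" for i in range(40)]),
            _trans_records("v3", [f"3:{i}" for i in range(32)]),
        ],
        ignore_index=True,
    )
    found = find_hotspots(records, ld_block_genotypes, min_cpgs=30)
    assert [h.lead_variant for h in found] == ["v1", "v3"]
    a, b = found
    assert a.interval_end < b.interval_start or b.interval_end < a.interval_start
    table = hotspot_table(found)
    assert list(table["n_trans_cpgs"]) == [40, 32]


def test_claimed_interval_removes_proxies_from_candidacy(ld_block_genotypes):
    # v0 (perfect proxy of v1) also has >30 CpGs but sits inside v1's interval
    records = pd.concat(
        [
            _trans_records("v1", [f"2:{i}" for i in range(40)]),
            _trans_records("v0", [f"2:{i}" for i in range(35)]),
        ],
        ignore_index=True,
    )
    found = find_hotspots(records, ld_block_genotypes, min_cpgs=30)
    assert [h.lead_variant for h in found] == ["v1"]


# ---------------------------------------------------------------------------
# direction and independence summaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "betas, expected",
    [
        ([1, 1, 1, -1], 25.0),
        ([2, 2, 2], 0.0),
        ([1, 1, -1, -1], 50.0),
        ([1, 1, 0, -1], 25.0),  # zero counted with (positive) majority
        ([], 0.0),
    ],
)
def test_direction_summary(betas, expected):
    assert direction_summary(np.array(betas, dtype=float)) == pytest.approx(expected)


def _matrix(values, pos):
    values = np.asarray(values, dtype=float)
    return MethylationMatrix(
        bull_ids=[f"b{i}" for i in range(values.shape[0])],
        cpg_ids=np.array([f"1:{p}" for p in pos], dtype=object),
        chrom=np.array(["1"] * len(pos), dtype=object),
        pos=np.asarray(pos),
        values=values,
        depth_weights=np.full_like(values, 20.0),
    )


def test_count_independent_trans(rng):
    n = 40
    latent = rng.standard_normal(n)
    a = 50 + 10 * latent
    b = 50 + 10 * latent + 8 * rng.standard_normal(n)  # r ~ 0.6..0.8
    c = 50 + 10 * rng.standard_normal(n)
    mat = _matrix(np.column_stack([a, b, c]), [100, 200, 300])
    r_ab = np.corrcoef(a, b)[0, 1]
    assert r_ab**2 >= 0.25  # linked pair by construction
    hs = Hotspot(
        hotspot_id="H1", lead_variant="v0", lead_chrom="9", lead_pos=500,
        interval_start=400, interval_end=600,
        trans_cpg_ids=["1:100", "1:200", "1:300"], betas=np.ones(3),
    )
    assert count_independent_trans(hs, mat) == 2
    # all-independent limit
    mat2 = _matrix(rng.standard_normal((n, 3)) * 5 + 50, [100, 200, 300])
    assert count_independent_trans(hs, mat2) == 3


# ---------------------------------------------------------------------------
# TFBS windows
# ---------------------------------------------------------------------------

def test_single_cpg_window_is_100bp():
    ws = tfbs_windows(pd.DataFrame({"chrom": ["1"], "pos": [1000]}), min_sequences=1)
    w = ws.windows.iloc[0]
    assert (w["start"], w["end"]) == (950, 1049)
    assert w["end"] - w["start"] + 1 == 100


def test_close_cpgs_merge_into_one_window():
    ws = tfbs_windows(
        pd.DataFrame({"chrom": ["1", "1"], "pos": [1000, 1060]}), min_sequences=1
    )
    assert len(ws.windows) == 1
    w = ws.windows.iloc[0]
    assert (w["start"], w["end"]) == (950, 1109)  # 50 bp before first to 50 after last


def test_windows_disjoint_and_cover_all_cpgs(rng):
    pos = np.sort(rng.choice(np.arange(100, 100_000), size=60, replace=False))
    ws = tfbs_windows(pd.DataFrame({"chrom": "1", "pos": pos}), min_sequences=1)
    w = ws.windows
    assert (w["start"].to_numpy()[1:] > w["end"].to_numpy()[:-1]).all()
    for p in pos:
        assert ((w["start"] <= p) & (p <= w["end"])).any()


def test_below_min_sequences_flagged():
    pos = np.arange(15) * 10_000 + 1000
    ws = tfbs_windows(pd.DataFrame({"chrom": "1", "pos": pos}))
    assert ws.n_sequences == 15 and not ws.retained


def test_window_truncated_at_chromosome_start():
    ws = tfbs_windows(pd.DataFrame({"chrom": ["1"], "pos": [20]}), min_sequences=1)
    assert ws.windows.iloc[0]["start"] == 1


# ---------------------------------------------------------------------------
# cross-tissue concordance
# ---------------------------------------------------------------------------

def _concordance_fixture(rng, n=60):
    lead = rng.binomial(2, 0.4, size=n).astype(float)
    gset = _gset(lead[:, None], pos=[5_000_000], chrom=["9"])
    cpg_pos = [1000, 40_000, 90_000, 150_000]
    sperm_vals = np.column_stack(
        [40 + 6 * lead + 2 * rng.standard_normal(n) for _ in cpg_pos]
    )
    mat = _matrix(sperm_vals, cpg_pos)
    hs = Hotspot(
        hotspot_id="H1", lead_variant="v0", lead_chrom="9", lead_pos=5_000_000,
        interval_start=4_999_000, interval_end=5_001_000,
        trans_cpg_ids=list(mat.cpg_ids), betas=np.full(4, 6.0),
    )
    return gset, mat, hs


def test_identical_tissues_perfectly_concordant(rng):
    gset, mat, hs = _concordance_fixture(rng)
    res = cross_tissue_concordance(hs, mat, mat, gset)
    assert not res.skipped
    assert res.shared_fraction == 1.0
    assert res.effect_correlation == pytest.approx(1.0)
    assert res.sign_agreement == 1.0
    assert set(res.stratified_means["tissue"]) == {"sperm", "other"}


def test_low_sharing_skipped(rng):
    gset, mat, hs = _concordance_fixture(rng)
    other = mat.subset_cpgs(np.array([True, False, False, False]))
    res = cross_tissue_concordance(hs, mat, other, gset, min_shared=0.5)
    assert res.skipped and res.shared_fraction == pytest.approx(0.25)


def test_genotype_independent_tissue_uncorrelated(rng):
    gset, mat, hs = _concordance_fixture(rng)
    corrs = []
    for _ in range(100):
        other_vals = 40 + 5 * rng.standard_normal(mat.values.shape)
        other = _matrix(np.clip(other_vals, 0, 100), list(mat.pos))
        res = cross_tissue_concordance(hs, mat, other, gset)
        corrs.append(abs(res.effect_correlation))
    assert np.mean(corrs) < 0.7  # no systematic concordance (4 CpGs only)
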