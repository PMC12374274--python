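import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meqtlmap.association import (
    CLASS_BUFFER,
    CLASS_CIS,
    CLASS_TRANS,
    CHI2_NULL_MEDIAN,
    MlmaScanner,
    classify_pair,
    genomic_control,
    top_snp,
)
from meqtlmap.genetics import GRM, VarianceComponents, compute_grm
from meqtlmap.io import ASSOCIATION_COLUMNS, GenotypeSet


def _gset(dosage):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    p = dosage.mean(axis=0) / 2
    return GenotypeSet(
        variant_id=np.array([f"v{i}" for i in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=(np.arange(m) + 1) * 10_000,
        dosage=dosage,
        maf=np.minimum(p, 1 - p),
        individual_ids=[f"b{i}" for i in range(n)],
    )


@pytest.fixture(scope="module")
def fixture_50x20():
    rng = np.random.default_rng(42)
    dosage = rng.integers(0, 3, size=(50, 20)).astype(float)
    return _gset(dosage)


def test_scan_with_zero_polygenic_equals_fixed_variance_regression(fixture_50x20):
    """With sigma_u2 = 0 the mixed-model scan reduces to per-variant
    least-squares regression with known error variance (oracle loop)."""
    rng = np.random.default_rng(7)
    y = rng.standard_normal(50) * 3 + 10
    sigma_e2 = 2.5
    vc = VarianceComponents(0.0, sigma_e2, 0.0, 0.0, True)
    grm = GRM(np.eye(50), fixture_50x20.individual_ids)
    beta, se, chi2, tested, _ = MlmaScanner(fixture_50x20, grm).scan_arrays(y, vc)
    for j in range(20):
        x = fixture_50x20.dosage[:, j]
        X = np.column_stack([np.ones(50), x])
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        cov = sigma_e2 * np.linalg.inv(X.T @ X)
        assert beta[j] == pytest.approx(coef[1], abs=1e-8)
        assert se[j] == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-8)
        # the OLS point estimate itself is identical
        assert beta[j] == pytest.approx(np.polyfit(x, y, 1)[0], abs=1e-8)


def test_scan_invariant_to_phenotype_shift(fixture_50x20):
    rng = np.random.default_rng(8)
    y = rng.standard_normal(50)
    grm = compute_grm(fixture_50x20)
    scanner = MlmaScanner(fixture_50x20, grm)
    vc = scanner.null_model(y)
    _, _, chi2_a, _, _ = scanner.scan_arrays(y, vc)
    _, _, chi2_b, _, _ = scanner.scan_arrays(y + 1234.5, vc)
    np.testing.assert_allclose(chi2_a, chi2_b, atol=1e-7)


def test_constant_variant_skipped(fixture_50x20):
    dosage = fixture_50x20.dosage.copy()
    dosage[:, 5] = 1.0
    gset = _gset(dosage)
    grm = GRM(np.eye(50), gset.individual_ids)
    vc = VarianceComponents(0.0, 1.0, 0.0, 0.0, True)
    y = np.random.default_rng(0).standard_normal(50)
    _, _, _, tested, _ = MlmaScanner(gset, grm).scan_arrays(y, vc)
    assert not tested[5] and tested.sum() == 19


def test_planted_effect_attains_minimum_p(small_dataset):
    """The planted cis variant of a strong-effect CpG wins its scan."""
    spec, genotypes, samples, meta, truth = small_dataset
    grm = compute_grm(genotypes)
    scanner = MlmaScanner(genotypes, grm)
    latent = truth.latent.to_numpy()
    row = truth.cis_pairs.iloc[truth.cis_pairs["beta"].abs().idxmax()]
    j = int(row["cpg_idx"])
    rec, _ = scanner.scan(latent[:, j], row["cpg_id"], "1", 1)
    best = rec.loc[rec["p_adj"].idxmin(), "variant_id"]
    # winner is the planted variant or a near-perfect LD proxy
    vidx = {v: k for k, v in enumerate(genotypes.variant_id)}
    r = np.corrcoef(
        genotypes.dosage[:, vidx[best]], genotypes.dosage[:, int(row["variant_idx"])]
    )[0, 1]
    assert r * r > 0.8


def test_null_scan_p_values_uniform():
    """Independent variants, permuted phenotype: raw p uniform (KS test)."""
    rng = np.random.default_rng(9)
    n, m = 200, 5000
    dosage = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    keep = dosage.std(axis=0) > 0
    gset = _gset(dosage[:, keep.nonzero()[0][:4000]])
    grm = GRM(np.eye(n), gset.individual_ids)
    y = rng.standard_normal(n)
    vc = VarianceComponents(0.0, 1.0, 0.0, 0.0, True)
    _, _, chi2, tested, _ = MlmaScanner(gset, grm).scan_arrays(y, vc)
    p = stats.chi2.sf(chi2[tested], 1)
    assert stats.kstest(p, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# genomic control
# ---------------------------------------------------------------------------

def _records_from_chi2(chi2):
    chi2 = np.asarray(chi2, dtype=float)
    return pd.DataFrame(
        {
            "cpg_id": "c",
            "variant_id": [f"v{i}" for i in range(len(chi2))],
            "beta": 1.0,
            "se": 1.0,
            "chi2": chi2,
            "p_raw": stats.chi2.sf(chi2, 1),
            "p_adj": np.nan,
            "distance": 0.0,
            "class": CLASS_CIS,
        }
    )


def test_lambda_one_when_chi2_at_null_median():
    rec, lam = genomic_control(_records_from_chi2(np.full(200, CHI2_NULL_MEDIAN)))
    assert lam == pytest.approx(1.0)
    np.testing.assert_allclose(rec["p_adj"], rec["p_raw"], atol=1e-12)


def test_lambda_two_when_chi2_doubled():
    rng = np.random.default_rng(1)
    chi2 = stats.chi2.rvs(1, size=10001, random_state=rng)
    chi2 = chi2 * (CHI2_NULL_MEDIAN / np.median(chi2))  # exact null median
    rec, lam = genomic_control(_records_from_chi2(2 * chi2))
    assert lam == pytest.approx(2.0)
    assert np.median(rec["chi2"]) == pytest.approx(CHI2_NULL_MEDIAN)


def test_single_record_warns_and_empty_errors(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        _, lam = genomic_control(_records_from_chi2([1.0]))
    assert lam == pytest.approx(1.0 / CHI2_NULL_MEDIAN)
    assert any("unstable" in r.message for r in caplog.records)
    with pytest.raises(ValueError, match="empty"):
        genomic_control(_records_from_chi2([]))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cpg, variant, expected",
    [
        (("5", 10_000_000), ("5", 10_800_000), CLASS_CIS),
        (("5", 10_000_000), ("7", 10_800_000), CLASS_TRANS),
        (("5", 10_000_000), ("5", 11_500_000), CLASS_BUFFER),
        (("5", 10_000_000), ("5", 13_000_000), CLASS_TRANS),
        (("5", 10_000_000), ("5", 11_000_000), CLASS_CIS),  # exactly 1 Mb
        (("5", 10_000_000), ("5", 12_000_000), CLASS_BUFFER),  # exactly 2 Mb
    ],
)
def test_classify_pair(cpg, variant, expected):
    assert classify_pair(cpg, variant) == expected


def test_classification_partitions_distance_grid():
    """Every same-chromosome distance maps to exactly one class."""
    distances = np.concatenate(
        [
            np.arange(0, 3_000_000, 9_999),
            [999_999, 1_000_000, 1_000_001, 1_999_999, 2_000_000, 2_000_001],
            [50_000_000],
        ]
    )
    for d in distances:
        for sign in (1, -1):
            labels = {
                classify_pair(("1", 10_000_000), ("1", 10_000_000 + sign * int(d)))
            }
            assert len(labels) == 1
            assert labels <= {CLASS_CIS, CLASS_BUFFER, CLASS_TRANS}
    assert classify_pair(("1", 1), ("2", 1)) == CLASS_TRANS


# ---------------------------------------------------------------------------
# top SNP
# ---------------------------------------------------------------------------

def test_top_snp_lowest_p_and_ties():
    rec = _records_from_chi2([10.0, 30.0, 20.0])
    rec["p_adj"] = [1e-6, 1e-8, 1e-7]
    assert top_snp(rec, CLASS_CIS)["variant_id"] == "v1"
    # tie on p: smaller |distance| wins
    rec["p_adj"] = [1e-8, 1e-8, 1e-7]
    rec["distance"] = [50_000.0, 5_000.0, 1.0]
    assert top_snp(rec, CLASS_CIS)["variant_id"] == "v1"
    assert top_snp(rec, CLASS_TRANS) is None
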