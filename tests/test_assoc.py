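"""Association stage: HWE exact test, marker/sample QC, the OLS engine
(against statsmodels and a hand-rolled normal-equations oracle), and
genotype-stratified trajectories."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from growthgwas.ages import N_AGES
from growthgwas.assoc import (
    covariate_design, forward_variants, hwe_exact_test, hwe_from_dosages,
    marker_sample_qc, run_assoc, stratified_trajectories,
)
from growthgwas.genotypes import GenotypeData
from growthgwas.phenotypes import PhenotypeMatrix


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def make_geno(dosages, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = (np.array([f"S{i:05d}" for i in range(n)], dtype=object)
           if ids is None else np.asarray(ids, dtype=object))
    with np.errstate(invalid="ignore"):
        eaf = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame({
        "id": [f"v{k}" for k in range(m)],
        "chrom": "1", "pos": np.arange(m) + 1000,
        "ea": "A", "oa": "G", "eaf": eaf, "info": 1.0,
    })
    return GenotypeData(ids, variants, dosages)


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-integer enumeration of the conditional HWE distribution."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if rare == 0:
        return 1.0
    f = factorial
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - hr - h
        probs[h] = Fraction(
            f(n) * 2**h * f(rare) * f(2 * n - rare),
            f(hr) * f(h) * f(hc) * f(2 * n),
        )
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def test_hwe_edge_cases_and_validation():
    assert hwe_exact_test(50, 0, 0) == 1.0     # monomorphic
    assert hwe_exact_test(0, 0, 50) == 1.0
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_symmetric_in_homozygote_labels():
    rng = np.random.default_rng(43)
    for _ in range(50):
        a, h, b = (int(x) for x in rng.integers(0, 40, 3))
        if a + h + b == 0:
            continue
        assert hwe_exact_test(a, h, b) == pytest.approx(
            hwe_exact_test(b, h, a), rel=1e-14
        )


def test_hwe_matches_exact_enumeration_small_n():
    for n in range(1, 26):
        for n_aa in range(n + 1):
            for n_Aa in range(n - n_aa + 1):
                n_AA = n - n_aa - n_Aa
                got = hwe_exact_test(n_AA, n_Aa, n_aa)
                want = hwe_oracle(n_AA, n_Aa, n_aa)
                assert got == pytest.approx(want, rel=1e-12, abs=1e-12), (
                    n_AA, n_Aa, n_aa
                )


def test_hwe_all_heterozygote_is_extreme():
    assert hwe_exact_test(0, 100, 0) < 1e-20


def test_hwe_from_dosages_drops_missing():
    d = np.array([0, 0, 1, 1, 2, 2, np.nan, np.nan])
    assert hwe_from_dosages(d) == pytest.approx(hwe_exact_test(2, 2, 2))


# ---------------------------------------------------------------------------
# marker and sample QC
# ---------------------------------------------------------------------------

def test_marker_sample_qc_removes_the_right_variants_and_samples():
    rng = np.random.default_rng(47)
    n, m = 500, 100
    ds = rng.binomial(2, 0.5, size=(n, m)).astype(float)
    low_call = rng.binomial(2, 0.5, size=n).astype(float)
    low_call[: n // 10] = np.nan               # 90% call rate
    hwe_fail = np.ones(n)                      # everyone heterozygous
    ds = np.column_stack([ds, low_call, hwe_fail])

    ds[1, :5] = np.nan                         # sample 1: 5/102 missing
    ds[2] = 1.0                                # sample 2: heterozygote excess
    g = make_geno(ds)
    kept, rep = marker_sample_qc(g)

    assert rep["variants_removed_call_rate"] == 1
    assert rep["variants_removed_hwe"] == 1
    assert rep["variants_kept"] == m
    assert rep["samples_removed_call_rate"] == 1
    assert rep["samples_removed_het_excess"] == 1
    assert rep["samples_kept"] == n - 2
    assert f"v{m}" not in set(kept.variants["id"])
    assert f"v{m + 1}" not in set(kept.variants["id"])
    assert "S00001" not in set(kept.sample_ids)
    assert "S00002" not in set(kept.sample_ids)


def test_marker_sample_qc_raises_when_nothing_survives():
    g = make_geno(np.ones((50, 2)))            # both variants all-het
    with pytest.raises(ValueError):
        marker_sample_qc(g)


# ---------------------------------------------------------------------------
# covariate design
# ---------------------------------------------------------------------------

def test_covariate_design_columns_and_order():
    df = pd.DataFrame({
        "sex": [0, 1, 0, 1],
        "batch": [0, 1, 2, 1],
        "PC1": [0.1, 0.2, 0.3, 0.4],
        "label": ["a", "b", "c", "d"],         # non-numeric: ignored
    })
    X, names = covariate_design(df)
    assert names == ["sex", "batch_1", "batch_2", "PC1"]
    np.testing.assert_array_equal(X[:, 0], [0, 1, 0, 1])
    np.testing.assert_array_equal(X[:, 1], [0, 1, 0, 1])   # batch == 1
    np.testing.assert_array_equal(X[:, 2], [0, 0, 1, 0])   # batch == 2
    np.testing.assert_allclose(X[:, 3], [0.1, 0.2, 0.3, 0.4])


def test_collinear_covariates_raise_with_names():
    rng = np.random.default_rng(53)
    n = 50
    pm = PhenotypeMatrix(
        np.arange(n).astype(object), rng.normal(size=(n, N_AGES))
    )
    g = make_geno(
        rng.binomial(2, 0.4, size=(n, 1)).astype(float),
        ids=pm.sample_ids,
    )
    sex = rng.integers(0, 2, n)
    cov = pd.DataFrame({"sex": sex, "sex_copy": sex.astype(float)})
    with pytest.raises(ValueError, match="collinear"):
        run_assoc(pm, g, covariates=cov, ages=[0])


# ---------------------------------------------------------------------------
# the OLS engine
# ---------------------------------------------------------------------------

def test_exact_linear_relation_recovered():
    rng = np.random.default_rng(59)
    n = 200
    g_dos = rng.binomial(2, 0.3, n).astype(float)
    sex = rng.integers(0, 2, n)
    y = 1.5 + 0.3 * g_dos + 2.0 * sex
    pm = PhenotypeMatrix(
        np.arange(n).astype(object), np.tile(y[:, None], (1, N_AGES))
    )
    geno = make_geno(g_dos[:, None], ids=pm.sample_ids)
    res = run_assoc(pm, geno, covariates=pd.DataFrame({"sex": sex}), ages=[0])
    row = res.table.iloc[0]
    assert row["beta"] == pytest.approx(0.3, abs=1e-10)
    assert row["se"] == pytest.approx(0.0, abs=1e-10)
    assert row["estimable"]


def assoc_vs_oracles(use_t):
    rng = np.random.default_rng(61)
    n = 400
    dosages = (
        rng.binomial(2, 0.25, size=(n, 3))
        + rng.uniform(-0.2, 0.2, size=(n, 3))
    ).clip(0, 2)
    sex = rng.integers(0, 2, n)
    pcs = rng.normal(size=(n, 2))
    y = rng.normal(size=n) + 0.1 * dosages[:, 0] + 0.3 * sex
    vals = np.full((n, N_AGES), np.nan)
    vals[:, 2] = y
    pm = PhenotypeMatrix(np.arange(n).astype(object), vals)
    geno = make_geno(dosages, ids=pm.sample_ids)
    cov = pd.DataFrame({"sex": sex, "PC1": pcs[:, 0], "PC2": pcs[:, 1]})
    res = run_assoc(pm, geno, covariates=cov, ages=[2], use_t=use_t)

    for k in range(3):
        row = res.table[res.table["id"] == f"v{k}"].iloc[0]
        X = sm.add_constant(
            np.column_stack([dosages[:, k], sex, pcs]), prepend=True
        )
        fit = sm.OLS(y, X).fit(use_t=use_t)
        assert row["beta"] == pytest.approx(fit.params[1], rel=1e-10)
        assert row["se"] == pytest.approx(fit.bse[1], rel=1e-10)
        assert row["p"] == pytest.approx(fit.pvalues[1], rel=1e-8)
        # independent normal-equations oracle
        XtX_inv = np.linalg.inv(X.T @ X)
        coef = XtX_inv @ (X.T @ y)
        resid = y - X @ coef
        s2 = resid @ resid / (n - X.shape[1])
        assert row["beta"] == pytest.approx(coef[1], rel=1e-10)
        assert row["se"] == pytest.approx(
            np.sqrt(s2 * XtX_inv[1, 1]), rel=1e-10
        )


def test_assoc_matches_statsmodels_t_reference():
    assoc_vs_oracles(use_t=True)


def test_assoc_matches_statsmodels_normal_reference():
    assoc_vs_oracles(use_t=False)


def test_zero_variance_dosage_not_estimable():
    rng = np.random.default_rng(67)
    n = 100
    pm = PhenotypeMatrix(
        np.arange(n).astype(object), rng.normal(size=(n, N_AGES))
    )
    geno = make_geno(np.full((n, 1), 2.0), ids=pm.sample_ids)
    res = run_assoc(pm, geno, ages=[0])
    row = res.table.iloc[0]
    assert not row["estimable"]
    assert np.isnan(row["beta"])


def test_missing_phenotypes_complete_case_per_age():
    rng = np.random.default_rng(71)
    n = 120
    vals = rng.normal(size=(n, N_AGES))
    vals[:30, 0] = np.nan
    pm = PhenotypeMatrix(np.arange(n).astype(object), vals)
    geno = make_geno(
        rng.binomial(2, 0.5, size=(n, 1)).astype(float), ids=pm.sample_ids
    )
    res = run_assoc(pm, geno, ages=[0, 1])
    assert res.table.set_index("age_index").loc[0, "n"] == n - 30
    assert res.table.set_index("age_index").loc[1, "n"] == n
    # oracle on the complete cases at age 0
    X = sm.add_constant(geno.dosages[30:, 0], prepend=True)
    fit = sm.OLS(vals[30:, 0], X).fit(use_t=True)
    row = res.table[res.table["age_index"] == 0].iloc[0]
    assert row["beta"] == pytest.approx(fit.params[1], rel=1e-10)


def test_conditional_analysis_matches_explicit_covariate():
    rng = np.random.default_rng(73)
    n = 300
    dosages = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
    y = rng.normal(size=n) + 0.2 * dosages[:, 0] + 0.2 * dosages[:, 1]
    vals = np.tile(y[:, None], (1, N_AGES))
    pm = PhenotypeMatrix(np.arange(n).astype(object), vals)
    geno = make_geno(dosages, ids=pm.sample_ids)
    res = run_assoc(pm, geno, conditional_variant_ids=("v1",), ages=[0])
    # v1 is not itself tested
    assert set(res.table["id"]) == {"v0"}
    X = sm.add_constant(
        np.column_stack([dosages[:, 0], dosages[:, 1]]), prepend=True
    )
    fit = sm.OLS(y, X).fit(use_t=True)
    row = res.table.iloc[0]
    assert row["beta"] == pytest.approx(fit.params[1], rel=1e-10)
    assert row["se"] == pytest.approx(fit.bse[1], rel=1e-10)


def test_sample_permutation_invariance():
    rng = np.random.default_rng(79)
    n = 150
    dosages = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
    vals = rng.normal(size=(n, N_AGES))
    sex = rng.integers(0, 2, n)
    ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    perm = rng.permutation(n)

    res1 = run_assoc(
        PhenotypeMatrix(ids, vals),
        make_geno(dosages, ids=ids),
        covariates=pd.DataFrame({"sex": sex}),
        ages=[0],
    )
    res2 = run_assoc(
        PhenotypeMatrix(ids[perm], vals[perm]),
        make_geno(dosages[perm], ids=ids[perm]),
        covariates=pd.DataFrame({"sex": sex[perm]}),
        ages=[0],
    )
    for col in ("beta", "se", "p"):
        np.testing.assert_allclose(
            res1.table[col], res2.table[col], rtol=1e-9
        )


def test_misaligned_samples_raise():
    rng = np.random.default_rng(83)
    n = 50
    pm = PhenotypeMatrix(
        np.arange(n).astype(object), rng.normal(size=(n, N_AGES))
    )
    geno = make_geno(
        rng.binomial(2, 0.5, size=(n, 1)).astype(float),
        ids=np.arange(n)[::-1].astype(object),
    )
    with pytest.raises(ValueError):
        run_assoc(pm, geno)


def test_forward_variants_threshold():
    table = pd.DataFrame({
        "id": ["a", "a", "b", "c"],
        "age_index": [0, 1, 0, 0],
        "n": 10, "beta": 0.1, "se": 0.01, "t": 1.0,
        "p": [1e-8, 1e-3, 0.5, 9e-8],
        "estimable": [True, True, True, True],
    })
    res = type("R", (), {"table": table})()
    assert forward_variants(res, 1e-7) == ["a", "c"]


# ---------------------------------------------------------------------------
# stratified trajectories
# ---------------------------------------------------------------------------

def test_stratified_trajectories_single_variant_oracle():
    rng = np.random.default_rng(89)
    n = 600
    pheno = rng.normal(size=(n, N_AGES))
    sex = rng.integers(0, 2, n)
    dos = rng.binomial(2, 0.4, n).astype(float)
    geno = make_geno(dos[:, None])
    out = stratified_trajectories(pheno, sex, geno, ["v0"])
    for geno_code in (0, 1, 2):
        for s in (0, 1):
            sub = pheno[(dos == geno_code) & (sex == s)]
            for a in (0, 5, 11):
                row = out[
                    (out["genotype"] == geno_code) & (out["sex"] == s)
                    & (out["age_index"] == a)
                ].iloc[0]
                assert row["n"] == len(sub)
                assert row["median"] == pytest.approx(
                    np.median(sub[:, a]), rel=1e-12
                )
                assert row["mean"] == pytest.approx(
                    sub[:, a].mean(), rel=1e-12
                )


def test_stratified_trajectories_two_variants_and_empty_strata():
    rng = np.random.default_rng(97)
    n = 40
    pheno = rng.normal(size=(n, N_AGES))
    sex = rng.integers(0, 2, n)
    dos = np.column_stack([
        rng.binomial(2, 0.5, n), np.zeros(n)      # second variant monomorphic
    ]).astype(float)
    geno = make_geno(dos)
    out = stratified_trajectories(pheno, sex, geno, ["v0", "v1"])
    # strata with genotype_2 != 0 are empty
    empty = out[out["genotype_2"] == 2]
    assert (empty["n"] == 0).all()
    assert empty["mean"].isna().all()
    filled = out[
        (out["genotype_1"] == 1) & (out["genotype_2"] == 0)
        & (out["age_index"] == 3)
    ].iloc[0]
    sub = pheno[dos[:, 0] == 1, 3]
    assert filled["mean"] == pytest.approx(sub.mean(), rel=1e-12)
    with pytest.raises(ValueError):
        stratified_trajectories(pheno, sex, geno, [])
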