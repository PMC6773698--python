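"""Genotype QC and time-resolved additive association.

Association follows the frequentist additive model: at each of the 12 ages,
ordinary least squares of sd-BMI on the effect-allele dosage with an
intercept, sex, genotyping-batch indicators and principal components as
covariates (optionally plus dosages of conditioning variants), complete-case
per age.  Standard errors come from the usual OLS variance estimate and
two-sided p-values from the t reference distribution (normal optional).

Marker QC applies the computable genotype-level filters: call rate, exact
Hardy-Weinberg test, and per-sample call rate / heterozygosity excess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm, t as t_dist

from .ages import N_AGES
from .genotypes import GenotypeData
from .phenotypes import PhenotypeMatrix


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations no more probable than the observed one.
    Monomorphic input returns 1.  Symmetric in the homozygote labels.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total count must be positive")
    n_a = 2 * n_aa + n_Aa          # one allele's count; symmetry makes the
    n_A = 2 * n_AA + n_Aa          # choice irrelevant
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    # possible heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2               # rare-allele homozygotes
    homc = n - homr - hets                  # common-allele homozygotes
    # log P(het = h | allele counts) up to a constant
    logp = (
        hets * np.log(2.0)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = np.searchsorted(hets, n_Aa)
    p_obs = p[obs]
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_from_dosages(dosage: np.ndarray) -> float:
    """HWE exact p from hard-called dosages (missing entries dropped)."""
    from .meta_prs import hard_call

    d = dosage[np.isfinite(dosage)]
    if d.size == 0:
        return 1.0
    g = hard_call(d)
    return hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))


# ---------------------------------------------------------------------------
# Marker and sample QC
# ---------------------------------------------------------------------------

def marker_sample_qc(
    genotypes: GenotypeData,
    call_rate_threshold: float = 0.98,
    hwe_threshold: float = 1e-6,
    het_excess_sd: float = 4.0,
) -> tuple[GenotypeData, dict]:
    """Filter variants (call rate, HWE) and samples (call rate, het excess).

    Heterozygosity filtering is one-sided: only samples whose heterozygote
    rate exceeds the cohort mean by more than ``het_excess_sd`` standard
    deviations are removed.  Raises if nothing survives.
    """
    from .meta_prs import hard_call

    ds = genotypes.dosages
    n_samples, n_variants = ds.shape
    finite = np.isfinite(ds)

    v_call = finite.mean(axis=0)
    v_keep = v_call >= call_rate_threshold
    hwe_p = np.ones(n_variants)
    for k in np.nonzero(v_keep)[0]:
        hwe_p[k] = hwe_from_dosages(ds[:, k])
    v_keep &= hwe_p >= hwe_threshold

    sub = ds[:, v_keep]
    finite_s = np.isfinite(sub)
    s_call = finite_s.mean(axis=1) if sub.shape[1] else np.ones(n_samples)
    het = np.full(n_samples, np.nan)
    if sub.shape[1]:
        hard = np.where(finite_s, np.round(sub), np.nan)
        with np.errstate(invalid="ignore"):
            het = np.nanmean(hard == 1, axis=1)
    if np.isfinite(het).any():
        mu, sd = np.nanmean(het), np.nanstd(het)
    else:
        mu, sd = np.nan, 0.0
    het_fail = (het > mu + het_excess_sd * sd) if sd > 0 else np.zeros(n_samples, bool)
    s_keep = (s_call >= call_rate_threshold) & ~het_fail

    report = {
        "variants_removed_call_rate": int((v_call < call_rate_threshold).sum()),
        "variants_removed_hwe": int(
            ((v_call >= call_rate_threshold) & (hwe_p < hwe_threshold)).sum()
        ),
        "samples_removed_call_rate": int((s_call < call_rate_threshold).sum()),
        "samples_removed_het_excess": int(
            het_fail[s_call >= call_rate_threshold].sum()
        ),
        "variants_kept": int(v_keep.sum()),
        "samples_kept": int(s_keep.sum()),
    }
    if not v_keep.any() or not s_keep.any():
        raise ValueError("marker/sample QC removed everything")
    return genotypes.subset_variants(v_keep).subset_samples(s_keep), report


# ---------------------------------------------------------------------------
# Covariate design
# ---------------------------------------------------------------------------

def covariate_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric design columns: sex, batch indicators (first level dropped),
    principal components, and any other numeric covariates, in that order."""
    cols, names = [], []
    if "sex" in covariates:
        cols.append(covariates["sex"].to_numpy(dtype=float))
        names.append("sex")
    if "batch" in covariates:
        dummies = pd.get_dummies(covariates["batch"], prefix="batch", drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(str(c))
    for c in covariates.columns:
        if c in ("sex", "batch") or not np.issubdtype(covariates[c].dtype, np.number):
            continue
        cols.append(covariates[c].to_numpy(dtype=float))
        names.append(c)
    if not cols:
        return np.empty((len(covariates), 0)), []
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    _, R = np.linalg.qr(np.column_stack([np.ones(len(X)), X]))
    diag = np.abs(np.diag(R))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    if bad.any():
        all_names = ["intercept"] + names
        collinear = [all_names[i] for i in np.nonzero(bad)[0]]
        raise ValueError(f"collinear covariate columns: {collinear}")


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["id", "age_index", "n", "beta", "se", "t", "p", "estimable"]


@dataclass
class AssocResult:
    """Per-variant, per-age additive-model estimates."""

    table: pd.DataFrame              # columns RESULT_COLUMNS
    variants: pd.DataFrame           # metadata of tested variants

    def for_age(self, age_index: int) -> pd.DataFrame:
        sub = self.table[self.table["age_index"] == age_index]
        out = self.variants.merge(sub, on="id")
        out = out.rename(
            columns={"chrom": "chr", "ea": "EA", "oa": "nonEA", "eaf": "EAF"}
        )
        return out[
            ["id", "chr", "pos", "EA", "nonEA", "EAF", "info", "n", "beta", "se", "p"]
        ]

    def for_variant(self, variant_id: str) -> pd.DataFrame:
        return self.table[self.table["id"] == variant_id].reset_index(drop=True)


def _ols(y: np.ndarray, X: np.ndarray, use_t: bool) -> tuple[float, float, float, float]:
    """OLS of y on X (dosage in column 1); returns beta, se, t, p for it."""
    n, k = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    try:
        coef = np.linalg.solve(XtX, Xty)
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan, np.nan
    resid = y - X @ coef
    df = n - k
    if df <= 0:
        return np.nan, np.nan, np.nan, np.nan
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    beta = float(coef[1])
    if se == 0.0:
        return beta, se, np.inf, 0.0
    tval = beta / se
    if use_t:
        p = 2.0 * float(t_dist.sf(abs(tval), df))
    else:
        p = 2.0 * float(norm.sf(abs(tval)))
    return beta, se, tval, max(p, 5e-324)


def run_assoc(
    phenotypes: PhenotypeMatrix,
    genotypes: GenotypeData,
    covariates: pd.DataFrame | None = None,
    conditional_variant_ids: tuple[str, ...] = (),
    ages: list[int] | None = None,
    use_t: bool = True,
) -> AssocResult:
    """Per-age OLS of sd-BMI on dosage with covariates.

    Samples must be row-aligned across phenotypes, genotypes and covariates;
    complete cases are selected independently at each age.  Conditioning
    variants enter as additional dosage covariates and are not themselves
    tested.  Zero-variance dosage after filtering yields a not-estimable row.
    """
    n = phenotypes.n_samples
    if genotypes.n_samples != n or np.any(
        np.asarray(phenotypes.sample_ids) != np.asarray(genotypes.sample_ids)
    ):
        raise ValueError("phenotype and genotype samples are not aligned")
    if covariates is not None and len(covariates) != n:
        raise ValueError("covariate rows not aligned with samples")

    C, cov_names = (
        covariate_design(covariates) if covariates is not None else (np.empty((n, 0)), [])
    )
    cond_idx = [genotypes.index_of(v) for v in conditional_variant_ids]
    if cond_idx:
        C = np.column_stack([C, genotypes.dosages[:, cond_idx]])
        cov_names = cov_names + [f"cond_{v}" for v in conditional_variant_ids]
    _check_full_rank(C, cov_names)

    test_idx = [k for k in range(genotypes.n_variants) if k not in cond_idx]
    ages = list(range(N_AGES)) if ages is None else list(ages)
    cov_ok = np.all(np.isfinite(C), axis=1) if C.shape[1] else np.ones(n, bool)

    rows = []
    var_ids = genotypes.variants["id"].to_numpy()
    for a in ages:
        y_all = phenotypes.values[:, a]
        base = np.isfinite(y_all) & cov_ok
        for k in test_idx:
            g = genotypes.dosages[:, k]
            mask = base & np.isfinite(g)
            m = int(mask.sum())
            if m == 0 or np.nanstd(g[mask]) == 0.0:
                rows.append((var_ids[k], a, m, np.nan, np.nan, np.nan, np.nan, False))
                continue
            X = np.column_stack([np.ones(m), g[mask], C[mask]])
            beta, se, tval, p = _ols(y_all[mask], X, use_t)
            rows.append((var_ids[k], a, m, beta, se, tval, p, np.isfinite(beta)))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return AssocResult(table, genotypes.variants.iloc[test_idx].reset_index(drop=True))


def forward_variants(result: AssocResult, p_threshold: float = 1e-7) -> list[str]:
    """Variants reaching the forwarding threshold at one or more ages."""
    ok = result.table["estimable"] & (result.table["p"] < p_threshold)
    return list(pd.unique(result.table.loc[ok, "id"]))


# ---------------------------------------------------------------------------
# Genotype-stratified trajectories
# ---------------------------------------------------------------------------

def stratified_trajectories(
    phenotype: np.ndarray,
    sex: np.ndarray,
    genotypes: GenotypeData,
    variant_ids: list[str],
) -> pd.DataFrame:
    """Median (single variant, per sex) or mean (two-variant combination)
    phenotype per genotype stratum and age, with the standard error of the
    mean.  Empty strata are reported as missing.

    ``phenotype`` is an (n, 12) matrix — raw BMI for trajectory plots or
    sd-BMI for combined-genotype contrasts.
    """
    from .meta_prs import hard_call

    if len(variant_ids) not in (1, 2):
        raise ValueError("supply one or two variant ids")
    calls = [hard_call(genotypes.dosage(v)) for v in variant_ids]
    rows = []
    if len(variant_ids) == 1:
        g = calls[0]
        for geno in (0, 1, 2):
            for s in (0, 1):
                sub = phenotype[(g == geno) & (sex == s)]
                for a in range(N_AGES):
                    col = sub[:, a] if sub.size else np.empty(0)
                    col = col[np.isfinite(col)]
                    rows.append(
                        {
                            "variant": variant_ids[0], "genotype": geno, "sex": s,
                            "age_index": a, "n": col.size,
                            "median": float(np.median(col)) if col.size else np.nan,
                            "mean": float(col.mean()) if col.size else np.nan,
                            "sem": float(col.std(ddof=1) / np.sqrt(col.size))
                            if col.size > 1 else np.nan,
                        }
                    )
    else:
        g1, g2 = calls
        for a1 in (0, 1, 2):
            for a2 in (0, 1, 2):
                sub = phenotype[(g1 == a1) & (g2 == a2)]
                for a in range(N_AGES):
                    col = sub[:, a] if sub.size else np.empty(0)
                    col = col[np.isfinite(col)]
                    rows.append(
                        {
                            "genotype_1": a1, "genotype_2": a2, "age_index": a,
                            "n": col.size,
                            "mean": float(col.mean()) if col.size else np.nan,
                            "median": float(np.median(col)) if col.size else np.nan,
                            "sem": float(col.std(ddof=1) / np.sqrt(col.size))
                            if col.size > 1 else np.nan,
                        }
                    )
    return pd.DataFrame(rows)
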