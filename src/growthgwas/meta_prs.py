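"""Fixed-effects meta-analysis and polygenic-score profiling.

Two-cohort summary statistics are pooled by inverse-variance weighting
(weights 1/SE^2, pooled SE = 1/sqrt(sum of weights), two-sided normal p).
Polygenic scores are effect-weighted sums of hard-called effect-allele
counts over variants passing the imputation-info filter, and are profiled
against the phenotype as a Pearson correlation at each age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ages import N_AGES
from .genotypes import GenotypeData
from .phenotypes import PhenotypeMatrix


# ---------------------------------------------------------------------------
# Inverse-variance-weighted fixed-effects meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class MetaResult:
    beta: float
    se: float
    p: float
    inputs: tuple = ()

    def __post_init__(self) -> None:
        betas = [b for b, _ in self.inputs]
        ses = [s for _, s in self.inputs]
        assert self.se <= min(ses) + 1e-12
        assert min(betas) - 1e-12 <= self.beta <= max(betas) + 1e-12


def meta_ivw(beta1: float, se1: float, beta2: float, se2: float) -> MetaResult:
    """Pool two cohort estimates with inverse-variance fixed-effects weights."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    beta = (w1 * beta1 + w2 * beta2) / (w1 + w2)
    se = 1.0 / np.sqrt(w1 + w2)
    z = beta / se
    p = 2.0 * float(norm.sf(abs(z)))
    return MetaResult(float(beta), float(se), max(p, 5e-324),
                      inputs=((beta1, se1), (beta2, se2)))


def load_lead_snp_table() -> pd.DataFrame:
    """Published two-cohort summary statistics for the forwarded lead SNPs
    (discovery and replication beta/SE/p per variant), shipped as package
    data.  Meta columns are not included; they are recomputed by meta_ivw."""
    with resources.files("growthgwas.data").joinpath(
        "lead_snps_two_cohorts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def meta_table(two_cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply meta_ivw row-wise to a two-cohort summary table.

    Expects columns beta_disc, se_disc, beta_repl, se_repl; appends
    beta_meta, se_meta, p_meta.
    """
    out = two_cohort.copy()
    metas = [
        meta_ivw(r.beta_disc, r.se_disc, r.beta_repl, r.se_repl)
        for r in out.itertuples()
    ]
    out["beta_meta"] = [m.beta for m in metas]
    out["se_meta"] = [m.se for m in metas]
    out["p_meta"] = [m.p for m in metas]
    return out


# ---------------------------------------------------------------------------
# Hard calls and polygenic scores
# ---------------------------------------------------------------------------

def hard_call(dosage, boundary: str = "away_from_het"):
    """Hard-call dosages to genotype counts {0, 1, 2}.

    Nearest integer; exact .5 boundaries round away from the heterozygote by
    default (0.5 -> 0, 1.5 -> 2), or toward it with ``boundary="to_het"``.
    Missing (NaN) propagates; values outside [0, 2] raise.
    """
    d = np.asarray(dosage, dtype=float)
    finite = np.isfinite(d)
    if np.any((d[finite] < 0) | (d[finite] > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    out = np.round(d)  # banker's rounding: 0.5 -> 0, 1.5 -> 2 (away from het)
    if boundary == "to_het":
        out = np.where(d == 0.5, 1.0, out)
        out = np.where(d == 1.5, 1.0, out)
    elif boundary != "away_from_het":
        raise ValueError(f"unknown boundary rule {boundary!r}")
    if out.ndim == 0:
        return float(out) if np.isnan(out) else int(out)
    return out


@dataclass
class PRSModel:
    """Weight table for a polygenic score."""

    variant_ids: np.ndarray
    effect_alleles: np.ndarray
    weights: np.ndarray
    info_threshold: float = 0.7

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.effect_alleles = np.asarray(self.effect_alleles, dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant ids must be unique")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @classmethod
    def from_table(cls, df: pd.DataFrame, info_threshold: float = 0.7) -> "PRSModel":
        return cls(
            df["id"].to_numpy(), df["effect_allele"].to_numpy(),
            df["weight"].to_numpy(), info_threshold,
        )

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.variant_ids,
                "effect_allele": self.effect_alleles,
                "weight": self.weights,
            }
        )


def compute_prs(
    genotypes: GenotypeData, model: PRSModel, boundary: str = "away_from_het"
) -> tuple[np.ndarray, dict]:
    """Per-sample polygenic score: sum of weight x hard-called allele count.

    Variants are matched by id; if the model's effect allele equals the
    genotype file's other allele the count direction flips (count becomes
    2 - count).  Variants with info score <= the model threshold are dropped
    and reported.  Raises if no model variant can be scored.
    """
    gvars = genotypes.variants.set_index("id")
    scores = np.zeros(genotypes.n_samples)
    used, dropped_info, unmatched, flipped = [], [], [], []
    for vid, ea, w in zip(model.variant_ids, model.effect_alleles, model.weights):
        if vid not in gvars.index:
            unmatched.append(vid)
            continue
        rec = gvars.loc[vid]
        if rec["info"] <= model.info_threshold:
            dropped_info.append(vid)
            continue
        count = hard_call(genotypes.dosage(vid), boundary=boundary)
        if ea == rec["ea"]:
            pass
        elif ea == rec["oa"]:
            count = 2.0 - count
            flipped.append(vid)
        else:
            unmatched.append(vid)
            continue
        scores = scores + w * np.where(np.isfinite(count), count, 0.0)
        used.append(vid)
    if not used:
        raise ValueError("no model variants could be matched and scored")
    report = {
        "n_used": len(used),
        "dropped_info": dropped_info,
        "unmatched": unmatched,
        "flipped": flipped,
    }
    return scores, report


def prs_correlation(
    scores: np.ndarray, phenotypes: PhenotypeMatrix
) -> pd.DataFrame:
    """Pearson correlation between the score and the phenotype at each age.

    Complete cases per age; a constant score vector yields a missing r.
    """
    rows = []
    for a in range(N_AGES):
        y = phenotypes.values[:, a]
        mask = np.isfinite(y) & np.isfinite(scores)
        n = int(mask.sum())
        if n < 3 or np.std(scores[mask]) == 0 or np.std(y[mask]) == 0:
            rows.append({"age_index": a, "n": n, "r": np.nan})
            continue
        r = float(np.corrcoef(scores[mask], y[mask])[0, 1])
        rows.append({"age_index": a, "n": n, "r": r})
    return pd.DataFrame(rows)
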