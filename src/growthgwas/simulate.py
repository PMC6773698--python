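"""Synthetic cohort generator: growth curves, corruption, genotypes, effects.

The generator emulates the statistical structure of a longitudinal birth
cohort measured on the fixed 12-point age grid:

* sex-specific multiplicative growth around a packaged median table, with a
  child-level size intercept, a persistent growth-tempo process (each child
  multiplies every interval's median log-growth by exp(g_k), where g is an
  autocorrelated, per-child-centred deviation sequence), and per-measurement
  noise — all on the log scale, so medians are preserved, growth ratios are
  well defined, and clean curves are monotone wherever the median table is;
* transcription and unit errors (heights recorded in centimetres, weights in
  grams), isolated spikes/gaps, and spurious height decreases, injected with
  a complete ground-truth log;
* Hardy-Weinberg hard genotypes with bounded imputation noise so the info
  score (observed dosage variance over 2p(1-p)) is controllable;
* additive SNP effects on standardized BMI whose magnitude varies over age.

Persistent tempo variation matters: if growth ratios varied only through
measurement noise, consecutive log-ratios would be correlated -0.5 and the
quantile-anchored peak/gap rule would flag a fixed ~6% of interior cells on
perfectly clean data regardless of the noise level (the rule's thresholds
are empirical quantiles, so marginal exceedance is 15.9% per tail by
construction; only positive correlation between consecutive ratio
deviations makes the opposite-tail coincidence rare).  Real cohorts — and
this generator — have between-child growth-rate variation that dominates
measurement noise at every interval and persists across neighbouring
intervals, so a flagged peak almost always reflects a genuinely off-curve
measurement.  Making the tempo multiplicative on the median log-growth (a
slow child grows a fraction of the median increment, never a negative one)
keeps clean height curves monotone, so the height-decrease machinery only
ever sees measurement noise; centring each child's tempo sequence keeps the
cross-sectional spread at later ages realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ages import AGE_DAYS, N_AGES, INTERIOR
from .cohort import Cohort, MEASURES, MISSING, OBSERVED
from .genotypes import GenotypeData, VARIANT_COLUMNS
from .phenotypes import PhenotypeMatrix

# ---------------------------------------------------------------------------
# Packaged growth fixture: median height (m) and weight (kg) per sex x age.
# Rows: sex code 0 = female, 1 = male; columns follow ages.AGE_LABELS.
# Plausible WHO-like medians for a Northern-European cohort.
# ---------------------------------------------------------------------------
MEDIAN_HEIGHT = np.array(
    [
        [0.49, 0.56, 0.60, 0.66, 0.69, 0.74, 0.81, 0.86, 0.95, 1.09, 1.21, 1.27],
        [0.50, 0.57, 0.61, 0.68, 0.71, 0.76, 0.82, 0.87, 0.96, 1.10, 1.22, 1.28],
    ]
)
MEDIAN_WEIGHT = np.array(
    [
        [3.4, 4.6, 5.9, 7.3, 8.0, 9.0, 10.3, 11.5, 13.9, 18.0, 22.7, 25.8],
        [3.5, 4.9, 6.4, 7.9, 8.6, 9.6, 10.9, 12.2, 14.3, 18.4, 23.0, 25.8],
    ]
)
GROWTH_MEDIANS = {"height": MEDIAN_HEIGHT, "weight": MEDIAN_WEIGHT}


@dataclass
class SimConfig:
    """Configuration of the clean-cohort generator.

    All random-effect and noise standard deviations are on the natural-log
    scale and may be given per measure (``{"height": .., "weight": ..}``) or
    as a single float applied to both.
    """

    n_children: int = 1000
    sex_ratio: float = 0.5            # probability of a male child
    medians: dict = field(default_factory=lambda: GROWTH_MEDIANS)
    re_sd: dict | float = field(
        default_factory=lambda: {"height": 0.035, "weight": 0.12}
    )
    tempo_sd: dict | float = field(
        default_factory=lambda: {"height": 1.0, "weight": 0.7}
    )
    tempo_corr: float = 0.9           # lag-1 correlation of tempo deviations
    noise_sd: dict | float = field(
        default_factory=lambda: {"height": 0.008, "weight": 0.02}
    )
    missing_prob: float = 0.10
    preterm_prob: float = 0.055
    gest_mean: float = 282.0          # term gestational age, days
    gest_sd: float = 8.0
    seed: int = 0

    def _per_measure(self, value) -> dict:
        if isinstance(value, dict):
            return value
        return {m: float(value) for m in MEASURES}

    def validate(self) -> None:
        if self.n_children <= 0:
            raise ValueError("n_children must be positive")
        for p in (self.sex_ratio, self.missing_prob, self.preterm_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for m in MEASURES:
            med = np.asarray(self.medians[m])
            if med.shape != (2, N_AGES):
                raise ValueError(f"median table for {m} must be 2 x {N_AGES}")
            if np.any(med <= 0):
                raise ValueError("medians must be positive")
        if np.any(np.diff(np.asarray(self.medians["height"]), axis=1) <= 0):
            raise ValueError("height medians must increase with age")


@dataclass
class ErrorConfig:
    """Corruption model: probabilities and magnitudes of injected errors."""

    unit_error_prob: float = 0.003    # height recorded in cm / weight in g
    spike_gap_prob: float = 0.01      # isolated multiplicative spike or gap
    spike_magnitude: float = 1.4      # multiplier (>1); gaps use 1/magnitude
    decrease_prob: float = 0.005      # spurious height decrease per pair
    decrease_magnitude: float = 0.05  # shrink fraction for h_{i+1}
    seed: int = 0

    def validate(self) -> None:
        for p in (self.unit_error_prob, self.spike_gap_prob, self.decrease_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.spike_magnitude <= 1.0:
            raise ValueError("spike magnitude must exceed 1")
        if not 0.0 < self.decrease_magnitude < 1.0:
            raise ValueError("decrease magnitude must lie in (0, 1)")


@dataclass
class EffectProfile:
    """Age-resolved additive effect of one variant on sd-BMI."""

    variant_id: str
    eaf: float
    effects: np.ndarray               # (12,) effect per age, sd-BMI per allele
    dosage_noise_sd: float = 0.0      # controls the info score

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if not 0.0 < self.eaf < 1.0:
            raise ValueError("effect allele frequency must lie in (0, 1)")
        if self.effects.shape != (N_AGES,):
            raise ValueError(f"effects must have length {N_AGES}")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("effects must be finite")


#: TruthLog column layout: one row per corrupted cell.
TRUTHLOG_COLUMNS = ["child_id", "age_index", "measure", "kind", "original"]


def _empty_truthlog() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "child_id": pd.Series(dtype=object),
            "age_index": pd.Series(dtype=int),
            "measure": pd.Series(dtype=object),
            "kind": pd.Series(dtype=object),
            "original": pd.Series(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# Clean cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a clean cohort of growth curves.

    Each non-missing log value is ``log median[sex, 0] + u0 + C_i + e_i``
    where ``u0`` is a child size intercept, ``C_i`` the cumulative sum of
    per-interval growth ``dlogm_k * (1 + tanh(g_k))`` (``dlogm_k`` the
    median log-growth of interval ``k``; ``g`` an AR(1) tempo sequence with
    lag-1 correlation ``tempo_corr`` and marginal sd ``tempo_sd``, centred
    per child), and ``e`` independent measurement noise.  The tempo factor
    is strictly positive and point-symmetric around 1, so clean curves are
    monotone wherever the median table is and the population median stays on
    the table at every age.  Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_children

    sex = (rng.random(n) < config.sex_ratio).astype(np.int8)
    preterm = rng.random(n) < config.preterm_prob
    gest = np.clip(rng.normal(config.gest_mean, config.gest_sd, n), 259, 310)
    gest[preterm] = rng.uniform(196, 258, preterm.sum())
    gest = np.round(gest)

    re_sd = config._per_measure(config.re_sd)
    tempo_sd = config._per_measure(config.tempo_sd)
    noise_sd = config._per_measure(config.noise_sd)
    phi = float(config.tempo_corr)

    values = {}
    for meas in MEASURES:
        med = np.asarray(config.medians[meas], dtype=float)
        logm = np.log(med)                       # (2, 12)
        dlogm = np.diff(logm, axis=1)            # (2, 11) median log-growth
        u0 = rng.normal(0.0, re_sd[meas], n)
        # AR(1) tempo deviations with stationary sd tempo_sd, centred
        innov_sd = tempo_sd[meas] * np.sqrt(max(1.0 - phi**2, 1e-12))
        g = np.empty((n, N_AGES - 1))
        g[:, 0] = rng.normal(0.0, tempo_sd[meas], n)
        for k in range(1, N_AGES - 1):
            g[:, k] = phi * g[:, k - 1] + rng.normal(0.0, innov_sd, n)
        if tempo_sd[meas] > 0:
            g -= g.mean(axis=1, keepdims=True)   # centre: end near percentile
        # 1 + tanh(g) is strictly positive (monotone clean curves) and
        # point-symmetric around 1, so the population median log value stays
        # exactly on the fixture table at every age.
        growth = dlogm[sex] * (1.0 + np.tanh(g))
        C = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(growth, axis=1)], axis=1
        )
        eps = rng.normal(0.0, noise_sd[meas], (n, N_AGES))
        values[meas] = np.exp(logm[sex, 0][:, None] + u0[:, None] + C + eps)

    miss = rng.random((n, N_AGES)) < config.missing_prob
    height, weight = values["height"], values["weight"]
    height[miss] = np.nan
    weight[miss] = np.nan
    hst = np.where(miss, MISSING, OBSERVED).astype(np.int16)
    wst = hst.copy()

    ids = np.array([f"C{i:06d}" for i in range(n)], dtype=object)
    return Cohort(ids, sex, gest, height, weight, hst, wst,
                  meta={"seed": config.seed})


# ---------------------------------------------------------------------------
# Corruption
# ---------------------------------------------------------------------------

def inject_errors(cohort: Cohort, err: ErrorConfig) -> tuple[Cohort, pd.DataFrame]:
    """Corrupt a clean cohort and return it with a complete truth log.

    At most one corruption is applied per cell; corruption is applied after
    missingness, so every logged entry corresponds to an observed cell whose
    value now differs from the clean cohort.  Deterministic given the seed.
    """
    err.validate()
    rng = np.random.default_rng(err.seed)
    out = cohort.copy()
    log_rows: list[tuple] = []
    taken = {m: np.zeros(out.values(m).shape, dtype=bool) for m in MEASURES}

    def corrupt(measure, r, c, kind, new_value):
        v = out.values(measure)
        log_rows.append((out.child_ids[r], int(c), measure, kind, float(v[r, c])))
        v[r, c] = new_value
        taken[measure][r, c] = True

    # 1. unit errors (any age)
    for meas, factor in (("height", 100.0), ("weight", 1000.0)):
        v = out.values(meas)
        cells = np.isfinite(v) & (rng.random(v.shape) < err.unit_error_prob)
        for r, c in zip(*np.nonzero(cells)):
            corrupt(meas, r, c, "unit", v[r, c] * factor)

    # 2. spikes / gaps on interior cells
    for meas in MEASURES:
        v = out.values(meas)
        hit = rng.random(v.shape) < err.spike_gap_prob
        hit[:, 0] = hit[:, -1] = False
        cells = np.isfinite(v) & hit & ~taken[meas]
        rs, cs = np.nonzero(cells)
        spikes = rng.random(len(rs)) < 0.5
        for r, c, up in zip(rs, cs, spikes):
            fac = err.spike_magnitude if up else 1.0 / err.spike_magnitude
            corrupt(meas, r, c, "spike" if up else "gap", v[r, c] * fac)

    # 3. spurious height decreases on consecutive observed pairs
    v = out.values("height")
    pair_ok = np.isfinite(v[:, :-1]) & np.isfinite(v[:, 1:])
    pair_ok &= ~taken["height"][:, :-1] & ~taken["height"][:, 1:]
    pair_hit = pair_ok & (rng.random(pair_ok.shape) < err.decrease_prob)
    rs, cs = np.nonzero(pair_hit)
    swaps = rng.random(len(rs)) < 0.5
    for r, c, swap in zip(rs, cs, swaps):
        if taken["height"][r, c] or taken["height"][r, c + 1]:
            continue
        if swap and v[r, c + 1] > v[r, c]:
            a, b = v[r, c], v[r, c + 1]
            corrupt("height", r, c, "decrease_swap", b)
            corrupt("height", r, c + 1, "decrease_swap", a)
        else:
            corrupt("height", r, c + 1, "decrease_shrink",
                    v[r, c] * (1.0 - err.decrease_magnitude))

    log = _empty_truthlog() if not log_rows else pd.DataFrame(
        log_rows, columns=TRUTHLOG_COLUMNS
    )
    return out, log


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_samples: int, profiles: list[EffectProfile], seed: int = 0,
    sample_ids: np.ndarray | None = None,
) -> GenotypeData:
    """Draw Hardy-Weinberg hard genotypes and noisy dosages per profile.

    Hard genotypes are Binomial(2, eaf); the dosage adds Gaussian noise
    clipped to [0, 2].  The recorded info score is the observed dosage
    variance over 2*p*(1-p) at the observed dosage allele frequency.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = np.array([f"C{i:06d}" for i in range(n_samples)], dtype=object)

    dosages = np.empty((n_samples, len(profiles)))
    rows = []
    for k, prof in enumerate(profiles):
        hard = rng.binomial(2, prof.eaf, n_samples).astype(float)
        ds = hard
        if prof.dosage_noise_sd > 0:
            ds = np.clip(hard + rng.normal(0, prof.dosage_noise_sd, n_samples), 0, 2)
        dosages[:, k] = ds
        p_obs = ds.mean() / 2.0
        denom = 2.0 * p_obs * (1.0 - p_obs)
        info = float(ds.var() / denom) if denom > 0 else np.nan
        rows.append(
            {
                "id": prof.variant_id,
                "chrom": "1",
                "pos": 10_000 + 1_000 * k,
                "ea": "G",
                "oa": "A",
                "eaf": float(p_obs),
                "info": info,
            }
        )
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return GenotypeData(sample_ids, variants, dosages)


# ---------------------------------------------------------------------------
# Phenotype effects
# ---------------------------------------------------------------------------

def attach_genetic_effects(
    phenotypes: PhenotypeMatrix,
    genotypes: GenotypeData,
    profiles: list[EffectProfile],
) -> PhenotypeMatrix:
    """Add dosage-weighted, age-varying variant effects to sd-BMI.

    The input is expected to be standardized (mean ~0, sd ~1 per age); no
    re-standardization is applied, so the caller controls the final scale.
    """
    if len(phenotypes.sample_ids) != len(genotypes.sample_ids) or np.any(
        np.asarray(phenotypes.sample_ids) != np.asarray(genotypes.sample_ids)
    ):
        raise ValueError("phenotype and genotype sample ids are not aligned")
    out = phenotypes.copy()
    for prof in profiles:
        ds = genotypes.dosage(prof.variant_id)
        out.values += ds[:, None] * prof.effects[None, :]
    return out


def standard_normal_phenotypes(
    n_samples: int, seed: int = 0, sample_ids: np.ndarray | None = None
) -> PhenotypeMatrix:
    """A standardized null phenotype matrix (iid standard normal per age)."""
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = np.array([f"C{i:06d}" for i in range(n_samples)], dtype=object)
    return PhenotypeMatrix(sample_ids, rng.standard_normal((n_samples, N_AGES)))


def simulate_covariates(
    n_samples: int, seed: int = 0, n_pcs: int = 10, n_batches: int = 3,
    sex: np.ndarray | None = None,
) -> pd.DataFrame:
    """Covariate table: sex, genotyping batch, and principal components."""
    rng = np.random.default_rng(seed)
    if sex is None:
        sex = (rng.random(n_samples) < 0.5).astype(int)
    df = pd.DataFrame({"sex": np.asarray(sex, dtype=int)})
    df["batch"] = rng.integers(0, n_batches, n_samples)
    pcs = rng.standard_normal((n_samples, n_pcs))
    for j in range(n_pcs):
        df[f"PC{j + 1}"] = pcs[:, j]
    return df
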