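"""Longitudinal growth-phenotype QC and sd-BMI standardization.

The pipeline cleans per-child height/weight curves on the 12-point age grid:

1. exclude preterm children (gestation < 37 weeks 0 days = 259 days);
2. harmonize units (heights recorded in cm, weights in g);
3. remove extreme outliers against pooled per-age 1st/99th percentile bounds;
4. build the sex-specific reference panel on eligible children;
5. remove curve outliers: a value whose surrounding scaled log2 growth
   ratios jump above +1 then below -1 is a peak, the reverse a gap;
6. resolve physiologically impossible height decreases by exclusion or by
   iterative 10%-step correction toward ratio-interpolated targets;
7. impute missing values as the median of ratio-interpolations from the
   child's own observed values;
8. repeat outlier removal and decrease correction on the augmented curves
   and impute newly exposed missing values (one repeat pass, matching the
   published procedure; a config switch iterates to a fixed point).

Finally BMI = weight / height^2 is computed wherever both components exist
and standardized per sex and age with the quantile-anchored robust transform
(0 at the median, +/-1 at the empirical quantiles matching +/-1 normal
deviates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ages import AT_AFTER_TWO, BEFORE_TWO, N_AGES
from .cohort import (
    Cohort, MEASURES, MISSING, OBSERVED, IMPUTED, PLAUSIBLE,
    EXC_NONPOSITIVE, EXC_IMPLAUSIBLE, EXC_EXTREME, EXC_PEAK, EXC_GAP,
    EXC_DECREASE, EXC_BOUND, EXC_UNRESOLVED, is_excluded,
)
from .phenotypes import PhenotypeMatrix, PROV_OBSERVED, PROV_PART_IMPUTED, PROV_MISSING
from .reference import (
    MIN_CELL, MeasurePanel, ReferencePanel, build_measure_panel,
    build_reference, scale_robust,
)

#: One-sided multiplier of the anchor distance in the sparse-curve bound rule.
Z99 = float(norm.ppf(0.99))

PRETERM_THRESHOLD_DAYS = 259  # 37 weeks 0 days


@dataclass
class QCConfig:
    preterm_threshold_days: int = PRETERM_THRESHOLD_DAYS
    n_passes: int = 2                  # outlier/decrease/imputation passes
    iterate_to_fixed_point: bool = False
    max_passes: int = 10               # cap when iterating to fixed point
    rebuild_panel_each_pass: bool = True
    decrease_iteration_cap: int = 1000
    decrease_step: float = 0.9         # residual retained per iteration


@dataclass
class QCReport:
    """Counts of values excluded, converted, corrected, imputed per rule."""

    counts: dict = field(default_factory=dict)      # (rule, measure) -> int
    imputed_per_age: dict = field(default_factory=dict)  # measure -> (12,) int
    warnings: list = field(default_factory=list)
    passes: int = 0

    def add(self, rule: str, measure: str, k: int = 1) -> None:
        if k:
            key = (rule, measure)
            self.counts[key] = self.counts.get(key, 0) + int(k)

    def total(self, rule: str | None = None) -> int:
        return sum(
            v for (r, _), v in self.counts.items() if rule is None or r == rule
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": r, "measure": m, "count": v}
            for (r, m), v in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["rule", "measure", "count"])

    @property
    def n_excluded_cells(self) -> int:
        rules = ("nonpositive", "implausible", "extreme", "peak", "gap",
                 "decrease", "bound", "unresolved")
        return sum(self.total(r) for r in rules)


# ---------------------------------------------------------------------------
# 1-2: preterm exclusion, unit harmonization
# ---------------------------------------------------------------------------

def exclude_preterm(
    cohort: Cohort,
    threshold_days: int = PRETERM_THRESHOLD_DAYS,
    report: QCReport | None = None,
) -> Cohort:
    """Drop children with gestation below the threshold (or unknown)."""
    report = report if report is not None else QCReport()
    gest = cohort.gest_age_days
    missing = ~np.isfinite(gest)
    preterm = np.isfinite(gest) & (gest < threshold_days)
    report.add("preterm", "child", int(preterm.sum()))
    report.add("missing_gestation", "child", int(missing.sum()))
    return cohort.subset(~(preterm | missing))


def harmonize_value(value: float, measure: str) -> float:
    """Convert a single value recorded in cm (height) or g (weight).

    Heights above 2.5 are read as centimetres, weights above 200 as grams.
    Non-positive values are invalid here and raise.
    """
    if value <= 0:
        raise ValueError("non-positive measurement")
    if measure == "height" and value > 2.5:
        return value / 100.0
    if measure == "weight" and value > 200.0:
        return value / 1000.0
    return value


def harmonize_units(cohort: Cohort, report: QCReport | None = None) -> Cohort:
    """Vectorized unit harmonization with plausibility screening.

    Converted cells are counted; non-positive values and values implausible
    even after conversion are excluded with distinct reasons.
    """
    report = report if report is not None else QCReport()
    out = cohort.copy()
    for meas, factor, threshold in (("height", 100.0, 2.5), ("weight", 1000.0, 200.0)):
        v = out.values(meas)
        finite = np.isfinite(v)
        nonpos = finite & (v <= 0)
        out.exclude(meas, *np.nonzero(nonpos), EXC_NONPOSITIVE)
        report.add("nonpositive", meas, int(nonpos.sum()))
        conv = np.isfinite(v) & (v > threshold)
        v[conv] = v[conv] / factor
        report.add("unit_converted", meas, int(conv.sum()))
        lo, hi = PLAUSIBLE[meas]
        bad = np.isfinite(v) & ((v < lo) | (v > hi))
        out.exclude(meas, *np.nonzero(bad), EXC_IMPLAUSIBLE)
        report.add("implausible", meas, int(bad.sum()))
    return out


# ---------------------------------------------------------------------------
# 3: extreme outliers (pooled percentiles)
# ---------------------------------------------------------------------------

def remove_extreme_outliers(cohort: Cohort, report: QCReport | None = None) -> Cohort:
    """Exclude values strictly outside median +/- 2x the one-sided 1%/99%
    percentile distance, per age, pooled across sexes.

    Percentile estimates use observed values only; the rule is applied to
    observed and imputed cells alike.  Ages with fewer than MIN_CELL
    observed values are skipped with a logged warning.
    """
    report = report if report is not None else QCReport()
    out = cohort.copy()
    from .reference import extreme_outlier_bounds

    for meas in MEASURES:
        obs_vals = out.usable_values(meas, include_imputed=False)
        all_vals = out.usable_values(meas, include_imputed=True)
        for i in range(N_AGES):
            col = obs_vals[:, i]
            if np.isfinite(col).sum() < MIN_CELL:
                report.warnings.append(
                    f"extreme-outlier rule skipped: {meas} age {i} has "
                    f"<{MIN_CELL} values"
                )
                continue
            low, high = extreme_outlier_bounds(col)
            flag = np.isfinite(all_vals[:, i]) & (
                (all_vals[:, i] < low) | (all_vals[:, i] > high)
            )
            rows = np.nonzero(flag)[0]
            out.exclude(meas, rows, np.full(rows.shape, i), EXC_EXTREME)
            report.add("extreme", meas, len(rows))
    return out


# ---------------------------------------------------------------------------
# 5: curve outliers (peaks and gaps)
# ---------------------------------------------------------------------------

def scaled_ratios(cohort: Cohort, panel: MeasurePanel, measure: str) -> np.ndarray:
    """Scaled log2 consecutive-age ratios r'_k per child (n, 11).

    NaN where either endpoint is unusable or the panel interval statistics
    are unavailable.
    """
    x = cohort.usable_values(measure, include_imputed=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        l2 = np.log2(x[:, 1:] / x[:, :-1])
    out = np.full_like(l2, np.nan)
    for s in range(2):
        rows = cohort.sex == s
        m = panel.log2r_median[s]
        q_hi = panel.log2r_qhi[s]
        q_lo = panel.log2r_qlo[s]
        ok = np.isfinite(m) & (q_hi > m) & (q_lo < m)
        sub = l2[rows]
        scaled = np.full_like(sub, np.nan)
        if ok.any():
            scaled[:, ok] = scale_robust(
                sub[:, ok], m[ok][None, :], q_hi[ok][None, :], q_lo[ok][None, :]
            )
        out[rows] = scaled
    return out


def flag_curve_outliers(
    cohort: Cohort, panel: ReferencePanel, report: QCReport | None = None
) -> Cohort:
    """Exclude peaks (ratio jump up then down) and gaps (down then up).

    A value at interior age i is a peak if r'_{i-1} > 1 and r'_i < -1, a gap
    if r'_{i-1} < -1 and r'_i > 1; endpoints are never flagged.  All flags
    are computed on the same ratio set and applied together.
    """
    report = report if report is not None else QCReport()
    out = cohort.copy()
    for meas in MEASURES:
        rp = scaled_ratios(out, panel[meas], meas)
        with np.errstate(invalid="ignore"):
            peak = (rp[:, :-1] > 1) & (rp[:, 1:] < -1)
            gap = (rp[:, :-1] < -1) & (rp[:, 1:] > 1)
        for flag, code, rule in ((peak, EXC_PEAK, "peak"), (gap, EXC_GAP, "gap")):
            rows, cols = np.nonzero(flag)
            out.exclude(meas, rows, cols + 1, code)  # ratio k-1 ends at age k
            report.add(rule, meas, len(rows))
    return out


# ---------------------------------------------------------------------------
# 6: height-decrease correction
# ---------------------------------------------------------------------------

def _iterate_decrease(
    h_i: float, h_ip1: float, t_i: float, t_ip1: float,
    cap: int = 1000, step: float = 0.9,
) -> tuple[float, float, bool]:
    """Move the value with the larger absolute residual 10% toward its
    target (ties move h_{i+1}) until h_{i+1} >= h_i or the cap is reached.

    Returns (h_i, h_{i+1}, converged)."""
    a, b = float(h_i), float(h_ip1)
    for _ in range(cap):
        if b >= a:
            return a, b, True
        if abs(a - t_i) > abs(b - t_ip1):
            a = t_i + step * (a - t_i)
        else:
            b = t_ip1 + step * (b - t_ip1)
    return a, b, b >= a


def correct_height_decreases(
    cohort: Cohort,
    panel: ReferencePanel,
    report: QCReport | None = None,
    cap: int = 1000,
    step: float = 0.9,
) -> Cohort:
    """Resolve consecutive height decreases (h_{i+1} < h_i).

    With >=3 other observed heights the pair is tested against ratio
    interpolations from every other age: h_i above all of them (or h_{i+1}
    below all of them) is excluded; otherwise both values are pulled
    iteratively toward the medians of their interpolations.  With <=2 other
    heights only the one-sided panel bounds (median +/- z_{0.99} x anchor
    distance) can exclude; pairs violating neither bound are left unchanged
    and flagged unresolved.  Weight decreases are never corrected.
    """
    report = report if report is not None else QCReport()
    out = cohort.copy()
    hp = panel["height"]
    R = hp.interp_matrix()          # (2, 12, 12)
    heights = out.values("height")
    status = out.status("height")

    usable = out.usable("height", include_imputed=True)
    dec_rows = np.unique(
        np.nonzero(
            usable[:, :-1] & usable[:, 1:] & (heights[:, 1:] < heights[:, :-1])
        )[0]
    )

    for r in dec_rows:
        s = int(out.sex[r])
        unresolved: set[int] = set()
        for _ in range(4 * N_AGES):  # safety: each step excludes/corrects
            h = heights[r]
            use = (status[r] == OBSERVED) | (status[r] == IMPUTED)
            idx = np.nonzero(use[:-1] & use[1:] & (h[1:] < h[:-1]))[0]
            idx = [i for i in idx if i not in unresolved]
            if not idx:
                break
            i = int(idx[0])
            anchors = np.nonzero((status[r] == OBSERVED))[0]
            anchors = anchors[(anchors != i) & (anchors != i + 1)]
            interp_i = h[anchors] * R[s, i, anchors]
            interp_ip1 = h[anchors] * R[s, i + 1, anchors]
            valid = np.isfinite(interp_i) & np.isfinite(interp_ip1)
            interp_i, interp_ip1 = interp_i[valid], interp_ip1[valid]

            if len(anchors) >= 3 and len(interp_i) >= 3:
                excluded = False
                if np.all(h[i] > interp_i):
                    out.exclude("height", [r], [i], EXC_DECREASE)
                    report.add("decrease", "height", 1)
                    excluded = True
                if np.all(h[i + 1] < interp_ip1):
                    out.exclude("height", [r], [i + 1], EXC_DECREASE)
                    report.add("decrease", "height", 1)
                    excluded = True
                if excluded:
                    continue
                t_i = float(np.median(interp_i))
                t_ip1 = float(np.median(interp_ip1))
                a, b, done = _iterate_decrease(h[i], h[i + 1], t_i, t_ip1, cap, step)
                if done:
                    heights[r, i], heights[r, i + 1] = a, b
                    report.add("decrease_corrected", "height", 1)
                else:
                    out.exclude("height", [r], [i, i + 1], EXC_UNRESOLVED)
                    report.add("unresolved", "height", 2)
            else:
                excluded = False
                if hp.usable[s, i]:
                    h_high = hp.median[s, i] + Z99 * (hp.q_hi[s, i] - hp.median[s, i])
                    if h[i] > h_high:
                        out.exclude("height", [r], [i], EXC_BOUND)
                        report.add("bound", "height", 1)
                        excluded = True
                if hp.usable[s, i + 1]:
                    h_low = hp.median[s, i + 1] - Z99 * (
                        hp.median[s, i + 1] - hp.q_lo[s, i + 1]
                    )
                    if h[i + 1] < h_low:
                        out.exclude("height", [r], [i + 1], EXC_BOUND)
                        report.add("bound", "height", 1)
                        excluded = True
                if not excluded:
                    unresolved.add(i)
                    report.add("unresolved_pair", "height", 1)
    return out


# ---------------------------------------------------------------------------
# 7: imputation
# ---------------------------------------------------------------------------

def impute_missing(
    cohort: Cohort, panel: ReferencePanel, report: QCReport | None = None
) -> Cohort:
    """Impute missing values as the median of ratio interpolations.

    Children with >=3 observed values before age two and >=2 at/after two
    are imputed at all ages; children with only the before-two criterion at
    before-two ages only.  A value is imputed only where at least two
    non-imputed observed values exist both earlier and later; imputed cells
    are flagged and never serve as anchors.
    """
    report = report if report is not None else QCReport()
    out = cohort.copy()
    for meas in MEASURES:
        p = panel[meas]
        R = p.interp_matrix()
        vals = out.values(meas)
        status = out.status(meas)
        obs = status == OBSERVED
        obs_vals = np.where(obs, vals, np.nan)

        nb = obs[:, BEFORE_TWO].sum(axis=1)
        na = obs[:, AT_AFTER_TWO].sum(axis=1)
        allowed = np.zeros((out.n_children, N_AGES), dtype=bool)
        allowed[(nb >= 3) & (na >= 2)] = True
        allowed[(nb >= 3) & (na < 2)] = BEFORE_TWO[None, :]

        earlier = np.cumsum(obs, axis=1) - obs          # strictly earlier count
        later = obs[:, ::-1].cumsum(axis=1)[:, ::-1] - obs
        target = (
            ~obs
            & ~(status == IMPUTED)
            & allowed
            & (earlier >= 2)
            & (later >= 2)
        )
        if not target.any():
            continue
        imputed_ages = np.zeros(N_AGES, dtype=int)
        for s in range(2):
            rows = np.nonzero((out.sex == s) & target.any(axis=1))[0]
            if rows.size == 0:
                continue
            # interp[c, i, j] = obs value at j interpolated to i
            interp = obs_vals[rows][:, None, :] * R[s][None, :, :]
            with np.errstate(all="ignore"):
                med = np.nanmedian(interp, axis=2)
            for c, r in enumerate(rows):
                ages = np.nonzero(target[r])[0]
                for i in ages:
                    if np.isfinite(med[c, i]):
                        vals[r, i] = med[c, i]
                        status[r, i] = IMPUTED
                        imputed_ages[i] += 1
        report.add("imputed", meas, int(imputed_ages.sum()))
        acc = report.imputed_per_age.setdefault(meas, np.zeros(N_AGES, dtype=int))
        acc += imputed_ages
    return out


# ---------------------------------------------------------------------------
# 8: full pipeline
# ---------------------------------------------------------------------------

def run_growth_qc(
    cohort: Cohort, config: QCConfig | None = None
) -> tuple[Cohort, QCReport]:
    """Run the full longitudinal QC: preterm exclusion, unit harmonization,
    then repeated passes of outlier removal, height-decrease correction and
    imputation (two passes by default)."""
    config = config or QCConfig()
    report = QCReport()
    cur = exclude_preterm(cohort, config.preterm_threshold_days, report)
    cur = harmonize_units(cur, report)

    n_passes = config.max_passes if config.iterate_to_fixed_point else config.n_passes
    panel = None
    for p in range(n_passes):
        before_h = cur.height_status.copy()
        before_w = cur.weight_status.copy()
        cur = remove_extreme_outliers(cur, report)
        if panel is None or config.rebuild_panel_each_pass:
            panel = build_reference(cur)
        cur = flag_curve_outliers(cur, panel, report)
        cur = correct_height_decreases(
            cur, panel, report, config.decrease_iteration_cap, config.decrease_step
        )
        cur = impute_missing(cur, panel, report)
        report.passes = p + 1
        if config.iterate_to_fixed_point:
            if np.array_equal(before_h, cur.height_status) and np.array_equal(
                before_w, cur.weight_status
            ):
                break
    cur.meta["qc_passes"] = report.passes
    return cur, report


# ---------------------------------------------------------------------------
# sd-BMI
# ---------------------------------------------------------------------------

def bmi_matrix(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """BMI (kg/m^2) per child x age, and per-cell provenance codes."""
    h = cohort.usable_values("height", include_imputed=True)
    w = cohort.usable_values("weight", include_imputed=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        bmi = w / h**2
    both_obs = (cohort.height_status == OBSERVED) & (cohort.weight_status == OBSERVED)
    prov = np.where(
        np.isfinite(bmi),
        np.where(both_obs, PROV_OBSERVED, PROV_PART_IMPUTED),
        PROV_MISSING,
    ).astype(np.int8)
    return bmi, prov


def standardized_bmi(
    cohort: Cohort, return_panel: bool = False
) -> PhenotypeMatrix | tuple[PhenotypeMatrix, MeasurePanel]:
    """Compute sd-BMI: per sex x age robust standardization of BMI.

    The scaling reference at each sex x age is every child with a BMI value
    there (observed or partly imputed components); cells with fewer than
    MIN_CELL reference values are left missing.
    """
    bmi, prov = bmi_matrix(cohort)
    panel = build_measure_panel(
        bmi, cohort.sex, np.ones(cohort.n_children, dtype=bool), "bmi"
    )
    out = np.full_like(bmi, np.nan)
    for s in range(2):
        rows = cohort.sex == s
        ok = panel.usable[s]
        if ok.any():
            out[np.ix_(rows, ok)] = scale_robust(
                bmi[np.ix_(rows, ok)],
                panel.median[s, ok][None, :],
                panel.q_hi[s, ok][None, :],
                panel.q_lo[s, ok][None, :],
            )
    prov = np.where(np.isfinite(out), prov, PROV_MISSING).astype(np.int8)
    pm = PhenotypeMatrix(cohort.child_ids, out, prov)
    return (pm, panel) if return_panel else pm
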