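"""Reference panels for growth QC: medians, quantile anchors, growth ratios.

The panel drives every rule of the longitudinal QC:

* the robust standardization ``f`` maps a value to 0 at the sex/age median
  and to +/-1 at the empirical quantiles corresponding to +/-1 standard
  normal deviates (``Phi(1)`` ~ 0.8413, ``Phi(-1)`` ~ 0.1587), scaling each
  side by its own anchor distance so skewed distributions are handled;
* per-interval median growth ratios ``r_k`` support multiplicative
  interpolation of a curve from any observed anchor age;
* pooled (sex-combined) 1st/99th percentiles drive the extreme-outlier rule.

All panel statistics except the pooled percentiles are computed per sex on
the *eligible* children only: those presenting at least three non-excluded
observed values before age two (exclusive) and at least two at or after age
two (inclusive).  Imputed values never feed a panel.  Empirical quantiles
use the inverse empirical CDF with linear interpolation between order
statistics (numpy's default "linear" method).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ages import AT_AFTER_TWO, BEFORE_TWO, N_AGES
from .cohort import Cohort, MEASURES, OBSERVED

#: Standard-normal CDF at +1 / -1: the anchor quantile levels.
PHI_1 = float(norm.cdf(1.0))
PHI_M1 = float(norm.cdf(-1.0))

#: Minimum values per sex x age cell for any panel statistic.
MIN_CELL = 20


# ---------------------------------------------------------------------------
# The robust scaling transform (sign-preserving)
# ---------------------------------------------------------------------------

def scale_robust(x, m, q_hi, q_lo):
    """Quantile-anchored robust scaling.

    ``f(x) = (x - m) / (q_hi - m)`` for ``x >= m`` and
    ``(x - m) / (m - q_lo)`` for ``x < m``, so ``f(m) = 0``,
    ``f(q_hi) = 1`` and ``f(q_lo) = -1``.  Strictly increasing in ``x``.
    Accepts scalars or broadcastable arrays; NaNs propagate.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    q_hi = np.asarray(q_hi, dtype=float)
    q_lo = np.asarray(q_lo, dtype=float)
    up = q_hi - m
    dn = m - q_lo
    bad = (up <= 0) | (dn <= 0)
    if np.any(bad & np.isfinite(up) & np.isfinite(dn)):
        raise ValueError("degenerate anchors: require q_lo < m < q_hi")
    with np.errstate(invalid="ignore"):
        out = np.where(x >= m, (x - m) / up, (x - m) / dn)
    if out.ndim == 0:
        return float(out)
    return out


def extreme_outlier_bounds(values_at_age: np.ndarray) -> tuple[float, float]:
    """Bounds of the extreme-outlier rule at one age.

    Returns ``(m - 2*(m - perc_1), m + 2*(perc_99 - m))`` from the pooled
    non-missing values; values strictly outside are extreme outliers.
    Requires at least MIN_CELL values.
    """
    v = np.asarray(values_at_age, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < MIN_CELL:
        raise ValueError(f"need at least {MIN_CELL} values, got {v.size}")
    m = float(np.median(v))
    p1, p99 = np.quantile(v, [0.01, 0.99], method="linear")
    return m - 2.0 * (m - float(p1)), m + 2.0 * (float(p99) - m)


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def eligibility_mask(cohort: Cohort, measure: str) -> np.ndarray:
    """Children with >=3 observed values before age two (exclusive) and >=2
    at/after age two (inclusive), counting non-excluded observed values only."""
    obs = cohort.status(measure) == OBSERVED
    return (obs[:, BEFORE_TWO].sum(axis=1) >= 3) & (
        obs[:, AT_AFTER_TWO].sum(axis=1) >= 2
    )


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def _cell_stats(values: np.ndarray) -> tuple[float, float, float, int]:
    v = values[np.isfinite(values)]
    if v.size < MIN_CELL:
        return np.nan, np.nan, np.nan, v.size
    m = float(np.median(v))
    q_lo, q_hi = np.quantile(v, [PHI_M1, PHI_1], method="linear")
    return m, float(q_hi), float(q_lo), v.size


@dataclass
class MeasurePanel:
    """Reference statistics for one measure (height, weight, or BMI)."""

    measure: str
    median: np.ndarray        # (2, 12) per sex x age, NaN if unusable
    q_hi: np.ndarray          # (2, 12) anchor at Phi(1)
    q_lo: np.ndarray          # (2, 12) anchor at Phi(-1)
    n: np.ndarray             # (2, 12) values behind each cell
    pooled_median: np.ndarray = None  # (12,)
    perc1: np.ndarray = None          # (12,)
    perc99: np.ndarray = None         # (12,)
    pooled_n: np.ndarray = None       # (12,)
    ratio_median: np.ndarray = None   # (2, 11) median consecutive-age ratio
    log2r_median: np.ndarray = None   # (2, 11)
    log2r_qhi: np.ndarray = None      # (2, 11)
    log2r_qlo: np.ndarray = None      # (2, 11)
    interval_n: np.ndarray = None     # (2, 11)

    @property
    def usable(self) -> np.ndarray:
        return (
            np.isfinite(self.median)
            & (self.q_hi > self.median)
            & (self.q_lo < self.median)
        )

    @property
    def interval_usable(self) -> np.ndarray:
        if self.ratio_median is None:
            return np.zeros((2, N_AGES - 1), dtype=bool)
        return np.isfinite(self.ratio_median) & (self.ratio_median > 0)

    def interp_matrix(self) -> np.ndarray:
        """R[sex, i, j] such that x_{i,j} = R[s, i, j] * x_j.

        Built from cumulative log median ratios, so the forward product rule
        (j < i) and the reciprocal rule (j > i) are a single expression
        ``exp(L_i - L_j)``.  NaN where the interval path crosses an unusable
        panel cell; the diagonal is exactly 1.
        """
        R = np.full((2, N_AGES, N_AGES), np.nan)
        for s in range(2):
            ok = self.interval_usable[s]
            with np.errstate(invalid="ignore"):
                logr = np.where(ok, np.log(self.ratio_median[s]), 0.0)
            L = np.concatenate([[0.0], np.cumsum(logr)])
            # path j..i usable iff all intervals strictly between are usable
            for i in range(N_AGES):
                for j in range(N_AGES):
                    lo, hi = min(i, j), max(i, j)
                    if lo == hi:
                        R[s, i, j] = 1.0
                    elif ok[lo:hi].all():
                        R[s, i, j] = np.exp(L[i] - L[j])
        return R


def build_measure_panel(
    values: np.ndarray, sex: np.ndarray, eligible: np.ndarray, measure: str
) -> MeasurePanel:
    """Panel for one measure from a value matrix with NaN for unusable cells.

    ``values`` must already have excluded/imputed cells set to NaN; pooled
    extreme-outlier percentiles are computed across sexes on all children
    (no eligibility restriction), everything else per sex on eligible
    children only.
    """
    median = np.full((2, N_AGES), np.nan)
    q_hi = np.full((2, N_AGES), np.nan)
    q_lo = np.full((2, N_AGES), np.nan)
    n = np.zeros((2, N_AGES), dtype=int)
    for s in range(2):
        sub = values[(sex == s) & eligible]
        for i in range(N_AGES):
            median[s, i], q_hi[s, i], q_lo[s, i], n[s, i] = _cell_stats(sub[:, i])

    pooled_median = np.full(N_AGES, np.nan)
    perc1 = np.full(N_AGES, np.nan)
    perc99 = np.full(N_AGES, np.nan)
    pooled_n = np.zeros(N_AGES, dtype=int)
    for i in range(N_AGES):
        v = values[:, i]
        v = v[np.isfinite(v)]
        pooled_n[i] = v.size
        if v.size >= MIN_CELL:
            pooled_median[i] = np.median(v)
            perc1[i], perc99[i] = np.quantile(v, [0.01, 0.99], method="linear")

    ratio_median = np.full((2, N_AGES - 1), np.nan)
    l2_median = np.full((2, N_AGES - 1), np.nan)
    l2_qhi = np.full((2, N_AGES - 1), np.nan)
    l2_qlo = np.full((2, N_AGES - 1), np.nan)
    interval_n = np.zeros((2, N_AGES - 1), dtype=int)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = values[:, 1:] / values[:, :-1]
    for s in range(2):
        sub = ratios[(sex == s) & eligible]
        for k in range(N_AGES - 1):
            r = sub[:, k]
            r = r[np.isfinite(r) & (r > 0)]
            interval_n[s, k] = r.size
            if r.size >= MIN_CELL:
                ratio_median[s, k] = np.median(r)
                l2 = np.log2(r)
                l2_median[s, k] = np.median(l2)
                l2_qlo[s, k], l2_qhi[s, k] = np.quantile(
                    l2, [PHI_M1, PHI_1], method="linear"
                )
    return MeasurePanel(
        measure, median, q_hi, q_lo, n,
        pooled_median, perc1, perc99, pooled_n,
        ratio_median, l2_median, l2_qhi, l2_qlo, interval_n,
    )


@dataclass
class ReferencePanel:
    """Height and weight panels plus the per-measure eligibility masks."""

    panels: dict                     # measure -> MeasurePanel
    eligible: dict                   # measure -> (n_children,) bool

    def __getitem__(self, measure: str) -> MeasurePanel:
        return self.panels[measure]

    # ---- serialization -----------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        rows = []
        for meas, p in self.panels.items():
            for s in range(2):
                for i in range(N_AGES):
                    rows.append(
                        dict(measure=meas, kind="age", sex=s, index=i,
                             median=p.median[s, i], q_hi=p.q_hi[s, i],
                             q_lo=p.q_lo[s, i], n=p.n[s, i]))
                for k in range(N_AGES - 1):
                    rows.append(
                        dict(measure=meas, kind="interval", sex=s, index=k,
                             median=p.ratio_median[s, k],
                             q_hi=p.log2r_qhi[s, k], q_lo=p.log2r_qlo[s, k],
                             l2_median=p.log2r_median[s, k],
                             n=p.interval_n[s, k]))
            for i in range(N_AGES):
                rows.append(
                    dict(measure=meas, kind="pooled", sex=-1, index=i,
                         median=p.pooled_median[i], q_lo=p.perc1[i],
                         q_hi=p.perc99[i], n=p.pooled_n[i]))
        return pd.DataFrame(rows)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "ReferencePanel":
        panels = {}
        for meas, sub in df.groupby("measure"):
            p = MeasurePanel(
                meas,
                np.full((2, N_AGES), np.nan), np.full((2, N_AGES), np.nan),
                np.full((2, N_AGES), np.nan), np.zeros((2, N_AGES), dtype=int),
                np.full(N_AGES, np.nan), np.full(N_AGES, np.nan),
                np.full(N_AGES, np.nan), np.zeros(N_AGES, dtype=int),
                np.full((2, N_AGES - 1), np.nan), np.full((2, N_AGES - 1), np.nan),
                np.full((2, N_AGES - 1), np.nan), np.full((2, N_AGES - 1), np.nan),
                np.zeros((2, N_AGES - 1), dtype=int),
            )
            for _, r in sub.iterrows():
                i = int(r["index"])
                if r["kind"] == "age":
                    s = int(r["sex"])
                    p.median[s, i] = r["median"]
                    p.q_hi[s, i] = r["q_hi"]
                    p.q_lo[s, i] = r["q_lo"]
                    p.n[s, i] = int(r["n"])
                elif r["kind"] == "interval":
                    s = int(r["sex"])
                    p.ratio_median[s, i] = r["median"]
                    p.log2r_qhi[s, i] = r["q_hi"]
                    p.log2r_qlo[s, i] = r["q_lo"]
                    p.log2r_median[s, i] = r.get("l2_median", np.nan)
                    p.interval_n[s, i] = int(r["n"])
                else:
                    p.pooled_median[i] = r["median"]
                    p.perc1[i] = r["q_lo"]
                    p.perc99[i] = r["q_hi"]
                    p.pooled_n[i] = int(r["n"])
            panels[meas] = p
        return cls(panels, eligible={})


def build_reference(cohort: Cohort) -> ReferencePanel:
    """Build height and weight panels from a QC-harmonized cohort.

    Uses non-excluded *observed* values only (imputed values never feed a
    panel); sex x age cells or intervals with fewer than MIN_CELL values are
    marked unusable and dependent rules are skipped by the callers.
    """
    panels, eligible = {}, {}
    for meas in MEASURES:
        elig = eligibility_mask(cohort, meas)
        vals = cohort.usable_values(meas, include_imputed=False)
        panels[meas] = build_measure_panel(vals, cohort.sex, elig, meas)
        eligible[meas] = elig
    return ReferencePanel(panels, eligible)


def interpolate_from(
    panel: MeasurePanel, x_j: float, sex: int, i: int, j: int
) -> float:
    """Interpolate the value at age ``i`` from the observed value at ``j``
    using the panel's median consecutive-age ratios (product rule forward,
    reciprocal backward; ``i == j`` is the identity)."""
    if i == j:
        return float(x_j)
    lo, hi = min(i, j), max(i, j)
    ok = panel.interval_usable[sex]
    if not ok[lo:hi].all():
        return np.nan
    with np.errstate(invalid="ignore"):
        logr = np.where(ok, np.log(panel.ratio_median[sex]), 0.0)
    L = np.concatenate([[0.0], np.cumsum(logr)])
    return float(x_j * np.exp(L[i] - L[j]))
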