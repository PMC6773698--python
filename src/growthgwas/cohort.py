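"""Cohort container: per-child growth curves with per-cell provenance.

A cohort holds height (m) and weight (kg) matrices of shape (n_children, 12)
over the fixed age grid, with a parallel integer status code per cell.  Cells
excluded by a QC rule have their value set to NaN and keep the exclusion
reason in the status matrix; excluded values never re-enter any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ages import AGE_DAYS, N_AGES

MEASURES = ("height", "weight")
SEX_LABELS = ("F", "M")  # sex code 0 = female, 1 = male

# ---- per-cell status codes -------------------------------------------------
MISSING = 0
OBSERVED = 1
IMPUTED = 2
EXC_NONPOSITIVE = 10
EXC_IMPLAUSIBLE = 11
EXC_EXTREME = 12
EXC_PEAK = 13
EXC_GAP = 14
EXC_DECREASE = 15
EXC_BOUND = 16
EXC_UNRESOLVED = 17

STATUS_LABELS = {
    MISSING: "missing",
    OBSERVED: "observed",
    IMPUTED: "imputed",
    EXC_NONPOSITIVE: "excluded:nonpositive",
    EXC_IMPLAUSIBLE: "excluded:implausible",
    EXC_EXTREME: "excluded:extreme",
    EXC_PEAK: "excluded:peak",
    EXC_GAP: "excluded:gap",
    EXC_DECREASE: "excluded:decrease",
    EXC_BOUND: "excluded:bound",
    EXC_UNRESOLVED: "excluded:unresolved-decrease",
}
LABEL_TO_STATUS = {v: k for k, v in STATUS_LABELS.items()}

# Plausibility bounds after unit harmonization.
PLAUSIBLE = {"height": (0.2, 2.5), "weight": (0.2, 120.0)}


def is_excluded(status: np.ndarray) -> np.ndarray:
    return status >= 10


@dataclass
class Cohort:
    """Growth curves for a set of children on the 12-point age grid."""

    child_ids: np.ndarray            # (n,) int or str identifiers
    sex: np.ndarray                  # (n,) int8, 0=F 1=M
    gest_age_days: np.ndarray        # (n,) float, NaN if unknown
    height: np.ndarray               # (n, 12) float, metres, NaN if absent
    weight: np.ndarray               # (n, 12) float, kilograms, NaN if absent
    height_status: np.ndarray        # (n, 12) int16 status codes
    weight_status: np.ndarray        # (n, 12) int16 status codes
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.child_ids)
        for name in ("sex", "gest_age_days"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        for name in ("height", "weight", "height_status", "weight_status"):
            if getattr(self, name).shape != (n, N_AGES):
                raise ValueError(f"{name} must have shape (n, {N_AGES})")

    # ---- accessors ---------------------------------------------------------
    @property
    def n_children(self) -> int:
        return len(self.child_ids)

    def values(self, measure: str) -> np.ndarray:
        return self.height if measure == "height" else self.weight

    def status(self, measure: str) -> np.ndarray:
        return self.height_status if measure == "height" else self.weight_status

    def usable(self, measure: str, include_imputed: bool = True) -> np.ndarray:
        """Mask of cells whose value may enter computations."""
        st = self.status(measure)
        ok = st == OBSERVED
        if include_imputed:
            ok = ok | (st == IMPUTED)
        return ok

    def usable_values(self, measure: str, include_imputed: bool = True) -> np.ndarray:
        """Values with everything non-usable set to NaN."""
        v = self.values(measure).copy()
        v[~self.usable(measure, include_imputed)] = np.nan
        return v

    def copy(self) -> "Cohort":
        return Cohort(
            child_ids=self.child_ids.copy(),
            sex=self.sex.copy(),
            gest_age_days=self.gest_age_days.copy(),
            height=self.height.copy(),
            weight=self.weight.copy(),
            height_status=self.height_status.copy(),
            weight_status=self.weight_status.copy(),
            meta=dict(self.meta),
        )

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(
            child_ids=self.child_ids[mask],
            sex=self.sex[mask],
            gest_age_days=self.gest_age_days[mask],
            height=self.height[mask],
            weight=self.weight[mask],
            height_status=self.height_status[mask],
            weight_status=self.weight_status[mask],
            meta=dict(self.meta),
        )

    # ---- cell updates ------------------------------------------------------
    def exclude(self, measure: str, rows, cols, code: int) -> None:
        """Exclude cells: NaN the value, record the reason code."""
        v, st = self.values(measure), self.status(measure)
        v[rows, cols] = np.nan
        st[rows, cols] = code

    # ---- long-format round trip -------------------------------------------
    def to_table(self) -> pd.DataFrame:
        n = self.n_children
        idx = np.repeat(np.arange(n), N_AGES)
        ages = np.tile(np.arange(N_AGES), n)
        return pd.DataFrame(
            {
                "child_id": np.asarray(self.child_ids)[idx],
                "sex": np.asarray([SEX_LABELS[s] for s in self.sex])[idx],
                "gest_age_days": self.gest_age_days[idx],
                "age_index": ages,
                "age_days": AGE_DAYS[ages],
                "height_m": self.height[idx, ages],
                "weight_kg": self.weight[idx, ages],
                "height_status": [STATUS_LABELS[c] for c in self.height_status[idx, ages]],
                "weight_status": [STATUS_LABELS[c] for c in self.weight_status[idx, ages]],
            }
        )

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "Cohort":
        ids = df["child_id"].drop_duplicates().to_numpy()
        order = {c: i for i, c in enumerate(ids)}
        n = len(ids)
        sex = np.zeros(n, dtype=np.int8)
        gest = np.full(n, np.nan)
        height = np.full((n, N_AGES), np.nan)
        weight = np.full((n, N_AGES), np.nan)
        hst = np.full((n, N_AGES), MISSING, dtype=np.int16)
        wst = np.full((n, N_AGES), MISSING, dtype=np.int16)
        rows = df["child_id"].map(order).to_numpy()
        cols = df["age_index"].to_numpy(dtype=int)
        sex[rows] = np.where(df["sex"].to_numpy() == "M", 1, 0)
        gest[rows] = df["gest_age_days"].to_numpy()
        height[rows, cols] = df["height_m"].to_numpy()
        weight[rows, cols] = df["weight_kg"].to_numpy()
        hst[rows, cols] = [LABEL_TO_STATUS[s] for s in df["height_status"]]
        wst[rows, cols] = [LABEL_TO_STATUS[s] for s in df["weight_status"]]
        return cls(ids, sex, gest, height, weight, hst, wst)
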