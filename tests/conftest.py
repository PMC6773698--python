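"""Shared fixtures: small cohorts and panels used across test modules."""

import numpy as np
import pytest

from growthgwas.ages import N_AGES
from growthgwas.cohort import Cohort, MISSING, OBSERVED
from growthgwas.reference import build_reference
from growthgwas.simulate import GROWTH_MEDIANS, SimConfig, simulate_cohort


def make_cohort(height, weight, sex=None, gest=None, ids=None):
    """Build a Cohort from raw (n, 12) value arrays; NaN = missing."""
    height = np.asarray(height, dtype=float)
    weight = np.asarray(weight, dtype=float)
    n = height.shape[0]
    sex = np.zeros(n, dtype=np.int8) if sex is None else np.asarray(sex, np.int8)
    gest = np.full(n, 282.0) if gest is None else np.asarray(gest, float)
    ids = (
        np.array([f"T{i:04d}" for i in range(n)], dtype=object)
        if ids is None else np.asarray(ids, dtype=object)
    )
    hst = np.where(np.isfinite(height), OBSERVED, MISSING).astype(np.int16)
    wst = np.where(np.isfinite(weight), OBSERVED, MISSING).astype(np.int16)
    return Cohort(ids, sex, gest, height, weight, hst, wst)


def median_cohort(n=60, sex_split=True):
    """Every child exactly on the sex median curve (both measures)."""
    sex = np.tile([0, 1], n // 2).astype(np.int8) if sex_split else np.zeros(n, np.int8)
    h = GROWTH_MEDIANS["height"][sex].astype(float)
    w = GROWTH_MEDIANS["weight"][sex].astype(float)
    return make_cohort(h.copy(), w.copy(), sex=sex)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic noisy cohort, large enough for usable panels."""
    return simulate_cohort(SimConfig(n_children=800, seed=123, preterm_prob=0.0))


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    return build_reference(small_cohort)


@pytest.fixture(scope="session")
def exact_median_cohort():
    return median_cohort(n=80)


@pytest.fixture(scope="session")
def exact_median_panel(exact_median_cohort):
    return build_reference(exact_median_cohort)
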