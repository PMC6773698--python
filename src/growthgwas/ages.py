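"""The fixed 12-point measurement age grid.

Measurements are scheduled at birth; 6 weeks; 3, 6, and 8 months; and 1, 1.5,
2, 3, 5, 7, and 8 years.  Several rules split the grid at age two: "before
two" means strictly younger than two years, "at/after two" includes the
two-year visit itself.
"""

from __future__ import annotations

import numpy as np

AGE_LABELS: tuple[str, ...] = (
    "birth", "6w", "3m", "6m", "8m", "1y", "1.5y", "2y", "3y", "5y", "7y", "8y",
)

#: Nominal age of each visit in days.
AGE_DAYS: np.ndarray = np.array(
    [0, 42, 91, 182, 243, 365, 548, 730, 1095, 1826, 2556, 2922], dtype=float
)

N_AGES: int = 12

#: Boolean mask for ages strictly before two years.
BEFORE_TWO: np.ndarray = AGE_DAYS < 730.0

#: Boolean mask for ages at or after two years.
AT_AFTER_TWO: np.ndarray = ~BEFORE_TWO

#: Interior grid indices (both neighbours exist): 1..10.
INTERIOR: np.ndarray = np.arange(1, N_AGES - 1)

assert BEFORE_TWO.sum() == 7 and AT_AFTER_TWO.sum() == 5
assert np.all(np.diff(AGE_DAYS) > 0)
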