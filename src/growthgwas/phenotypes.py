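"""Standardized-BMI phenotype matrix (children x ages) with provenance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import AGE_LABELS, N_AGES

# provenance codes per cell
PROV_MISSING = 0
PROV_OBSERVED = 1     # both BMI components observed
PROV_PART_IMPUTED = 2  # at least one component imputed


@dataclass
class PhenotypeMatrix:
    """Per-child, per-age standardized BMI (sd-BMI) values."""

    sample_ids: np.ndarray        # (n,)
    values: np.ndarray            # (n, 12), NaN = missing
    provenance: np.ndarray = None  # (n, 12) int8 codes, optional

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), N_AGES):
            raise ValueError(f"values must have shape (n, {N_AGES})")
        if self.provenance is None:
            self.provenance = np.where(
                np.isnan(self.values), PROV_MISSING, PROV_OBSERVED
            ).astype(np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "PhenotypeMatrix":
        return PhenotypeMatrix(
            self.sample_ids.copy(), self.values.copy(), self.provenance.copy()
        )

    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"sdbmi_{a}" for a in AGE_LABELS])
        df.insert(0, "child_id", self.sample_ids)
        return df

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "PhenotypeMatrix":
        cols = [f"sdbmi_{a}" for a in AGE_LABELS]
        return cls(df["child_id"].to_numpy(), df[cols].to_numpy(dtype=float))
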