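"""Genotype dosage container.

Dosages are expected effect-allele counts in [0, 2] under imputation
uncertainty; the info score is the ratio of the observed dosage variance to
the binomial variance 2p(1-p) at the observed allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ea", "oa", "eaf", "info"]


@dataclass
class GenotypeData:
    """Dosage matrix (samples x variants) with variant metadata."""

    sample_ids: np.ndarray           # (n_samples,)
    variants: pd.DataFrame           # columns VARIANT_COLUMNS
    dosages: np.ndarray              # (n_samples, n_variants), NaN = missing

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant table length does not match dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant ids must be unique")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(
                self.dosages, initial=2.0
            ) > 2.0 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not found")
        return int(idx[0])

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(variant_id)]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeData":
        return GenotypeData(
            self.sample_ids,
            self.variants.loc[np.asarray(mask)].reset_index(drop=True),
            self.dosages[:, np.asarray(mask)],
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeData":
        return GenotypeData(
            self.sample_ids[mask], self.variants.copy(), self.dosages[mask]
        )
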