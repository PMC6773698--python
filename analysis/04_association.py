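#!/usr/bin/env python
"""Stage 4: marker and sample QC on the genotypes, then per-age linear
association of sd-BMI on dosage with sex, batch and principal-component
covariates; writes one summary-statistics file per age and the list of
variants forwarded for replication."""

from growthgwas.pipeline import stage_assoc

from common import parse_config

cfg = parse_config(__doc__)
stage_assoc(cfg)
print(f"wrote sumstats/ and forwarded_variants.txt under {cfg.out_dir}")
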