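#!/usr/bin/env python
"""Stage 3: compute BMI from the cleaned cohort, standardize it per sex and
age with robust quantile anchors, and attach the simulated genetic effects
to produce the analysis phenotype (sd-BMI)."""

from growthgwas.pipeline import stage_standardize

from common import parse_config

cfg = parse_config(__doc__)
stage_standardize(cfg)
print(f"wrote sdbmi.tsv under {cfg.out_dir}")
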