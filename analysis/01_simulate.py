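#!/usr/bin/env python
"""Stage 1: draw the clean synthetic cohort, genotypes, covariates and true
effect profiles, then inject the measurement-error model to produce the raw
cohort and its truth log."""

import os

from growthgwas.pipeline import stage_corrupt, stage_simulate

from common import parse_config

cfg = parse_config(__doc__)
os.makedirs(cfg.out_dir, exist_ok=True)
stage_simulate(cfg)
stage_corrupt(cfg)
print(f"wrote clean and raw cohorts under {cfg.out_dir}")
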