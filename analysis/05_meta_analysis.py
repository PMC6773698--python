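#!/usr/bin/env python
"""Stage 5: inverse-variance meta-analysis of the packaged two-cohort lead
SNP table; reproduces the published pooled effect columns."""

import os

from growthgwas.pipeline import stage_meta

from common import parse_config

cfg = parse_config(__doc__)
os.makedirs(cfg.out_dir, exist_ok=True)
stage_meta(cfg)
print(f"wrote lead_snps_meta.tsv under {cfg.out_dir}")
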