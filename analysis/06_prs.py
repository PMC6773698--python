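#!/usr/bin/env python
"""Stage 6: polygenic score from the causal-variant weights on hard-called
genotypes, and its correlation with sd-BMI at every age."""

from growthgwas.pipeline import stage_prs

from common import parse_config

cfg = parse_config(__doc__)
stage_prs(cfg)
print(f"wrote prs_scores.tsv and prs_correlation.tsv under {cfg.out_dir}")
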