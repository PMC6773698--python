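#!/usr/bin/env python
"""Stage 2: run growth QC on the raw cohort (unit harmonization, extreme
values, curve peaks/gaps, height decreases, imputation) and write the
cleaned cohort, the QC report and the reference panel."""

from growthgwas.pipeline import stage_qc

from common import parse_config

cfg = parse_config(__doc__)
stage_qc(cfg)
print(f"wrote cohort_qc.tsv, qc_report.tsv and reference_panel.tsv under {cfg.out_dir}")
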