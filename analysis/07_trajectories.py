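#!/usr/bin/env python
"""Stage 7: genotype-stratified sd-BMI trajectories (per sex and age) for
the variants forwarded by the association stage — the transient-effect
visual of the analysis."""

import os

import pandas as pd

from growthgwas import io as gio
from growthgwas.assoc import stratified_trajectories
from growthgwas.phenotypes import PhenotypeMatrix
from growthgwas.pipeline import _align_genotypes

from common import parse_config

cfg = parse_config(__doc__)
out = cfg.out_dir
with open(os.path.join(out, "forwarded_variants.txt")) as fh:
    forwarded = [line.strip() for line in fh if line.strip()]
if not forwarded:
    print("no forwarded variants; nothing to do")
    raise SystemExit(0)

pm = PhenotypeMatrix.from_table(pd.read_csv(os.path.join(out, "sdbmi.tsv"), sep="\t"))
cohort = gio.read_cohort(os.path.join(out, "cohort_qc.tsv"))
sex = cohort.sex[pd.Index(cohort.child_ids).get_indexer(pm.sample_ids)]
geno = _align_genotypes(gio.read_vcf(os.path.join(out, "genotypes.vcf")),
                        pm.sample_ids)

frames = [stratified_trajectories(pm.values, sex, geno, [vid])
          for vid in forwarded]
pd.concat(frames).to_csv(os.path.join(out, "trajectories.tsv"),
                         sep="\t", index=False)
print(f"wrote trajectories.tsv for {len(forwarded)} variant(s) under {out}")
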