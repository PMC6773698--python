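"""Shared argument handling for the numbered analysis scripts.

Every script accepts ``--config`` (YAML run configuration), ``--seed`` and
``--out`` and builds the same :class:`growthgwas.pipeline.RunConfig`, so a
run can be executed stage by stage or end to end with identical results.
"""

import argparse

from growthgwas.pipeline import RunConfig


def parse_config(description: str) -> RunConfig:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--config", help="YAML run configuration file")
    ap.add_argument("--seed", type=int, help="master seed (overrides config)")
    ap.add_argument("--out", help="output directory (default results/run)")
    args = ap.parse_args()
    cfg = RunConfig.from_yaml(args.config) if args.config else RunConfig()
    if args.seed is not None:
        cfg.seed = args.seed
    if args.out is not None:
        cfg.out_dir = args.out
    cfg.validate()
    return cfg
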