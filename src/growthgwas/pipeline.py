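"""End-to-end pipeline: simulate -> corrupt -> QC -> standardize -> associate
-> meta -> PRS, with a content-hashed artifact manifest.

Every stage reads its predecessor's files from the run directory, so stages
can be re-run individually; all randomness flows from one master seed with
per-stage child seeds derived deterministically.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import AGE_LABELS, N_AGES
from . import io as gio
from .assoc import forward_variants, marker_sample_qc, run_assoc
from .cohort import Cohort
from .genotypes import GenotypeData
from .meta_prs import (
    PRSModel, compute_prs, load_lead_snp_table, meta_table, prs_correlation,
)
from .phenotypes import PhenotypeMatrix
from .qc import QCConfig, run_growth_qc, standardized_bmi, bmi_matrix
from .simulate import (
    EffectProfile, ErrorConfig, SimConfig, attach_genetic_effects,
    inject_errors, simulate_cohort, simulate_covariates, simulate_genotypes,
)

STAGES = ("simulate", "corrupt", "qc", "standardize", "assoc", "meta", "prs")

#: files each stage produces (relative to the run directory)
STAGE_OUTPUTS = {
    "simulate": ["cohort_clean.tsv", "genotypes.vcf", "covariates.tsv",
                 "effects_true.tsv"],
    "corrupt": ["cohort_raw.tsv", "truth_log.tsv"],
    "qc": ["cohort_qc.tsv", "qc_report.tsv", "reference_panel.tsv"],
    "standardize": ["sdbmi.tsv"],
    "assoc": ["assoc_report.json", "forwarded_variants.txt"]
    + [f"sumstats/assoc_{a}.tsv" for a in AGE_LABELS],
    "meta": ["lead_snps_meta.tsv"],
    "prs": ["prs_scores.tsv", "prs_correlation.tsv"],
}

#: files each stage needs before it can run
STAGE_INPUTS = {
    "simulate": [],
    "corrupt": ["cohort_clean.tsv"],
    "qc": ["cohort_raw.tsv"],
    "standardize": ["cohort_qc.tsv"],
    "assoc": ["sdbmi.tsv", "genotypes.vcf", "covariates.tsv"],
    "meta": [],
    "prs": ["sdbmi.tsv", "genotypes.vcf", "effects_true.tsv"],
}


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 1
    stages: tuple = STAGES
    # simulation
    n_children: int = 5000
    n_variants: int = 500
    causal: list = field(default_factory=lambda: [
        # (age-profile template) LEPR-like infancy peak, LEP-like toddler
        # peak, FTO-like late-childhood rise
        {"variant_id": "causal_infancy", "eaf": 0.16, "peak_age": 3,
         "peak_beta": 0.162, "width": 2.0},
        {"variant_id": "causal_toddler", "eaf": 0.49, "peak_age": 6,
         "peak_beta": 0.079, "width": 2.0},
        {"variant_id": "causal_late", "eaf": 0.44, "peak_age": 10,
         "peak_beta": 0.117, "width": 2.5},
    ])
    sim_overrides: dict = field(default_factory=dict)
    error_overrides: dict = field(default_factory=dict)
    # thresholds (defaults mirror the published analysis)
    forwarding_p: float = 1e-7
    info_threshold: float = 0.7
    call_rate_threshold: float = 0.98
    hwe_threshold: float = 1e-6
    het_excess_sd: float = 4.0
    preterm_threshold_days: int = 259
    qc_passes: int = 2
    prs_weights_file: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key: {k}")
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if not 0 < self.info_threshold < 1 or not 0 < self.call_rate_threshold <= 1:
            raise ValueError("thresholds out of range")
        if not 0 < self.hwe_threshold < 1 or self.het_excess_sd <= 0:
            raise ValueError("thresholds out of range")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2^31."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def validate_inputs(config: RunConfig) -> None:
    """Every enabled stage must get its inputs from an earlier enabled stage
    or from files already present in the run directory."""
    produced: set[str] = set()
    for s in config.stages:
        for req in STAGE_INPUTS[s]:
            if req in produced:
                continue
            if not os.path.exists(os.path.join(config.out_dir, req)):
                raise FileNotFoundError(
                    f"stage '{s}' requires {req}, which no enabled stage "
                    "produces and which does not exist"
                )
        produced.update(STAGE_OUTPUTS[s])


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _profiles_from_config(config: RunConfig, rng: np.random.Generator) -> list[EffectProfile]:
    profiles = []
    for prof in config.causal:
        ages = np.arange(N_AGES)
        betas = prof["peak_beta"] * np.exp(
            -0.5 * ((ages - prof["peak_age"]) / prof["width"]) ** 2
        )
        if prof.get("monotone_late"):
            betas[ages > prof["peak_age"]] = prof["peak_beta"]
        profiles.append(
            EffectProfile(prof["variant_id"], prof["eaf"], betas,
                          dosage_noise_sd=prof.get("dosage_noise_sd", 0.05))
        )
    n_null = config.n_variants - len(profiles)
    eafs = rng.uniform(0.05, 0.95, n_null)
    noise = rng.uniform(0.0, 0.3, n_null)
    for k in range(n_null):
        profiles.append(
            EffectProfile(f"null_{k:05d}", float(eafs[k]), np.zeros(N_AGES),
                          dosage_noise_sd=float(noise[k]))
        )
    return profiles


def _write_profiles(profiles: list[EffectProfile], path: str) -> None:
    rows = []
    for p in profiles:
        row = {"variant_id": p.variant_id, "eaf": p.eaf,
               "dosage_noise_sd": p.dosage_noise_sd}
        for a, label in enumerate(AGE_LABELS):
            row[f"beta_{label}"] = p.effects[a]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_profiles(path: str) -> list[EffectProfile]:
    df = pd.read_csv(path, sep="\t")
    cols = [f"beta_{a}" for a in AGE_LABELS]
    return [
        EffectProfile(r["variant_id"], r["eaf"], r[cols].to_numpy(dtype=float),
                      r["dosage_noise_sd"])
        for _, r in df.iterrows()
    ]


def _align_genotypes(genotypes: GenotypeData, sample_ids: np.ndarray) -> GenotypeData:
    pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
    idx = np.array([pos[s] for s in sample_ids])
    return GenotypeData(
        genotypes.sample_ids[idx], genotypes.variants.copy(), genotypes.dosages[idx]
    )


def stage_simulate(config: RunConfig) -> None:
    out = config.out_dir
    rng = np.random.default_rng(config.stage_seed("profiles"))
    sim = SimConfig(n_children=config.n_children,
                    seed=config.stage_seed("cohort"), **config.sim_overrides)
    cohort = simulate_cohort(sim)
    gio.write_cohort(cohort, os.path.join(out, "cohort_clean.tsv"), seed=sim.seed)

    profiles = _profiles_from_config(config, rng)
    genotypes = simulate_genotypes(
        config.n_children, profiles, seed=config.stage_seed("genotypes"),
        sample_ids=cohort.child_ids,
    )
    gio.write_vcf(genotypes, os.path.join(out, "genotypes.vcf"),
                  seed=config.stage_seed("genotypes"))
    _write_profiles(profiles, os.path.join(out, "effects_true.tsv"))

    cov = simulate_covariates(config.n_children,
                              seed=config.stage_seed("covariates"),
                              sex=cohort.sex)
    cov.insert(0, "child_id", cohort.child_ids)
    cov.to_csv(os.path.join(out, "covariates.tsv"), sep="\t", index=False)


def stage_corrupt(config: RunConfig) -> None:
    out = config.out_dir
    cohort = gio.read_cohort(os.path.join(out, "cohort_clean.tsv"))
    err = ErrorConfig(seed=config.stage_seed("errors"), **config.error_overrides)
    corrupted, log = inject_errors(cohort, err)
    gio.write_cohort(corrupted, os.path.join(out, "cohort_raw.tsv"),
                     seed=err.seed)
    log.to_csv(os.path.join(out, "truth_log.tsv"), sep="\t", index=False)


def stage_qc(config: RunConfig) -> None:
    out = config.out_dir
    cohort = gio.read_cohort(os.path.join(out, "cohort_raw.tsv"))
    qc_cfg = QCConfig(preterm_threshold_days=config.preterm_threshold_days,
                      n_passes=config.qc_passes)
    cleaned, report = run_growth_qc(cohort, qc_cfg)
    gio.write_cohort(cleaned, os.path.join(out, "cohort_qc.tsv"))
    report.to_frame().to_csv(os.path.join(out, "qc_report.tsv"), sep="\t",
                             index=False)
    from .reference import build_reference

    build_reference(cleaned).to_table().to_csv(
        os.path.join(out, "reference_panel.tsv"), sep="\t", index=False
    )


def stage_standardize(config: RunConfig) -> None:
    out = config.out_dir
    cohort = gio.read_cohort(os.path.join(out, "cohort_qc.tsv"))
    pm = standardized_bmi(cohort)
    effects_path = os.path.join(out, "effects_true.tsv")
    geno_path = os.path.join(out, "genotypes.vcf")
    if os.path.exists(effects_path) and os.path.exists(geno_path):
        profiles = [p for p in _read_profiles(effects_path) if p.effects.any()]
        if profiles:
            genotypes = _align_genotypes(gio.read_vcf(geno_path), pm.sample_ids)
            pm = attach_genetic_effects(pm, genotypes, profiles)
    pm.to_table().to_csv(os.path.join(out, "sdbmi.tsv"), sep="\t", index=False)


def stage_assoc(config: RunConfig) -> None:
    out = config.out_dir
    pm = PhenotypeMatrix.from_table(
        pd.read_csv(os.path.join(out, "sdbmi.tsv"), sep="\t")
    )
    genotypes = gio.read_vcf(os.path.join(out, "genotypes.vcf"))
    genotypes, qc_report = marker_sample_qc(
        genotypes, config.call_rate_threshold, config.hwe_threshold,
        config.het_excess_sd,
    )
    cov = pd.read_csv(os.path.join(out, "covariates.tsv"), sep="\t")
    cov = cov.set_index("child_id").loc[pm.sample_ids].reset_index(drop=True)
    keep = np.isin(pm.sample_ids, genotypes.sample_ids)
    pm = PhenotypeMatrix(pm.sample_ids[keep], pm.values[keep])
    cov = cov.loc[keep].reset_index(drop=True)
    genotypes = _align_genotypes(genotypes, pm.sample_ids)

    result = run_assoc(pm, genotypes, cov)
    gio.write_summary_stats(result, os.path.join(out, "sumstats"))
    forwarded = forward_variants(result, config.forwarding_p)
    with open(os.path.join(out, "forwarded_variants.txt"), "w") as fh:
        fh.write("\n".join(forwarded) + ("\n" if forwarded else ""))
    with open(os.path.join(out, "assoc_report.json"), "w") as fh:
        json.dump({"marker_sample_qc": qc_report,
                   "n_forwarded": len(forwarded)}, fh, indent=2)


def stage_meta(config: RunConfig) -> None:
    table = meta_table(load_lead_snp_table())
    table.to_csv(os.path.join(config.out_dir, "lead_snps_meta.tsv"),
                 sep="\t", index=False, float_format="%.6g")


def stage_prs(config: RunConfig) -> None:
    out = config.out_dir
    pm = PhenotypeMatrix.from_table(
        pd.read_csv(os.path.join(out, "sdbmi.tsv"), sep="\t")
    )
    genotypes = _align_genotypes(
        gio.read_vcf(os.path.join(out, "genotypes.vcf")), pm.sample_ids
    )
    if config.prs_weights_file:
        weights = pd.read_csv(config.prs_weights_file, sep="\t")
        model = PRSModel.from_table(weights, config.info_threshold)
    else:
        # weights = true simulated effects at each causal variant's peak age
        profiles = [
            p for p in _read_profiles(os.path.join(out, "effects_true.tsv"))
            if p.effects.any()
        ]
        gvars = genotypes.variants.set_index("id")
        model = PRSModel(
            np.array([p.variant_id for p in profiles], dtype=object),
            np.array([gvars.loc[p.variant_id, "ea"] for p in profiles],
                     dtype=object),
            np.array([p.effects.max() for p in profiles]),
            config.info_threshold,
        )
    scores, report = compute_prs(genotypes, model)
    pd.DataFrame({"child_id": pm.sample_ids, "prs": scores}).to_csv(
        os.path.join(out, "prs_scores.tsv"), sep="\t", index=False
    )
    corr = prs_correlation(scores, pm)
    corr.to_csv(os.path.join(out, "prs_correlation.tsv"), sep="\t", index=False)


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "corrupt": stage_corrupt,
    "qc": stage_qc,
    "standardize": stage_standardize,
    "assoc": stage_assoc,
    "meta": stage_meta,
    "prs": stage_prs,
}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in order and write a content-hashed manifest.

    A stage failure halts the run with the stage named; files produced so
    far are retained and listed in ``MANIFEST.partial``.  Rerunning with the
    same config and seed reproduces identical content hashes.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    os.makedirs(os.path.join(config.out_dir, "sumstats"), exist_ok=True)
    validate_inputs(config)

    completed = []
    try:
        for stage in config.stages:
            STAGE_FUNCS[stage](config)
            completed.append(stage)
    except Exception as exc:
        manifest = _build_manifest(config, completed)
        with open(os.path.join(config.out_dir, "MANIFEST.partial"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    manifest = _build_manifest(config, completed)
    with open(os.path.join(config.out_dir, "MANIFEST.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _build_manifest(config: RunConfig, completed: list[str]) -> dict:
    files = {}
    for stage in completed:
        for rel in STAGE_OUTPUTS[stage]:
            path = os.path.join(config.out_dir, rel)
            if os.path.exists(path):
                files[rel] = _sha256(path)
    return {"seed": config.seed, "stages": completed, "files": files}
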