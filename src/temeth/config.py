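"""Run configuration: defaults, validation, serialisation.

``DEFAULTS`` centralises every analysis constant, including the
study-derived thresholds: identity cutoffs 0.8 (within genome) and 0.6
(cross species) for subfamily clustering, DMR delta 0.2 over >= 5 CGs at
p < 0.01, site-distribution coverage >= 10, read-level epialleles at >= 5
CGs per read, TE transcription filter 0.5 TPM with mean coverage > 2 per
cytosine, and the Ka/Ks purifying-selection cutoff 0.2.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

from . import __version__

DEFAULTS: dict = {
    "simulate": {
        "genome_length": 200_000,
        "n_genes": 20,
        "cg_level": 0.7,
        "ch_level": 0.01,
        "ch_te_3prime_bias": 5.0,
        "heterogeneity": 2.0,
        "non_conversion": 0.005,
        "coverage": 30.0,
        "read_length": 100,
    },
    "call": {
        "min_mapq": 10,
        "min_opposite_g": 0.8,
        "min_opposite_cov": 3,
        "control_contig": "lambda_control",
    },
    "analyze": {
        "site_min_cov": 10,
        "read_min_cg": 5,
        "symmetry_min_cov": 10,
        "body_bins": 20,
        "flank_bp": 1000,
        "flank_bins": 10,
        "tpm_threshold": 0.5,
        "te_min_mean_cov": 2.0,
        "tail_fraction": 0.25,
        "enrichment_fold": 2.0,
    },
    "dmr": {
        "min_delta": 0.2,
        "min_cg": 5,
        "p_threshold": 0.01,
        "min_cov": 4.0,
        "max_gap": 300,
    },
    "te_structure": {
        "min_aa": 100,
        "min_repeat": 100,
        "min_identity": 0.8,
        "oe_mode": "frequency",
    },
    "evolution": {
        "within_identity": 0.8,
        "cross_identity": 0.6,
        "kaks_purifying_cutoff": 0.2,
        "n_subfamilies": 40,
        "loss_prob": 0.25,
        "kaks_omegas": [0.1, 0.5, 1.0],
        "kaks_pairs": 30,
        "kaks_codons": 150,
    },
}

STAGES = ("simulate", "call", "analyze", "dmr", "te_structure", "evolution")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 1
    outdir: str = "results/run"
    log_level: str = "INFO"
    stages: tuple = STAGES
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
        for stage, over in self.params.items():
            if stage not in DEFAULTS:
                raise ValueError(f"unknown parameter section {stage!r}")
            bad = set(over) - set(DEFAULTS[stage])
            if bad:
                raise ValueError(
                    f"unknown keys in params.{stage}: {sorted(bad)}")

    def effective(self, stage: str) -> dict:
        merged = copy.deepcopy(DEFAULTS[stage])
        merged.update(self.params.get(stage, {}))
        return merged


def load_config(path: str) -> RunConfig:
    """Read a YAML run configuration, rejecting unknown keys."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
    known = {"seed", "outdir", "log_level", "stages", "params", "inputs"}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"{path}: unknown top-level keys {sorted(bad)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


def write_config(config: RunConfig, path: str) -> None:
    data = {"seed": config.seed, "outdir": config.outdir,
            "log_level": config.log_level, "stages": list(config.stages),
            "params": config.params, "inputs": config.inputs}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def report_skeleton(config: RunConfig) -> dict:
    return {
        "tool": "temeth",
        "version": __version__,
        "seed": config.seed,
        "parameters": {s: config.effective(s) for s in config.stages
                       if s in DEFAULTS},
        "results": {},
    }
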