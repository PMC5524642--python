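"""Layered run configuration for the end-to-end pipeline.

A run is described by a nested YAML document; unspecified keys fall back to
defaults, unknown keys are a validation error (listing the offending keys).
All randomness flows from named per-stage seeds derived deterministically
from one master seed, and the fully resolved configuration is written into
the output directory for provenance.
"""

from __future__ import annotations

import copy
from typing import Any, Dict, List, Optional

import numpy as np
import yaml

DEFAULTS: Dict[str, Any] = {
    "seed": 0,
    "barcodes": {"n": 96, "k": 8, "min_distance": 3, "max_homopolymer": 3},
    "transcriptome": {
        "n_genes": 60,
        "iso_per_gene": 2,
        "length_min": 300,
        "length_max": 1000,
        "n_spikeins": 0,
    },
    "plate": {
        # seven perturbagens plus a vehicle at 12 replicates = 96 wells
        "conditions": ["drug1", "drug2", "drug3", "drug4", "drug5", "drug6", "drug7"],
        "vehicle": "DMSO",
        "replicates": 12,
        "planted_lfc": 2.0,
        "planted_genes_per_condition": 3,
        "planted_regulator_condition": "drug1",
        "planted_regulator_magnitude": -1.5,
    },
    "regulons": {"n_regulons": 20, "targets_per_regulon": 15},
    "counts": {"base_mean": 50.0, "dispersion": 0.1, "reads_per_well": 1500},
    "reads": {
        "read1_len": 26,
        "read2_len": 66,
        "sub_error_rate": 0.005,
        "frag_window": 250,
    },
    "demux": {"max_distance": 1, "mode": "hamming"},
    "align": {"seed_len": 16, "match": 1, "mismatch": 1},
    "qc": {"min_count": 1, "fractions": [round(f, 2) for f in np.arange(0.1, 1.01, 0.1)],
           "n_reps": 5},
    "signatures": {"pseudocount": 1.0, "top_k": 40, "mds_dims": 2},
    "activity": {"min_size": 10},
    "noise": {"pseudocount": 1.0, "cv_ddof": 1},
}

_STAGES = [
    "simulate",
    "align",
    "count",
    "qc",
    "signatures",
    "activity",
    "noise",
]


class ConfigError(ValueError):
    pass


def _merge(base: Dict[str, Any], override: Dict[str, Any], path: str = "") -> List[str]:
    """Merge override into base in place; return unknown key paths."""
    unknown: List[str] = []
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            unknown.append(here)
            continue
        if isinstance(base[key], dict) and isinstance(value, dict):
            unknown.extend(_merge(base[key], value, here))
        else:
            base[key] = value
    return unknown


def load_config(path: Optional[str] = None, overrides: Optional[Dict[str, Any]] = None) -> Dict[str, Any]:
    """Resolve a run configuration from YAML plus programmatic overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    unknown: List[str] = []
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        unknown.extend(_merge(cfg, doc))
    if overrides:
        unknown.extend(_merge(cfg, overrides))
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    validate_config(cfg)
    return cfg


def validate_config(cfg: Dict[str, Any]) -> None:
    problems = []
    n_wells = (len(cfg["plate"]["conditions"]) + 1) * cfg["plate"]["replicates"]
    if cfg["barcodes"]["n"] < n_wells:
        problems.append(
            f"barcodes.n={cfg['barcodes']['n']} < {n_wells} wells implied by plate"
        )
    if cfg["transcriptome"]["length_min"] < cfg["reads"]["read2_len"]:
        problems.append("transcriptome.length_min shorter than reads.read2_len")
    if cfg["reads"]["frag_window"] < cfg["reads"]["read2_len"]:
        problems.append("reads.frag_window must be >= reads.read2_len")
    for f in cfg["qc"]["fractions"]:
        if not 0 < f <= 1:
            problems.append(f"qc.fractions entry {f} outside (0, 1]")
    if problems:
        raise ConfigError("; ".join(problems))


def stage_seeds(master_seed: int) -> Dict[str, int]:
    """Named per-stage seeds derived deterministically from the master seed."""
    return {
        stage: int(
            np.random.SeedSequence([int(master_seed), i]).generate_state(1)[0]
            % (2**31)
        )
        for i, stage in enumerate(_STAGES)
    }


def dump_config(cfg: Dict[str, Any], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
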