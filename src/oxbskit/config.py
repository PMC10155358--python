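"""Run configuration: defaults, YAML loading, validation.

Every tunable of the pipeline appears here with its default, so a config
file only needs to state deviations.  ``mode`` selects between simulating
a cohort and ingesting methratio TSVs listed in a sample sheet.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
from typing import Any, Mapping

import yaml

DEFAULT_CONFIG: dict[str, Any] = {
    "mode": "simulate",  # simulate | ingest
    "seed": 0,
    "simulate": {
        "n_chromosomes": 2,
        "cpgs_per_chromosome": 400,
        "spacing": "clustered",
        "n_per_group": 8,
        "coverage_mean": 30.0,
        "coverage_dispersion": 5.0,
        "chemistry": {"eps_fail": 0.005, "eps_over": 0.005, "eta_ox": 0.95},
        "sample_effect_sd": 0.0,
        "per_sample_heterogeneity": False,
        # planted effects: evenly spaced regions of region_cpgs CpGs each
        "effects": {
            "n_5mc_regions": 4,
            "delta_5mc": 0.3,
            "n_5hmc_regions": 4,
            "delta_5hmc": 0.15,
            "coupling": 0.0,
            "region_cpgs": 8,
        },
    },
    "ingest": {
        "sample_sheet": None,  # CSV: sample_id, path_bs, path_ox, group cols
        "gene_model": None,    # BED12; optional
    },
    "contrast": {
        "name": "case-vs-control",
        "group_column": "group",       # column holding case/control labels
        "expression_column": None,     # set to use a median split instead
    },
    "estimation": {"min_cov": 5, "hmc_mode": "raw"},
    "segmentation": {
        "max_gap": 300,
        "min_cpg": 5,
        "min_group_presence": 0.8,
        "split_gain": 0.05,
    },
    "thresholds": {"diff_5mc": 0.2, "diff_5hmc": 0.1, "diff_bs": 0.2, "q": 0.05},
    "annotation": {
        "promoter_upstream": 1000,
        "promoter_downstream": 100,
        "tts_upstream": 100,
        "tts_downstream": 1000,
    },
    "screen": {"auc_cutoff": 0.8, "min_sample_frac": 0.8},
    "marks": ["5mC", "5hmC", "BS"],
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(source: str | Mapping | None = None) -> dict:
    """Merge a YAML file or mapping over the defaults and validate."""
    if source is None:
        cfg = copy.deepcopy(DEFAULT_CONFIG)
    elif isinstance(source, Mapping):
        cfg = _deep_merge(DEFAULT_CONFIG, source)
    else:
        with open(source) as fh:
            cfg = _deep_merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping) -> None:
    if cfg["mode"] not in ("simulate", "ingest"):
        raise ValueError(f"unknown mode {cfg['mode']!r}")
    th = cfg["thresholds"]
    for key in ("diff_5mc", "diff_5hmc", "diff_bs", "q"):
        if th[key] <= 0:
            raise ValueError(f"threshold {key} must be positive")
    if cfg["estimation"]["hmc_mode"] not in ("raw", "clamp", "mle"):
        raise ValueError("estimation.hmc_mode must be raw/clamp/mle")
    if cfg["mode"] == "ingest":
        sheet = cfg["ingest"]["sample_sheet"]
        if not sheet or not os.path.exists(sheet):
            raise ValueError("ingest mode needs an existing ingest.sample_sheet")
        gm = cfg["ingest"]["gene_model"]
        if gm and not os.path.exists(gm):
            raise ValueError(f"gene model not found: {gm}")


def config_hash(cfg: Mapping) -> str:
    """Stable hash of the fully-merged config, for the run manifest."""
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
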