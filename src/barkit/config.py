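"""Run configuration: one validated document of module defaults.

Unknown keys are rejected (typos should fail loudly); every run can echo
its resolved configuration, including all seeds, into a JSON manifest so
any output is reproducible from (inputs, manifest).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .cassette import DEFAULT_MASK

__all__ = ["default_config", "load_config", "merge_config", "ConfigError"]


class ConfigError(ValueError):
    pass


def default_config() -> dict[str, Any]:
    return {
        "seed": 0,
        "barcode": {
            "mask": DEFAULT_MASK,
        },
        "cassette": {
            "atgless_lambda_len": 250,
            "promoter_len": 240,
            "pad_len": 6,
            "ura4_len": 1497,
            "sfi_spacer_left": "AGGTT",
            "sfi_spacer_right": "AGGTT",
            "ura4_ecorv_offset": 1000,
            "backbone_seed": 7,
        },
        "oligomer": {
            "chain_extend_prob": 0.69,
            "max_chain": 30,
            "junction_mismatches": 1,
            "max_template_mismatches": 2,
            "size_select_min_bp": 300,
            "size_select_max_bp": 1000,
        },
        "census": {
            "max_edit": 4,
            "ratio": 2.0,
            "pseudocount": 0.5,
            "depleted_at": -2.0,
            "enriched_at": 2.0,
            "wilson_level": 0.95,
        },
        "mapping": {
            "max_product_bp": 3000,
            "isp_max_product_bp": 5000,
            "circularization_cap_bp": 20000,
            "adaptor_len": 30,
            "anchor_len": 8,
            "exact_threshold": 30,
            "min_seed": 20,
            "max_genomic_deletion": 5,
        },
        "toy_genome": {
            "n_nuclear": 3,
            "chrom_length": 120000,
            "mito_length": 20000,
            "coding_fraction": 0.57,
            "gene_length_mean": 2000.0,
        },
        "library": {
            "structure_mix": {
                "single": 0.15,
                "tandem_head_to_tail": 0.55,
                "head_to_head": 0.075,
                "tail_to_tail": 0.075,
                "mito_cointegrant": 0.15,
            },
        },
    }


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any], path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(base[key], Mapping) and isinstance(val, Mapping):
            out[key] = merge_config(base[key], val, where)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None) -> dict[str, Any]:
    cfg = default_config()
    if path is None:
        return cfg
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if data is None:
        return cfg
    if not isinstance(data, Mapping):
        raise ConfigError("config file must contain a mapping")
    return merge_config(cfg, data)
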