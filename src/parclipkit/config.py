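"""Pipeline configuration: YAML in, fully-resolved YAML beside the outputs.

Unknown keys are rejected so a typo in a parameter name fails loudly
instead of silently running with a default.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "parclip_run",
    "log_level": "INFO",
    "dialect": "tsv",
    "simulate": {
        "n_transcripts": 300,
        "fraction_targets": 0.3,
        "region_lengths": [120, 900, 240],
        "base_composition": [0.25, 0.25, 0.25, 0.25],
        "motif_first": "CUUC",
        "motif_second": "CACC",
        "spacer_nt": 5,
        "tandems_per_target": 2,
        "reads_per_site": 30.0,
        "background_read_rate": 1.0,
        "conversion_prob": 0.2,
        "background_conversion_prob": None,
        "read_length_mean": 32.0,
        "read_length_sd": 6.0,
        "n_replicates": 2,
        "secretome_slope": 0.5,
        "secretome_noise_sd": 0.2,
        "lfq_samples_per_group": 4,
        "counts_dispersion": 0.05,
        "nontarget_shift_fraction": 0.0,
    },
    "sites": {
        "min_cluster_reads": 5,
        "min_conversion_reads": 2,
        "min_site_len": 8,
        "kde_bandwidth": 3.0,
        "min_target_reads": 4,
        "metagene_bins": 20,
    },
    "motif": {
        "k": 4,
        "window": 20,
        "n_shuffles": 200,
        "shuffle_mode": "mono",
        "top_kmers": 2,
        "max_spacer": 8,
        "site_flank": 8,
        "background_orfs": 150,
    },
    "integrate": {
        "s0": 0.5,
        "n_perm": 250,
        "fdr": 0.01,
        "top_n": 100,
        "expression_floor": 2.0,
        "missing_cap": 0.5,
    },
}


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve a run configuration: defaults <- YAML file <- overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True, default_flow_style=False)


def show_defaults() -> str:
    return yaml.safe_dump(DEFAULTS, sort_keys=True, default_flow_style=False)
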