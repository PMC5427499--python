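"""YAML configuration loading for the CLI and pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml

DEMO_CONFIG: dict = {
    "seed": 1,
    "genome": {
        "n_chromosomes": 2,
        "chromosome_length": 300_000,
        "centromere_fraction": 0.45,
        "essential_gene_spacing": 45_000,
    },
    "simulate": {
        "n_strains": 5,
        "n_loci": 20,
        "p_duplication": 0.4,
        "p_subtelomeric": 0.5,
        "base_depth": 30.0,
    },
    "genes": {"mean_length": 1400, "mean_gap": 600},
    "calling": {"window": 250, "min_windows": 2, "alpha": 0.05},
    "context": {"subtel_span": 25_000, "peri_flank": 7_000},
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config; ``None`` returns the built-in demo config."""
    if path is None:
        return dict(DEMO_CONFIG)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
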