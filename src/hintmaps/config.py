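"""Pipeline configuration with the study's default parameters.

Every tunable the pipeline exposes lives here with its default; YAML files
may override any subset of keys.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Residue types the interaction-map library covers.
SUPPORTED_RESIDUES = ("ALA", "ILE", "LEU", "PRO", "VAL")

#: Maximum k for k-means per residue type (per chess square / parse).
K_MAX = {"ALA": 4, "ILE": 9, "LEU": 9, "PRO": 6, "VAL": 9}

#: Bins with at most this many maps are averaged, not clustered.
SMALL_BIN_MAX = 4

#: Ramachandran chessboard grid shifts (phi, psi) in degrees.
GRID_SHIFTS = {
    "ALA": (-20.0, -25.0),
    "ILE": (-20.0, -25.0),
    "LEU": (-20.0, -25.0),
    "VAL": (-20.0, -25.0),
    "PRO": (-35.0, -5.0),
}


@dataclass
class PipelineConfig:
    # structures_io
    lipid_names: tuple[str, ...] = ("DPPC", "DPP", "PC")
    water_names: tuple[str, ...] = ("HOH", "WAT")
    trim_cutoff: float = 6.0          # Å, whole-lipid retention distance
    protonate: bool = True

    # hint_core
    pair_cutoff: float = 8.0          # Å, residue-environment pair cutoff
    lj_enabled: bool = True
    lj_epsilon: float = 0.1
    s_mode: str = "local"             # per-atom S_i: "local" residue-only SASA,
                                      # "structure" in-context SASA, or "unit"

    # interaction_maps
    grid_spacing: float = 0.5         # Å
    gaussian_sigma: float = 0.5       # Å², divisor in exp(-d²/σ)
    deposit_floor: float = 1e-8       # skip grid points below this Gaussian factor

    # map_similarity
    transform_floor: float = 1.0      # F in the log-transform

    # clustering
    k_max: dict = field(default_factory=lambda: dict(K_MAX))
    kmeans_restarts: int = 50
    singleton_recovery: bool = False
    singleton_threshold_sd: float = 3.0

    # accessibility
    sasa_probe: float = 1.4           # Å
    sasa_points: int = 960
    in_threshold: float = 0.2         # In if SASA/reference < 0.2
    out_threshold: float = 0.5        # Out if SASA/reference > 0.5
    lasa_ratio: float = 0.1           # lipid-score ratio above which SASA -> LASA

    # misc
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key: {key}")
            setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
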