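"""Configuration objects for simulation and pipeline runs.

All analysis defaults mirror the conventional settings of array-based
differential-methylation studies: BH-adjusted p < 0.05 for significance,
group-mean beta cutoff 0.5 for methylation state, removal of probes with
more than 80% missing values, top-20 gene ranking, 10,000 CpGs sampled
for unsupervised visualisation, and ORA cutoffs p.adjust < 0.05 /
q < 0.2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

ISLAND_CATEGORIES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


def _default_island_proportions() -> dict[str, float]:
    # genome-wide shares of the 450K array, to two digits
    return {
        "Island": 0.20,
        "N_Shore": 0.13,
        "S_Shore": 0.10,
        "N_Shelf": 0.05,
        "S_Shelf": 0.05,
        "OpenSea": 0.47,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-group 450K-style methylation study.

    Defaults emulate the three-dataset gingival-tissue design this
    pipeline targets: 34 control and 31 case samples split over three
    dataset blocks, with roughly a third of probes differentially
    methylated and a tenth of those crossing the beta = 0.5 boundary.
    """

    n_probes: int = 20_000
    n_control: int = 34
    n_case: int = 31
    n_datasets: int = 3
    frac_dmp: float = 0.30
    frac_crossing_low_high: float = 0.05
    frac_crossing_high_low: float = 0.05
    effect_size_m: float = 2.0
    within_group_sd_m: float = 0.5
    missing_rate: float = 0.02
    frac_high_missing_probes: float = 0.01
    island_proportions: dict[str, float] = field(default_factory=_default_island_proportions)
    batch_shift_m: float = 0.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        fracs = {
            "frac_dmp": self.frac_dmp,
            "frac_crossing_low_high": self.frac_crossing_low_high,
            "frac_crossing_high_low": self.frac_crossing_high_low,
            "missing_rate": self.missing_rate,
            "frac_high_missing_probes": self.frac_high_missing_probes,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_crossing_low_high + self.frac_crossing_high_low > self.frac_dmp + 1e-12:
            raise ConfigError(
                "frac_crossing_low_high + frac_crossing_high_low must not exceed frac_dmp"
            )
        if self.n_probes < 1:
            raise ConfigError("n_probes must be >= 1")
        if set(self.island_proportions) != set(ISLAND_CATEGORIES):
            raise ConfigError(
                f"island_proportions must cover exactly {set(ISLAND_CATEGORIES)}, "
                f"got {set(self.island_proportions)}"
            )
        total = sum(self.island_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"island_proportions must sum to 1, got {total}")
        return self


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; every field is CLI-overridable."""

    out_dir: Path = Path("betacross_out")
    alpha: float = 0.05
    beta_cutoff: float = 0.5
    max_missing_fraction: float = 0.8
    n_top_genes: int = 20
    n_heatmap_cpgs: int = 10_000
    n_top_terms: int = 20
    pvalue_cutoff: float = 0.05
    qvalue_cutoff: float = 0.2
    m_epsilon: float = 1e-6
    n_gmt_terms: int = 50
    n_gmt_enriched: int = 5
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> "PipelineConfig":
        for name in ("alpha", "beta_cutoff", "max_missing_fraction", "pvalue_cutoff", "qvalue_cutoff"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.m_epsilon < 0.5:
            raise ConfigError(f"m_epsilon must lie in (0, 0.5), got {self.m_epsilon}")
        for name in ("n_top_genes", "n_heatmap_cpgs", "n_top_terms"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        self.simulation.validate()
        return self


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML (or JSON-subset) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_mapping(raw)


def config_from_mapping(raw: Mapping) -> PipelineConfig:
    raw = dict(raw)
    sim_raw = dict(raw.pop("simulation", {}))
    known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(sim_raw) - known_sim
    if unknown:
        raise ConfigError(f"unknown simulation fields: {sorted(unknown)}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"simulation"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    if "out_dir" in raw:
        raw["out_dir"] = Path(raw["out_dir"])
    cfg = PipelineConfig(simulation=SimulationConfig(**sim_raw), **raw)
    return cfg.validate()
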