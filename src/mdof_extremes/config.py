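"""Run configuration: defaults, YAML loading, flag overrides."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Resolved settings for a full analysis run.

    Defaults encode the reference study configuration: fourfold cancer
    limit scaling, Uzbekistan excluded as an outlier, a 0.6 % of
    population fitting cut-off, conditioning depths scanned up to k = 5,
    and a 100-year prediction horizon against a 1 % design limit.
    """

    # inputs
    input_path: str | None = None
    cancer_input_path: str | None = None
    cause_columns: list[str] = field(default_factory=lambda: ["rate"])
    cancer_cause_columns: list[str] = field(default_factory=lambda: ["rate"])
    population_column: str | None = None
    # analysis settings
    cancer_scale: float = 4.0
    exclusions: list[str] = field(default_factory=lambda: ["Uzbekistan"])
    maxima_mode: str = "auto"
    lambda_grid_size: int = 200
    lambda_start: float | None = None
    k_max: int = 5
    tol: float = 0.05
    cutoff: float = 0.6  # fitting cut-off, % of population
    threshold: float = 1.0  # design failure limit eta, % of population
    horizon_years: float = 100.0
    criterion: str = "one_expected_exceedance"
    target_probability: float | None = None
    thin_odd_years: bool = False
    tail_form: str = "naess-gaidai"
    # simulation settings (cmd_simulate / validation)
    n_components: int = 195
    n_years: int = 30
    lag1_autocorr: float = 0.6
    cross_corr: float = 0.4
    mean_rate: float = 0.25
    cv: float = 0.35
    # bookkeeping
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)


def load_config(path: str | PathLike | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    The file mirrors the field names of :class:`RunConfig`; explicit
    keyword overrides (CLI flags) win over file values, which win over
    defaults.  Unknown keys are rejected to catch typos.
    """
    cfg = RunConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cfg.replace(**raw)
    return cfg.replace(**overrides)
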