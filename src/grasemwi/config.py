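"""Run configuration: schema-validated nested settings from YAML/JSON.

Unknown keys are rejected with an error naming the key; every default is
explicit after parsing.  Field offsets are accepted in Hz in configuration
files and converted to rad/s once, at parse time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .epg import EchoTrainSpec, T2Grid, build_t2_grid
from .mapping import FittingConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class EchoTrainSection:
    n_se: int = 32
    esp_ms: float = 10.0
    n_ge: int = 2
    ge_offset_ms: tuple[float, ...] = (-2.5, 2.5)
    refocus_fa_deg: float = 180.0
    t1_ms: float = 1000.0

    def to_spec(self) -> EchoTrainSpec:
        return EchoTrainSpec(
            n_se=self.n_se,
            esp=self.esp_ms,
            n_ge=self.n_ge,
            ge_offsets=tuple(self.ge_offset_ms),
            refocus_fa=self.refocus_fa_deg,
            t1_assumed=self.t1_ms,
        )


@dataclass(frozen=True)
class T2GridSection:
    n: int = 40
    min_ms: float = 15.0
    max_ms: float = 2000.0

    def to_grid(self) -> T2Grid:
        return build_t2_grid(self.n, self.min_ms, self.max_ms)


@dataclass(frozen=True)
class DictionarySection:
    fa_min_deg: float = 120.0
    fa_max_deg: float = 180.0
    fa_step_deg: float = 10.0
    n_t2prime: int = 30
    t2prime_min_ms: float = 10.0
    t2prime_max_ms: float = 1000.0
    n_db0: int = 200
    db0_max_hz: float = 150.0
    max_atoms: int = 20000
    d: int = 8


@dataclass(frozen=True)
class SamplingSection:
    config_id: str = "AG1_caipis"
    R: int = 3
    patch: tuple[int, int] = (0, 0)
    halton_bases: tuple[int, int] = (2, 3)
    halton_skip: int = 0


@dataclass(frozen=True)
class SolverSection:
    tol: float = 1e-6
    max_iter: int = 200
    tikhonov: float = 0.0


@dataclass(frozen=True)
class FittingSection:
    fa_min_deg: float = 120.0
    fa_max_deg: float = 180.0
    fa_step_deg: float = 1.0
    reg_mode: str = "chi2"
    chi2_factor: float = 1.02

    def to_fitting(self) -> FittingConfig:
        return FittingConfig(
            fa_min=self.fa_min_deg,
            fa_max=self.fa_max_deg,
            fa_step=self.fa_step_deg,
            reg_mode=self.reg_mode,
            chi2_factor=self.chi2_factor,
        )


@dataclass(frozen=True)
class SimulationSection:
    shape: tuple[int, int] = (64, 64)
    seed: int = 0
    noise_sigma: float = 0.0
    phantom: str = "brain"  # or "vials"
    vial_t2_ms: tuple[float, ...] = (30.0, 80.0, 200.0, 600.0)
    n_coils: int = 6


@dataclass(frozen=True)
class RunConfig:
    echo_train: EchoTrainSection = field(default_factory=EchoTrainSection)
    t2_grid: T2GridSection = field(default_factory=T2GridSection)
    dictionary: DictionarySection = field(default_factory=DictionarySection)
    sampling: SamplingSection = field(default_factory=SamplingSection)
    solver: SolverSection = field(default_factory=SolverSection)
    fitting: FittingSection = field(default_factory=FittingSection)
    simulation: SimulationSection = field(default_factory=SimulationSection)


def _build_section(cls, data: dict, path: str):
    valid = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise KeyError(f"unknown configuration key {path}.{key}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(source) -> RunConfig:
    """Load a RunConfig from a YAML/JSON file path, a mapping, or None."""
    if source is None:
        return RunConfig()
    if isinstance(source, dict):
        data = source
    else:
        with open(source) as f:
            data = yaml.safe_load(f) or {}
    sections = {f.name: f for f in fields(RunConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in sections:
            raise KeyError(f"unknown configuration section {key!r}")
        cls = RunConfig.__dataclass_fields__[key].default_factory
        kwargs[key] = _build_section(cls, value or {}, key)
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a configuration, for provenance records."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
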