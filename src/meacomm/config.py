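"""Pipeline configuration: one YAML file drives every stage.

Unknown keys are rejected so that typos never silently fall back to
defaults; the full resolved configuration (and its hash) is embedded in
every report for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def _from_mapping(cls, data: dict, context: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateSection:
    enabled: bool = True
    stage: str = "day14"
    stim_state: str = "pre"
    duration_s: float = 120.0
    n_rows: int = 8
    n_cols: int = 8
    pitch_um: float = 200.0
    overrides: dict = field(default_factory=dict)


@dataclass
class RawSection:
    enabled: bool = False
    noise_sd: float = 5.0
    fs_hz: float = 20000.0


@dataclass
class DetectSection:
    k: float = 5.0
    cutout_pre_ms: float = 0.6
    cutout_post_ms: float = 1.0


@dataclass
class BurstSection:
    max_isi_ms: float = 100.0
    min_spikes: int = 3


@dataclass
class ActivitySection:
    active_rate_hz: float = 0.1


@dataclass
class SyncSection:
    enabled: bool = True
    bin_ms: float = 10.0
    max_lag_ms: float = 10.0


@dataclass
class MISection:
    enabled: bool = True
    bin_ms: float = 10.0
    edge_threshold: float = 0.1
    strong_threshold: float = 0.2
    bias_correction: bool = False


@dataclass
class CommSection:
    enabled: bool = True
    max_sl_ms: float = 10.0
    mode: str = "bursts"


@dataclass
class InputSection:
    spike_table: str | None = None
    layout: str | None = None
    duration_s: float | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateSection = field(default_factory=SimulateSection)
    raw: RawSection = field(default_factory=RawSection)
    detect: DetectSection = field(default_factory=DetectSection)
    bursts: BurstSection = field(default_factory=BurstSection)
    activity: ActivitySection = field(default_factory=ActivitySection)
    sync: SyncSection = field(default_factory=SyncSection)
    mi: MISection = field(default_factory=MISection)
    comm: CommSection = field(default_factory=CommSection)
    input: InputSection = field(default_factory=InputSection)

    _SECTIONS = {
        "simulate": SimulateSection,
        "raw": RawSection,
        "detect": DetectSection,
        "bursts": BurstSection,
        "activity": ActivitySection,
        "sync": SyncSection,
        "mi": MISection,
        "comm": CommSection,
        "input": InputSection,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if data is None:
            data = {}
        unknown = set(data) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        kwargs = {"seed": int(data.get("seed", 0))}
        for name, section_cls in cls._SECTIONS.items():
            kwargs[name] = _from_mapping(section_cls, data.get(name), name)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]
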