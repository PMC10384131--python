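"""Pipeline configuration with lossless YAML round-tripping.

A single structured file drives the whole analysis.  Defaults embed the
study constants: 2.5-s/0.5-s reference window offsets, 4.5-s activity
window, 466-tap Kaiser filters, alpha = 0.01 for the idle-power trend
and 0.05 elsewhere.  Band/lobe-keyed generator maps serialize as
``"Band/Lobe"`` strings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .filtering import DEFAULT_KAISER_BETA, DEFAULT_N_TAPS
from .synth import SynthConfig


def _pack_pairs(mapping: dict[tuple[str, str], float]) -> dict[str, float]:
    return {f"{b}/{l}": v for (b, l), v in mapping.items()}


def _unpack_pairs(mapping: dict[str, float]) -> dict[tuple[str, str], float]:
    out = {}
    for key, value in mapping.items():
        band, _, lobe = key.partition("/")
        if not lobe:
            raise ValueError(f"expected 'Band/Lobe' key, got {key!r}")
        out[(band, lobe)] = float(value)
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Everything `run_pipeline` needs, serializable to one YAML file."""

    #: Paths to a recorded session; when both are None the synthetic
    #: generator supplies the session.
    recording_path: str | None = None
    events_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)

    n_taps: int = DEFAULT_N_TAPS
    kaiser_beta: float = DEFAULT_KAISER_BETA

    alpha_rt_trend: float = 0.05
    alpha_power_trend: float = 0.01
    alpha_correlation: float = 0.05
    alpha_erc: float = 0.05

    correlation_mode: str = "lobe-mean"
    amp_threshold: float = 200.0  # uV; artifact screen
    output_dir: str = "results"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        synth = d["synth"]
        synth["channel_labels"] = list(synth["channel_labels"])
        synth["activity_gain"] = _pack_pairs(self.synth.activity_gain)
        synth["drift_slope"] = _pack_pairs(self.synth.drift_slope)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = dict(d.pop("synth", {}))
        if "channel_labels" in synth:
            synth["channel_labels"] = tuple(synth["channel_labels"])
        if "activity_gain" in synth:
            synth["activity_gain"] = _unpack_pairs(synth["activity_gain"])
        if "drift_slope" in synth:
            synth["drift_slope"] = _unpack_pairs(synth["drift_slope"])
        known = {f.name for f in dataclasses.fields(SynthConfig)}
        if unknown := set(synth) - known:
            raise ValueError(f"unknown synth config keys {sorted(unknown)}")
        known_top = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(d) - known_top:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(synth=SynthConfig(**synth), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path} does not contain a mapping")
        return cls.from_dict(data)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            synth=dataclasses.replace(self.synth, seed=seed),
        )
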