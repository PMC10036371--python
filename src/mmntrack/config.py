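"""Run configuration: one serialisable object covering the whole pipeline.

A run is fully regenerable from its config plus seeds; every command echoes
the config beside its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DecisionRules
from .errors import ConfigurationError
from .preprocess import PreprocessConfig
from .simulate import DEFAULT_SUBJECT_AMPLITUDE_SD, NoiseModel, ParadigmConfig


@dataclass
class DetectionConfig:
    """ROI, component windows and statistical parameters."""

    roi: list[str] = field(
        default_factory=lambda: ["F3", "Fz", "F4", "C3", "Cz", "C4"]
    )
    mmn_window_ms: tuple[float, float] = (80.0, 230.0)
    p3a_window_ms: tuple[float, float] = (250.0, 350.0)
    n_permutations: int = 1000
    alpha: float = 0.05
    bf_threshold: float = 3.0
    min_duration_ms: float = 10.0
    bayes_method: str = "bic"
    equal_var: bool = False

    def rules(self) -> DecisionRules:
        return DecisionRules(
            alpha=self.alpha,
            min_duration_ms=self.min_duration_ms,
            bf_threshold=self.bf_threshold,
        )


#: Named per-block gain schedules ("scenarios") for simulated studies.
SCENARIOS = {
    "control": [1.0, 1.0, 1.0, 1.0, 1.0],
    "coma-waxing": [1.0, 0.0, 1.0, 0.0, 1.0],
    "absent": [0.0, 0.0, 0.0, 0.0, 0.0],
}


@dataclass
class RunConfig:
    """Everything needed to simulate and analyse one study."""

    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    scenario: str = "control"
    n_subjects: int = 17
    n_blocks: int = 5
    subject_amplitude_sd: float = DEFAULT_SUBJECT_AMPLITUDE_SD
    seed: int = 0

    def block_gains(self) -> list[float]:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; known: {sorted(SCENARIOS)}"
            )
        gains = SCENARIOS[self.scenario]
        if self.n_blocks > len(gains):
            gains = gains + [gains[-1]] * (self.n_blocks - len(gains))
        return gains[: self.n_blocks]

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        out = cls()
        if "paradigm" in d:
            out.paradigm = ParadigmConfig(**d.pop("paradigm"))
        if "noise" in d:
            out.noise = NoiseModel(**d.pop("noise"))
        if "preprocessing" in d:
            pp = d.pop("preprocessing")
            for key in ("band_hz", "baseline_ms"):
                if key in pp and pp[key] is not None:
                    pp[key] = tuple(pp[key])
            out.preprocessing = PreprocessConfig(**pp)
        if "detection" in d:
            det = d.pop("detection")
            for key in ("mmn_window_ms", "p3a_window_ms"):
                if key in det and det[key] is not None:
                    det[key] = tuple(det[key])
            out.detection = DetectionConfig(**det)
        for key, value in d.items():
            if not hasattr(out, key):
                raise ConfigurationError(f"unknown config field {key!r}")
            setattr(out, key, value)
        return out

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        return cls.from_dict(data)


def _plain(obj):
    """YAML-safe plain types (tuples -> lists)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
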