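"""Configuration objects for the cohort generator and the analysis pipeline.

All angles are plain real degrees, counterclockwise positive, 0° pointing
subjectively rightward and 90° subjectively anterior (the task plane's
convention). No modular wrap-around is applied anywhere: every direction in
the task lives far from a wrap seam.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Signed feedback rotations used in the experiment (degrees).
DEFAULT_MANIPULATION_SET: tuple[float, ...] = (
    -40.0, -20.0, -10.0, -5.0, 0.0, 5.0, 10.0, 20.0, 40.0)

#: Relative weight of visual information per absolute rotation amount —
#: the internally attributed share of the visual prediction error.
DEFAULT_ATTRIBUTION_WEIGHTS: dict[float, float] = {
    5.0: 0.54, 10.0: 0.57, 20.0: 0.38, 40.0: 0.19}

#: Relative recalibration of the internal sensory prediction per amount.
#: 5° sits inside the error deadzone and induces none.
DEFAULT_RECAL_GAINS: dict[float, float] = {
    5.0: 0.0, 10.0: 0.20, 20.0: 0.14, 40.0: 0.07}


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class GeneratorParams:
    """Ground-truth parameters of the synthetic pointing cohort.

    The defaults reproduce the study conditions: 11 subjects, 180
    feedback/probe pairs each, rotations drawn uniformly from
    {0°, ±5°, ±10°, ±20°, ±40°}, freely chosen motor directions on
    [10°, 70°], a 9.0° instructed amplitude, and the published attribution
    weight and recalibration gain profiles with a 5° error deadzone.
    """

    n_subjects: int = 11
    n_pairs: int = 180
    manipulation_set: Sequence[float] = DEFAULT_MANIPULATION_SET
    attribution_weight_by_amount: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTRIBUTION_WEIGHTS))
    recal_gain_by_amount: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_RECAL_GAINS))
    deadzone_deg: float = 5.0
    coupling_mode: str = "attributed"  # or "uniform"
    beta_uniform: float = 0.219
    motor_adapt_gain: float = 1.0
    offset_fb_deg: float = 0.0
    offset_pp_deg: float = 0.0
    perceptual_noise_sd_deg: float = 4.0
    mpd_range_deg: tuple[float, float] = (10.0, 70.0)
    instructed_amplitude_deg: float = 9.0
    curvature_noise_sd_deg: float = 0.3
    n_traj_samples: int = 60
    sample_rate_hz: float = 60.0
    invalid_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_pairs < 1:
            raise ConfigError("n_subjects and n_pairs must be positive")
        amounts = self.amounts()
        if not amounts and any(m != 0 for m in self.manipulation_set):
            raise ConfigError("manipulation_set has no nonzero members")
        for a in amounts:
            w = self.attribution_weight_by_amount.get(a)
            if w is None:
                raise ConfigError(f"no attribution weight for amount {a}")
            if not 0.0 <= w <= 1.0:
                raise ConfigError(f"weight w({a})={w} outside [0, 1]")
            g = self.recal_gain_by_amount.get(a)
            if g is None:
                raise ConfigError(f"no recalibration gain for amount {a}")
            if g < 0:
                raise ConfigError(f"gain g({a})={g} negative")
            if a > self.deadzone_deg and g > 0 and w == 0:
                raise ConfigError(f"g({a})/w({a}) undefined: w=0 with g>0")
        if self.deadzone_deg not in set(amounts) | {0.0}:
            raise ConfigError(
                "deadzone_deg must be 0 or one of the manipulation amounts")
        if self.coupling_mode not in ("attributed", "uniform"):
            raise ConfigError(f"unknown coupling_mode {self.coupling_mode!r}")
        if self.perceptual_noise_sd_deg < 0 or self.curvature_noise_sd_deg < 0:
            raise ConfigError("noise SDs must be >= 0")
        lo, hi = self.mpd_range_deg
        if not lo < hi:
            raise ConfigError("mpd_range_deg must be an increasing interval")
        if self.n_traj_samples < 3:
            raise ConfigError("n_traj_samples must be >= 3")
        if self.sample_rate_hz <= 0 or self.instructed_amplitude_deg <= 0:
            raise ConfigError("sample_rate_hz and amplitude must be positive")
        if not 0.0 <= self.invalid_rate < 1.0:
            raise ConfigError("invalid_rate must lie in [0, 1)")

    def amounts(self) -> list[float]:
        """Sorted absolute nonzero rotation amounts."""
        return sorted({abs(m) for m in self.manipulation_set if m != 0})

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["manipulation_set"] = list(self.manipulation_set)
        d["mpd_range_deg"] = list(self.mpd_range_deg)
        d["attribution_weight_by_amount"] = {
            str(k): v for k, v in self.attribution_weight_by_amount.items()}
        d["recal_gain_by_amount"] = {
            str(k): v for k, v in self.recal_gain_by_amount.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorParams":
        d = dict(d)
        for key in ("attribution_weight_by_amount", "recal_gain_by_amount"):
            if key in d:
                d[key] = {float(k): float(v) for k, v in d[key].items()}
        if "manipulation_set" in d:
            d["manipulation_set"] = tuple(float(m) for m in d["manipulation_set"])
        if "mpd_range_deg" in d:
            d["mpd_range_deg"] = tuple(float(v) for v in d["mpd_range_deg"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown generator fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class AnalysisConfig:
    """Thresholds and conventions of the analysis stage.

    The defaults are the study's constants: curvature trials are excluded
    above 2.25° maximum chord deviation (one quarter of the instructed
    amplitude), tracker artefacts above 120°/s, movements shorter than half
    the instructed amplitude are invalid, and visual feedback is only shown
    beyond 4.5° amplitude. All exclusion thresholds are strict ("exceeded").
    """

    curvature_threshold_deg: float = 2.25
    speed_threshold_deg_s: float = 120.0
    amplitude_validity_fraction: float = 0.5
    feedback_visibility_amplitude_deg: float = 4.5
    bf_prior_sd: float = 0.5
    alpha: float = 0.05
    include_veridical_in_overall_regression: bool = True

    def __post_init__(self) -> None:
        if min(self.curvature_threshold_deg, self.speed_threshold_deg_s,
               self.amplitude_validity_fraction,
               self.feedback_visibility_amplitude_deg, self.bf_prior_sd) <= 0:
            raise ConfigError("analysis thresholds must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown analysis fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineConfig:
    """Full pipeline configuration: generator + analysis + seed."""

    generator: GeneratorParams = field(default_factory=GeneratorParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"generator": self.generator.to_dict(),
                "analysis": self.analysis.to_dict(),
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        gen = GeneratorParams.from_dict(d.get("generator", {}))
        ana = AnalysisConfig.from_dict(d.get("analysis", {}))
        seed = d.get("seed")
        cfg = cls(generator=gen, analysis=ana,
                  seed=None if seed is None else int(seed))
        if cfg.seed is not None:
            cfg.generator.seed = cfg.seed
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config root of {path} must be a mapping")
        return cls.from_dict(data)

    def write_sidecar(self, path: str | Path) -> None:
        """Record the exact configuration and seed next to generated data."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
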