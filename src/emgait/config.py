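"""Pipeline configuration: nested defaults, YAML loading, strict key checking.

Every tunable of the pipeline lives here with its documented default.  A
fully-defaulted config runs the demo pipeline end to end.  All stage
randomness derives from the single root ``seed``, so one number
reproduces a complete run.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = ["PipelineConfig", "ConfigError", "derive_seed"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed.

    Uses a CRC of the stage name (not ``hash()``, which is randomized per
    process) so a run is reproducible across interpreter sessions.
    """
    h = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0] % 2**31)


@dataclass
class SimulateConfig:
    n_cycles: int = 20
    cycle_duration: float = 1.1
    phase_fractions: tuple = (0.17, 0.33, 0.33, 0.17)
    fs: float = 1000.0
    noise_sd: float = 0.05
    profiles: str = "default"  # "default" or "well_separated"
    separation_gain: float = 5.0


@dataclass
class DenoiseConfig:
    method: str = "modulus_maxima"  # modulus_maxima | soft_threshold | none
    wavelet: str = "db5"
    levels: int = 5
    persistence_min: int = 2


@dataclass
class WindowConfig:
    length_samples: int = 256
    step_samples: int = 64


@dataclass
class FeatureConfig:
    families: tuple = ("T", "F", "W", "S")
    zc_eps: float = 0.0
    psd_method: str = "welch"
    wavelet: str = "db5"
    wavelet_levels: int = 6
    fuen_n: int = 2
    fuen_r: float = 0.15
    fuen_p: float = 2.0
    var_subtract_mean: bool = False


@dataclass
class PCAConfig:
    enabled: bool = True
    threshold: float = 95.0


@dataclass
class SVMConfig:
    C: float = 1.0
    g: float = 1.0


@dataclass
class ELMConfig:
    hidden: int = 100


@dataclass
class ABCOptConfig:
    colony_size: int = 20
    max_cycle: int = 30
    limit: int = 300
    lower_bound: float = 0.01
    upper_bound: float = 100.0
    cv_folds: int = 5


@dataclass
class SplitConfig:
    train_fraction: float = 0.7


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    pca: PCAConfig = field(default_factory=PCAConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    elm: ELMConfig = field(default_factory=ELMConfig)
    abc: ABCOptConfig = field(default_factory=ABCOptConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    classifiers: tuple = ("svm", "abc_svm")
    seed: int = 0
    input_csv: str | None = None  # load a recording instead of simulating

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _build(cls, data, path="")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict[str, Any], path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = path or "top level"
        raise ConfigError(f"unknown config key(s) at {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        sub = _SUBSECTIONS.get((cls, name))
        if sub is not None:
            if not isinstance(value, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build(sub, value, path=f"{path}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SUBSECTIONS = {
    (PipelineConfig, "simulate"): SimulateConfig,
    (PipelineConfig, "denoise"): DenoiseConfig,
    (PipelineConfig, "window"): WindowConfig,
    (PipelineConfig, "features"): FeatureConfig,
    (PipelineConfig, "pca"): PCAConfig,
    (PipelineConfig, "svm"): SVMConfig,
    (PipelineConfig, "elm"): ELMConfig,
    (PipelineConfig, "abc"): ABCOptConfig,
    (PipelineConfig, "split"): SplitConfig,
}
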