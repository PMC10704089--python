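"""Run configuration: nested, validated, YAML round-trippable.

The configuration mirrors the tunables of every pipeline stage.  Unknown
keys are rejected (typos should fail loudly, not silently fall back to
defaults) and parse -> serialize -> parse is the identity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from .filters import WaveletSpec
from .hilo import CameraModel, HiLoParams
from .nlm import NLMParams

__all__ = ["IOConfig", "CameraConfig", "WaveletConfig", "FilterConfig", "HiloConfig", "NLMConfig", "RunConfig"]


def _from_mapping(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)} (known: {sorted(names)})")
    return cls(**data)


@dataclass(frozen=True)
class IOConfig:
    input_uniform: Optional[str] = None
    input_speckle: Optional[str] = None
    output: Optional[str] = None
    pairing: str = "two_files"  # or "interleaved": alternating uniform/speckle pages of input_uniform
    save_intermediates: bool = False

    def __post_init__(self):
        if self.pairing not in ("two_files", "interleaved"):
            raise ValueError("io.pairing must be 'two_files' or 'interleaved'")


@dataclass(frozen=True)
class CameraConfig:
    gain: Optional[float] = None
    gain_units: str = "adu_per_e"
    read_noise_e: float = 0.0
    offset_adu: float = 0.0

    def model(self) -> Optional[CameraModel]:
        if self.gain is None:
            return None
        return CameraModel.from_gain(
            self.gain, self.gain_units, read_noise_e=self.read_noise_e, offset_adu=self.offset_adu
        )


@dataclass(frozen=True)
class WaveletConfig:
    sigma_w: float = 2.0


@dataclass(frozen=True)
class FilterConfig:
    cutoff: Union[float, str] = "auto"
    padding: str = "mirror"


@dataclass(frozen=True)
class HiloConfig:
    eta: Union[float, str] = "auto"
    local_stat_sigma: Optional[float] = None
    clip_negative: bool = True


@dataclass(frozen=True)
class NLMConfig:
    enabled: bool = False
    patch_halfwidth: int = 1
    search_halfwidth: int = 10
    h_lo: float = 10.0
    h_hi: float = 0.5
    enabled_channels: str = "both"

    def params(self) -> Optional[NLMParams]:
        if not self.enabled:
            return None
        return NLMParams(
            patch_halfwidth=self.patch_halfwidth,
            search_halfwidth=self.search_halfwidth,
            h_lo=self.h_lo,
            h_hi=self.h_hi,
            channels=self.enabled_channels,
        )


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration."""

    io: IOConfig = field(default_factory=IOConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    hilo: HiloConfig = field(default_factory=HiloConfig)
    nlm: NLMConfig = field(default_factory=NLMConfig)
    seed: int = 0
    log_level: str = "INFO"

    _SECTIONS = {
        "io": IOConfig,
        "camera": CameraConfig,
        "wavelet": WaveletConfig,
        "filter": FilterConfig,
        "hilo": HiloConfig,
        "nlm": NLMConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        known = set(cls._SECTIONS) | {"seed", "log_level"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys {sorted(unknown)} (known: {sorted(known)})")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _from_mapping(section_cls, data[name], context=name)
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "log_level" in data:
            kwargs["log_level"] = str(data["log_level"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def hilo_params(self) -> HiLoParams:
        return HiLoParams(
            wavelet=WaveletSpec(self.wavelet.sigma_w),
            cutoff=self.filter.cutoff,
            eta=self.hilo.eta,
            local_stat_sigma=self.hilo.local_stat_sigma,
            clip_negative=self.hilo.clip_negative,
            padding=self.filter.padding,
        )
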