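"""Pipeline configuration.

Every numeric rule of the analysis lives in one validated record: the 50%
site-to-neuron assignment fraction, the 0.1% contact colocalization, the
per-role instance size gates (400 voxels presynaptic, 200 postsynaptic and
gap-junction, 2000 for neuron-mask components), the gap-bridging setting
(gaps of <= 20 voxels, four iterations), the 0.8 probability threshold and
the 512-voxel analysis block edge. ``load_config`` fills these defaults from
an (optionally empty) YAML file and rejects unknown keys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Any

import yaml

from .errors import ConfigError

__all__ = [
    "ThresholdSpec",
    "BridgeSpec",
    "SegmentationProfile",
    "PipelineConfig",
    "load_config",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """How to compute an intensity threshold: 'otsu', 'li', or 'manual'."""

    method: str = "otsu"
    manual_value: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "li", "manual"):
            raise ConfigError(f"unknown threshold method {self.method!r}; expected otsu|li|manual")
        if (self.method == "manual") != (self.manual_value is not None):
            raise ConfigError("manual_value must be given exactly when method='manual'")


@dataclass(frozen=True)
class BridgeSpec:
    """Gap-bridging parameters: connect component pairs whose minimum
    voxel-centre distance is at most ``max_gap_voxels``, repeated for
    ``iterations`` rounds; bridge lines are thickened by ``bridge_radius``."""

    max_gap_voxels: float = 20.0
    iterations: int = 4
    bridge_radius: int = 1

    def __post_init__(self) -> None:
        if self.max_gap_voxels <= 0:
            raise ConfigError("max_gap_voxels must be positive")
        if self.iterations < 1:
            raise ConfigError("iterations must be a positive integer")
        if self.bridge_radius < 0:
            raise ConfigError("bridge_radius must be non-negative")


@dataclass(frozen=True)
class SegmentationProfile:
    """Per-marker-role instance segmentation settings."""

    marker_role: str = "presynaptic"
    prob_threshold: float = 0.8
    min_size_voxels: int = 400
    min_seed_separation_voxels: int = 3

    def __post_init__(self) -> None:
        if self.marker_role not in ("presynaptic", "postsynaptic", "gap_junction"):
            raise ConfigError(f"unknown marker_role {self.marker_role!r}")
        if not (0.0 < self.prob_threshold < 1.0):
            raise ConfigError("prob_threshold must lie in (0,1)")
        if self.min_size_voxels < 1:
            raise ConfigError("min_size_voxels must be positive")
        if self.min_seed_separation_voxels < 1:
            raise ConfigError("min_seed_separation_voxels must be positive")


def default_profile(role: str) -> SegmentationProfile:
    gates = {"presynaptic": 400, "postsynaptic": 200, "gap_junction": 200}
    if role not in gates:
        raise ConfigError(f"unknown marker role {role!r}")
    return SegmentationProfile(marker_role=role, min_size_voxels=gates[role])


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline thresholds in one place; defaults are the published settings."""

    assignment_fraction: float = 0.5
    contact_fraction: float = 0.001
    contact_dilation_voxels: int = 0
    presyn_profile: SegmentationProfile = field(default_factory=lambda: default_profile("presynaptic"))
    postsyn_profile: SegmentationProfile = field(default_factory=lambda: default_profile("postsynaptic"))
    gapjunction_profile: SegmentationProfile = field(default_factory=lambda: default_profile("gap_junction"))
    neuron_threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    neuron_bridge: BridgeSpec = field(default_factory=BridgeSpec)
    neuron_min_size_voxels: int = 2000
    block_edge: int = 512
    halo: int = 64
    connectivity: int = 26
    provider: str = "scaled_intensity"
    # Explicit 8-bit dynamic range: robust on sparse zero-background volumes where
    # high percentiles degenerate to 0. Set to {} to fall back to percentile scaling.
    provider_params: dict = field(default_factory=lambda: {"lo": 0.0, "hi": 255.0})
    anisotropic_distances: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.assignment_fraction <= 1.0):
            raise ConfigError("assignment_fraction must lie in (0,1]")
        if not (0.0 < self.contact_fraction <= 1.0):
            raise ConfigError("contact_fraction must lie in (0,1]")
        if self.contact_dilation_voxels < 0:
            raise ConfigError("contact_dilation_voxels must be non-negative")
        if self.neuron_min_size_voxels < 1:
            raise ConfigError("neuron_min_size_voxels must be positive")
        if self.block_edge < 1:
            raise ConfigError("block_edge must be positive")
        if self.halo < 0:
            raise ConfigError("halo must be non-negative")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be one of 6, 18, 26")

    def profile_for(self, role: str) -> SegmentationProfile:
        return {
            "presynaptic": self.presyn_profile,
            "postsynaptic": self.postsyn_profile,
            "gap_junction": self.gapjunction_profile,
        }[role]


_INT_FIELDS = {
    "contact_dilation_voxels",
    "neuron_min_size_voxels",
    "block_edge",
    "halo",
    "connectivity",
    "rng_seed",
    "min_size_voxels",
    "min_seed_separation_voxels",
    "iterations",
    "bridge_radius",
}
_FLOAT_FIELDS = {
    "assignment_fraction",
    "contact_fraction",
    "prob_threshold",
    "max_gap_voxels",
    "manual_value",
}


def _coerce(key: str, value: Any) -> Any:
    """Documented leniency: numeric strings are coerced with a warning."""
    if isinstance(value, str) and (key in _INT_FIELDS or key in _FLOAT_FIELDS):
        try:
            coerced = int(value) if key in _INT_FIELDS else float(value)
        except ValueError as exc:
            raise ConfigError(f"key {key!r}: expected a number, got {value!r}") from exc
        warnings.warn(f"config key {key!r}: coerced string {value!r} to {coerced}", stacklevel=3)
        return coerced
    if key in _INT_FIELDS and isinstance(value, bool):
        raise ConfigError(f"key {key!r}: expected an integer, got a boolean")
    if key in _INT_FIELDS and isinstance(value, float):
        if value != int(value):
            raise ConfigError(f"key {key!r}: expected an integer, got {value}")
        return int(value)
    return value


def _build(cls, mapping: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    kwargs = {k: _coerce(k, v) for k, v in mapping.items()}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in {where}: {exc}") from exc


_NESTED = {
    "presyn_profile": (SegmentationProfile, {"marker_role": "presynaptic", "min_size_voxels": 400}),
    "postsyn_profile": (SegmentationProfile, {"marker_role": "postsynaptic", "min_size_voxels": 200}),
    "gapjunction_profile": (SegmentationProfile, {"marker_role": "gap_junction", "min_size_voxels": 200}),
    "neuron_threshold": (ThresholdSpec, {}),
    "neuron_bridge": (BridgeSpec, {}),
}


def config_from_mapping(mapping: dict | None) -> PipelineConfig:
    """Build a PipelineConfig from a plain dict (e.g. parsed YAML)."""
    mapping = dict(mapping or {})
    kwargs: dict[str, Any] = {}
    for key, (cls, base) in _NESTED.items():
        if key in mapping:
            sub = mapping.pop(key)
            if not isinstance(sub, dict):
                raise ConfigError(f"key {key!r}: expected a mapping")
            kwargs[key] = _build(cls, {**base, **sub}, key)
    top_known = {f.name for f in fields(PipelineConfig)} - set(_NESTED)
    unknown = set(mapping) - top_known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for k, v in mapping.items():
        kwargs[k] = _coerce(k, v)
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load a YAML config file; an empty file yields all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping, got {type(raw).__name__}")
    return config_from_mapping(raw)


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Flatten a config to plain JSON/YAML-serializable types (for manifests)."""
    from dataclasses import asdict

    return asdict(cfg)
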