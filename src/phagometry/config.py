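"""Pipeline configuration: dataclasses, YAML loading, validation.

Every section rejects unknown keys and range-checks its values, so a
typo in a config file fails before any compute starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import PhantomConfig

__all__ = [
    "ConfigError",
    "SegmentationParams",
    "MaskingParams",
    "MorphometryParams",
    "AgreementParams",
    "InputPaths",
    "PipelineConfig",
    "load_config",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class SegmentationParams:
    """Thresholding, labeling and object-filtering parameters.

    ``min_object_voxels`` is interpreted in voxels, exactly as the
    segmentation protocol states; ``min_object_um3``, when given, takes
    precedence and is converted with the stack's voxel volume so the
    same config works across resolutions.
    """

    threshold_method: str = "otsu"
    fixed_threshold: int | None = None
    connectivity: int = 26
    min_object_voxels: int = 100
    min_object_um3: float | None = None
    outlier_rule: str = "upper_mad"
    mad_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigError(f"unknown threshold_method {self.threshold_method!r}")
        if (self.fixed_threshold is not None) != (self.threshold_method == "fixed"):
            raise ConfigError("fixed_threshold must be given iff threshold_method is 'fixed'")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if int(self.min_object_voxels) < 1:
            raise ConfigError(f"min_object_voxels must be >= 1, got {self.min_object_voxels}")
        self.min_object_voxels = int(self.min_object_voxels)
        if self.min_object_um3 is not None and self.min_object_um3 <= 0:
            raise ConfigError("min_object_um3 must be > 0")
        if self.outlier_rule not in ("none", "upper_mad"):
            raise ConfigError(f"unknown outlier_rule {self.outlier_rule!r}")
        if self.mad_multiplier <= 0:
            raise ConfigError("mad_multiplier must be > 0")


@dataclass
class MaskingParams:
    """ROI selection and dilation.

    The dilation extent is the single largest free parameter of the
    pipeline: it decides how far beyond an ROI surface the periductal
    cuff is searched for cells.  ``dilation_unit`` is ``"um"`` (default,
    anisotropy-aware) or ``"voxel"``.
    """

    roi_names: list[str] | None = None
    dilation_um: float = 12.0
    dilation_unit: str = "um"

    def __post_init__(self) -> None:
        if self.dilation_um < 0:
            raise ConfigError(f"dilation_um must be >= 0, got {self.dilation_um}")
        if self.dilation_unit not in ("um", "voxel"):
            raise ConfigError(f"dilation_unit must be 'um' or 'voxel', got {self.dilation_unit!r}")


@dataclass
class MorphometryParams:
    """Morphometry and classification parameters.

    ``solidity_threshold``: cells with solidity below it are called
    ramified, at or above it ameboid.  ``max_distance_um``: furthest a
    cell may sit from an ROI and still be assigned to it; ``None`` means
    "use the masking dilation radius" so assignment and masking agree.
    """

    solidity_threshold: float = 0.5
    max_distance_um: float | None = None
    hull_mode: str = "rasterized"
    solidity_space: str = "voxel"

    def __post_init__(self) -> None:
        if not 0.0 < self.solidity_threshold < 1.0:
            raise ConfigError("solidity_threshold must lie strictly between 0 and 1")
        if self.max_distance_um is not None and self.max_distance_um < 0:
            raise ConfigError("max_distance_um must be >= 0")
        if self.hull_mode not in ("rasterized", "continuous"):
            raise ConfigError(f"hull_mode must be 'rasterized' or 'continuous', got {self.hull_mode!r}")
        if self.solidity_space not in ("voxel", "physical"):
            raise ConfigError(f"solidity_space must be 'voxel' or 'physical', got {self.solidity_space!r}")


@dataclass
class AgreementParams:
    """Inter-rater agreement stage.

    Rater label maps may be supplied as files; on phantom runs,
    ``simulate_raters`` > 1 generates that many imperfect raters from
    the segmentation by boundary-localized flips with per-voxel
    probability ``disagreement``.
    """

    rater_paths: list[str] = field(default_factory=list)
    per_structure: bool = False
    simulate_raters: int = 0
    disagreement: float = 0.2

    def __post_init__(self) -> None:
        if self.simulate_raters < 0 or self.simulate_raters == 1:
            raise ConfigError("simulate_raters must be 0 (off) or >= 2")
        if not 0.0 <= self.disagreement <= 1.0:
            raise ConfigError("disagreement must be in [0, 1]")


@dataclass
class InputPaths:
    """File inputs for runs on real (non-phantom) stacks."""

    marker_path: str | None = None
    roi_labels_path: str | None = None


@dataclass
class GeometrySection:
    voxel_size_um: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.voxel_size_um is not None:
            vs = tuple(float(v) for v in self.voxel_size_um)
            if len(vs) != 3 or any(v <= 0 for v in vs):
                raise ConfigError(f"voxel_size_um must be 3 positive values, got {vs}")
            self.voxel_size_um = vs


@dataclass
class PipelineConfig:
    """Top-level configuration for a full pipeline run."""

    seed: int = 0
    output_dir: str = "phagometry_out"
    geometry: GeometrySection = field(default_factory=GeometrySection)
    inputs: InputPaths = field(default_factory=InputPaths)
    phantom: PhantomConfig | None = None
    masking: MaskingParams = field(default_factory=MaskingParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    morphometry: MorphometryParams = field(default_factory=MorphometryParams)
    agreement: AgreementParams = field(default_factory=AgreementParams)

    def __post_init__(self) -> None:
        self.seed = int(self.seed)
        if self.phantom is None and self.inputs.marker_path is None:
            # permitted for partially-configured objects; run_pipeline
            # validates completeness before any compute.
            pass

    def validate_runnable(self) -> None:
        if self.phantom is None:
            if not self.inputs.marker_path:
                raise ConfigError("config has neither a phantom section nor inputs.marker_path")
            if not self.inputs.roi_labels_path:
                raise ConfigError("inputs.roi_labels_path is required when no phantom is generated")


_TUPLE_FIELDS = {
    "voxel_size_um",
    "shape",
    "ameboid_axes_um",
    "n_branches_range",
    "branch_len_um_range",
    "branch_thickness_um_range",
}


def _build(cls, data, where: str):
    """Recursively build a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(f"{where}: unknown keys {unknown}; allowed: {sorted(fields)}")
    kwargs = {}
    for key, value in data.items():
        target = _NESTED.get((cls, key))
        if target is not None and value is not None:
            kwargs[key] = _build(target, value, f"{where}.{key}")
        elif key in _TUPLE_FIELDS and value is not None:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # e.g. wrong value shape
        raise ConfigError(f"{where}: {exc}") from exc


_NESTED: dict[tuple[type, str], type] = {
    (PipelineConfig, "geometry"): GeometrySection,
    (PipelineConfig, "inputs"): InputPaths,
    (PipelineConfig, "phantom"): PhantomConfig,
    (PipelineConfig, "masking"): MaskingParams,
    (PipelineConfig, "segmentation"): SegmentationParams,
    (PipelineConfig, "morphometry"): MorphometryParams,
    (PipelineConfig, "agreement"): AgreementParams,
}


def config_from_dict(data: dict | None) -> PipelineConfig:
    return _build(PipelineConfig, data, "config")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; an empty file yields full defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    return config_from_dict(data)


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Plain-dict form of a config (for provenance hashing and dumps)."""
    return dataclasses.asdict(cfg)
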