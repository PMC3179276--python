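"""Pipeline configuration.

Every threshold and numeric constant of the analysis chain is a config
key with the documented default, loadable from YAML so a run is fully
reproducible from its config file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import IntensityScale


@dataclass
class SegmentationConfig:
    full_scale_density: float = 2000.0
    cortical_threshold_frac: float = 0.16
    trabecular_threshold_frac: float = 0.40
    gaussian_sigma_voxels: float = 1.0
    periosteal_closing_radius: int = 5
    endosteal_closing_radius: int = 8
    laplace_hamming_cutoff: float = 0.8
    laplace_weight: float = 0.8
    laplace_rescale: str = "positive"
    min_pore_voxels: int = 0

    @property
    def intensity_scale(self) -> IntensityScale:
        return IntensityScale(
            full_scale_density=self.full_scale_density,
            cortical_threshold_frac=self.cortical_threshold_frac,
            trabecular_threshold_frac=self.trabecular_threshold_frac,
        )


@dataclass
class MorphometryConfig:
    tb_n_method: str = "intercept"  # or "sphere"
    inner_area_fraction: float = 0.6


@dataclass
class RegistrationConfig:
    max_shift: int = 30
    min_overlap: int = 50


@dataclass
class FEConfig:
    E_tissue_GPa: float = 10.0
    nu: float = 0.3
    applied_strain: float = 0.01
    boundary: str = "lateral-free"  # or "constrained"
    cg_rtol: float = 1e-6
    pistoia_volume_fraction: float = 0.02
    pistoia_critical_strain: float = 0.007
    a_gross: str = "periosteal"  # or "bounding-box"


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    fe: FEConfig = field(default_factory=FEConfig)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            segmentation=SegmentationConfig(**raw.get("segmentation", {})),
            morphometry=MorphometryConfig(**raw.get("morphometry", {})),
            registration=RegistrationConfig(**raw.get("registration", {})),
            fe=FEConfig(**raw.get("fe", {})),
        )
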