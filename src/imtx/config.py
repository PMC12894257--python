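"""Single-file pipeline configuration with field-standard defaults.

Defaults follow the analysis conventions the pipeline implements: 20-mm
FWHM reconstruction kernel with voxel p < 0.005, peak z >= 1 and 50-voxel
extent (10 for heterogeneity); 50% background-intensity and r >= 0.2 probe
rules with a top-50% differential-stability cut (40/60% alternates); 3-mm
spheres, 10-200 category sizes and 10,000 surrogates; pSI 0.05 panels,
0.9-confidence networks with top-10% hubs; 5,000 spatial permutations at
FDR alpha 0.01 for the receptor panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class CbmaParams:
    fwhm: float = 20.0
    voxel_p: float = 0.005
    peak_z: float = 1.0
    extent: int = 50
    het_extent: int = 10
    n_null: int = 200
    combine: str = "max"


@dataclass
class AhbaParams:
    intensity_fraction: float = 0.5
    probe_r: float = 0.2
    ds_fraction: float = 0.5
    ds_alternates: tuple[float, float] = (0.4, 0.6)
    n_regions: int = 30
    left_only: bool = True


@dataclass
class AssocParams:
    radius: float = 3.0
    n_surrogates: int = 10000
    go_min: int = 10
    go_max: int = 200
    alpha: float = 0.05


@dataclass
class EnrichParams:
    psi: float = 0.05
    string_cutoff: float = 0.9
    hub_fraction: float = 0.10


@dataclass
class NeuroParams:
    n_perm: int = 5000
    alpha: float = 0.01


@dataclass
class PipelineConfig:
    seed: int = 0
    voxel_size: float = 2.0
    cbma: CbmaParams = field(default_factory=CbmaParams)
    ahba: AhbaParams = field(default_factory=AhbaParams)
    assoc: AssocParams = field(default_factory=AssocParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    neuro: NeuroParams = field(default_factory=NeuroParams)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            seed=raw.get("seed", 0),
            voxel_size=raw.get("voxel_size", 2.0),
        )
        for name, typ in (
            ("cbma", CbmaParams),
            ("ahba", AhbaParams),
            ("assoc", AssocParams),
            ("enrich", EnrichParams),
            ("neuro", NeuroParams),
        ):
            if name in raw:
                d = dict(raw[name])
                if "ds_alternates" in d:
                    d["ds_alternates"] = tuple(d["ds_alternates"])
                setattr(cfg, name, typ(**d))
        return cfg

    @classmethod
    def demo_scale(cls, seed: int = 0) -> "PipelineConfig":
        """Reduced problem sizes for the end-to-end demo (coarser grid,
        smaller ensembles) so the full chain runs in minutes on one CPU."""
        cfg = cls(seed=seed, voxel_size=6.0)
        cfg.cbma.n_null = 40
        cfg.assoc.n_surrogates = 200
        cfg.neuro.n_perm = 200
        return cfg
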