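"""Pipeline configuration with the published stage defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the segmentation pipeline.

    Alignment: ``align_gate_deg`` — rotation is applied only when the
    estimated tilt exceeds this gate; ``bone_threshold`` — HU cutoff for the
    bone pixels used by the tilt PCA.  Chest mask: ``opening_radius`` (px).
    Separation: ``erosion_max_iters``, ``dp_band_fraction`` (central column
    band of the cost-path fallback).  Refinement: ``arc_step`` (L, px),
    ``poly_degree`` (n), ``half_window`` (k), ``max_passes`` (M),
    ``t1_ratio`` (concave depth/width threshold T1), ``t2_perimeter_tol``
    (T2, px), ``march_step`` (minimum concave span, points).  Slices whose
    candidate lung regions are smaller than ``min_lung_area_px`` are
    treated as lung-free.
    """

    align_gate_deg: float = 15.0
    bone_threshold: float = 200.0
    opening_radius: int = 3
    erosion_max_iters: int = 20
    dp_band_fraction: float = 1.0 / 3.0
    arc_step: float = 0.3
    poly_degree: int = 2
    half_window: int = 4
    max_passes: int = 12
    t1_ratio: float = 0.6
    t2_perimeter_tol: float = 0.01
    march_step: int = 5
    min_lung_area_px: int = 50
    radiological_labels: bool = False  # swap left/right to patient convention

    def __post_init__(self) -> None:
        if not 0 <= self.align_gate_deg <= 90:
            raise ValueError("align_gate_deg must be in [0, 90]")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")
        if self.erosion_max_iters < 1:
            raise ValueError("erosion_max_iters must be >= 1")
        if not 0 < self.dp_band_fraction <= 1:
            raise ValueError("dp_band_fraction must be in (0, 1]")
        if self.arc_step <= 0 or self.t2_perimeter_tol <= 0:
            raise ValueError("arc_step and t2_perimeter_tol must be positive")
        if 2 * self.half_window <= self.poly_degree:
            raise ValueError("need 2 * half_window > poly_degree")
        if self.t1_ratio <= 0:
            raise ValueError("t1_ratio must be positive")
        if self.march_step < 1:
            raise ValueError("march_step must be >= 1")

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
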