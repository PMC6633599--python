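"""Run configuration: one YAML file drives the whole pipeline.

Every default is echoed back into the run summary so runs are
self-describing.  Units after loading are µm and seconds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from tissuekin.divergence import DivergenceParams
from tissuekin.midline import DEFAULT_D_EPS, Midline
from tissuekin.specs import DivisionSpec, FlowSpec, SceneSpec, ShapeSpec, SurfaceSpec


def flow_from_dict(d: dict) -> FlowSpec:
    d = dict(d)
    if d.get("kind") == "composite":
        d["parts"] = tuple(flow_from_dict(p) for p in d.get("parts", []))
    for key in ("velocity", "center", "axis"):
        if key in d:
            d[key] = tuple(d[key])
    return FlowSpec(**d)


def surface_from_dict(d: dict) -> SurfaceSpec:
    d = dict(d)
    for key in ("slope", "apex"):
        if key in d:
            d[key] = tuple(d[key])
    return SurfaceSpec(**d)


def scene_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    d["flow"] = flow_from_dict(d["flow"])
    if "surface" in d:
        d["surface"] = surface_from_dict(d["surface"])
    if d.get("division_spec"):
        d["division_spec"] = DivisionSpec(**d["division_spec"])
    if d.get("shape_spec"):
        d["shape_spec"] = ShapeSpec(**d["shape_spec"])
    return SceneSpec(**d)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; see ``RunConfig.from_yaml``."""

    # input: either a track CSV ...
    tracks_path: Optional[str] = None
    column_map: Optional[dict] = None
    time_scale: float = 1.0
    length_scale: float = 1.0
    # ... or a synthetic scene
    scene: Optional[SceneSpec] = None

    midline_a: tuple = (0.0, -150.0, 0.0)
    midline_b: tuple = (0.0, 150.0, 0.0)

    filter_enabled: bool = True
    min_duration: int = 10
    min_displacement: float = 5.0

    drift_reference: Optional[object] = None

    divergence: DivergenceParams = field(default_factory=DivergenceParams)

    directionality_mode: str = "3d"
    d_eps: float = DEFAULT_D_EPS
    rose_bin_width: float = 15.0

    shapes_path: Optional[str] = None
    reference_point: Optional[tuple] = None
    divisions_path: Optional[str] = None
    density_radii: tuple = (70.0, 100.0)

    out_dir: str = "tkin_out"
    seed: int = 0
    log_level: str = "INFO"

    def midline(self) -> Midline:
        return Midline(self.midline_a, self.midline_b)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("scene") is not None:
            d["scene"] = scene_from_dict(d["scene"])
        if d.get("divergence") is not None:
            d["divergence"] = DivergenceParams(**d["divergence"])
        for key in ("midline_a", "midline_b", "density_radii", "reference_point"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def echo(self) -> dict:
        """Config (defaults included) as a plain serializable dict."""
        def conv(x):
            if hasattr(x, "__dataclass_fields__"):
                return {k: conv(v) for k, v in asdict(x).items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x
        return {k: conv(v) for k, v in asdict(self).items()}
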