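"""Run configuration: one dataclass bundle, YAML-loadable.

The YAML layout mirrors the processing stages::

    roi:      {vertices: [[r, c], ...]}          # optional
    filters:  {bilateral_diameter: 9, sigma_s: 75, sigma_r: 75,
               threshold: 180, i_max: 255, dilation_kernel: 5}
    canny:    {low: 50, high: 100}
    quantize: {k: 2, max_iter: 200, epsilon: 0.5, seed: 0}
    match:    {min_good: 4, ratio: 0.75, min_area: 9, fallback_area: null}
    motion:   {threshold: 25}
    library:  {dir: chips/, manifest: chips.csv}
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .features import MatchDecisionParams, ReferenceChip
from .filters import BilateralParams, DilationParams, GaussianParams, ThresholdParams
from .edges import CannyParams
from .imaging import RoiPolygon, read_frame
from .quantize import QuantizationParams


@dataclass
class PipelineConfig:
    roi: RoiPolygon | None = None
    bilateral: BilateralParams = field(default_factory=BilateralParams)
    gaussian: GaussianParams = field(default_factory=GaussianParams)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    dilation: DilationParams = field(default_factory=DilationParams)
    canny: CannyParams = field(default_factory=CannyParams)
    quantize: QuantizationParams = field(default_factory=QuantizationParams)
    match: MatchDecisionParams = field(default_factory=MatchDecisionParams)
    motion_threshold: int = 25
    library: list[ReferenceChip] = field(default_factory=list)


def load_chip_library(directory, manifest=None) -> list[ReferenceChip]:
    """Load reference chips from a directory with a ``chip_id,path,label`` CSV."""
    directory = Path(directory)
    manifest = Path(manifest) if manifest else directory / "chips.csv"
    if not manifest.exists():
        raise ConfigurationError(f"chip manifest not found: {manifest}")
    chips = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            img = read_frame(directory / row["path"])
            chips.append(ReferenceChip(image=img, label=row["label"]))
    if not chips:
        raise ConfigurationError(f"chip manifest {manifest} lists no chips")
    return chips


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; absent keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw, base_dir=Path(path).parent)


def config_from_dict(raw: dict, base_dir: Path | None = None) -> PipelineConfig:
    cfg = PipelineConfig()
    if "roi" in raw and raw["roi"]:
        cfg.roi = RoiPolygon(tuple(map(tuple, raw["roi"]["vertices"])))
    f = raw.get("filters", {})
    cfg.bilateral = BilateralParams(
        diameter=int(f.get("bilateral_diameter", 9)),
        sigma_s=float(f.get("sigma_s", 75.0)),
        sigma_r=float(f.get("sigma_r", 75.0)),
    )
    cfg.threshold = ThresholdParams(
        threshold=int(f.get("threshold", 180)), i_max=int(f.get("i_max", 255))
    )
    cfg.dilation = DilationParams(kernel_size=int(f.get("dilation_kernel", 5)))
    c = raw.get("canny", {})
    cfg.canny = CannyParams(
        low_threshold=float(c.get("low", 50.0)), high_threshold=float(c.get("high", 100.0))
    )
    q = raw.get("quantize", {})
    cfg.quantize = QuantizationParams(
        k=int(q.get("k", 2)),
        max_iterations=int(q.get("max_iter", 200)),
        epsilon=float(q.get("epsilon", 0.5)),
        seed=int(q.get("seed", 0)),
    )
    m = raw.get("match", {})
    fallback = m.get("fallback_area")
    cfg.match = MatchDecisionParams(
        min_good_matches=int(m.get("min_good", 4)),
        ratio=float(m.get("ratio", 0.75)),
        min_contour_area=int(m.get("min_area", 9)),
        fallback_area=None if fallback is None else int(fallback),
    )
    cfg.motion_threshold = int(raw.get("motion", {}).get("threshold", 25))
    lib = raw.get("library")
    if lib:
        lib_dir = Path(lib["dir"])
        if base_dir is not None and not lib_dir.is_absolute():
            lib_dir = base_dir / lib_dir
        cfg.library = load_chip_library(lib_dir, lib.get("manifest"))
    return cfg
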