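"""Pipeline configuration: every stage parameter with its default.

Defaults reproduce the analysis thresholds the pipeline is built
around: SNR 5, slope 0.1, circle/annulus radii 3/6 px, 20-80 percentile
background, BT grid 0-0.05 step 0.001, 200 randomization shifts,
terminal ratio cuts 0.4/0.6, module cut 0.2, lifetime cuts 120/480 s,
5-px scission association, sigma = 36 s edge kernel, 2.5x drop screen,
25-unit step, >3 px / >8 s object filter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .screening import ScreeningParams
from .synthetic import SimConfig

VERSION = "0.1.0"


@dataclass
class SegmentationConfig:
    n_scales: int = 3
    k_sigma: float = 3.0
    max_disp_px: float = 4.0
    max_gap_frames: int = 2


@dataclass
class RandomizationConfig:
    n_shifts: int = 200
    terminal_lo: float = 0.4
    terminal_hi: float = 0.6


@dataclass
class CCSConfig:
    association_radius_px: float = 5.0
    edge_sigma_s: float = 36.0
    drop_factor: float = 2.5
    step_units: float = 25.0
    lifetime_cuts_s: tuple[float, float] = (120.0, 480.0)
    n_boot: int = 1000


@dataclass
class DetProbConfig:
    radius_px: float = 3.0
    min_area_px: int = 3
    min_dwell_frames: int = 3


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    screening: ScreeningParams = field(default_factory=ScreeningParams)
    randomization: RandomizationConfig = field(default_factory=RandomizationConfig)
    ccs: CCSConfig = field(default_factory=CCSConfig)
    detprob: DetProbConfig = field(default_factory=DetProbConfig)
    seed: int = 0
    version: str = VERSION

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        if "sim" in kw:
            sim = dict(kw["sim"])
            for key in ("image_size_px", "red_families", "red_family_weights",
                        "vesicle_persist_frames"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            kw["sim"] = SimConfig(**sim)
        for name, typ in (("segmentation", SegmentationConfig),
                          ("screening", ScreeningParams),
                          ("randomization", RandomizationConfig),
                          ("detprob", DetProbConfig)):
            if name in kw:
                kw[name] = typ(**kw[name])
        if "ccs" in kw:
            ccs = dict(kw["ccs"])
            if isinstance(ccs.get("lifetime_cuts_s"), list):
                ccs["lifetime_cuts_s"] = tuple(ccs["lifetime_cuts_s"])
            kw["ccs"] = CCSConfig(**ccs)
        return cls(**kw)

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self, seed=seed)
        cfg.sim = dataclasses.replace(self.sim, rng_seed=seed)
        return cfg
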