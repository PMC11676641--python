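"""Pipeline configuration: campaign design, model parameters, seeds.

A :class:`PipelineConfig` fully determines a synthetic campaign.  The
master seed plus the (salt, concentration, timepoint, replicate, stage)
coordinates of each recording are hashed into per-recording seeds, so
adding a condition never perturbs the data of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .metrics import MotilityCriteria
from .simulate import MotionParams, SceneSpec, SurvivalModel
from .tracking import DetectionParams, LinkingParams
from .viability import SALT_GRIDS, TIMEPOINTS_H

__all__ = [
    "MotilityResponseModel",
    "SaltConfig",
    "CampaignDesign",
    "PlateParams",
    "PipelineConfig",
    "default_config",
    "config_hash",
    "derive_seed",
]


@dataclass
class MotilityResponseModel:
    """Ground-truth motile fraction of a salt condition relative to control.

    The response is a plateau-exponential decay in time (scaled by the
    concentration in mol/L) times an optional transient stimulation pulse
    peaking at ``stim_peak_h`` - salt stress transiently raises the motile
    fraction before toxicity wins.  Values above 1 are allowed (stimulated
    samples); the resulting absolute motile fraction is clipped to 1.
    """

    plateau: float = 0.0
    decay_rate_per_M_h: float = 1.0
    stim_amplitude: float = 0.0
    stim_peak_h: float = 1.0

    def relative_fraction(self, concentration_M: float, t_hours: float) -> float:
        k = self.decay_rate_per_M_h * concentration_M
        base = self.plateau + (1.0 - self.plateau) * math.exp(-k * t_hours)
        if self.stim_amplitude > 0:
            x = t_hours / self.stim_peak_h
            base *= 1.0 + self.stim_amplitude / (1.0 + concentration_M) * x * math.exp(1.0 - x)
        return base


@dataclass
class SaltConfig:
    name: str
    concentrations: tuple[float, ...]
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    motility: MotilityResponseModel = field(default_factory=MotilityResponseModel)

    def survival_at(self, concentration_M: float, t_hours: float) -> float:
        m = SurvivalModel(
            plateau_fraction=self.survival.plateau_fraction,
            decay_rate=self.survival.decay_rate * concentration_M,
            label=self.survival.label,
        )
        return float(m.survival(t_hours))


@dataclass
class CampaignDesign:
    """Which conditions to run and how many replicates of each."""

    salts: list[SaltConfig]
    timepoints: tuple[float, ...] = TIMEPOINTS_H
    n_bio_replicates: int = 3
    n_tech_replicates: int = 3
    cells_per_scene: int = 100
    control_motile_fraction: float = 0.07

    def __post_init__(self) -> None:
        if not 0.0 <= self.control_motile_fraction <= 1.0:
            raise ValueError("control_motile_fraction must be in [0, 1]")
        if self.n_bio_replicates < 1 or self.n_tech_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.cells_per_scene < 1:
            raise ValueError("cells_per_scene must be >= 1")


@dataclass
class PlateParams:
    baseline_cfu_per_ml: float = 2e7
    dilution: float = 1e4
    plated_volume_ml: float = 0.05
    n_replicates: int = 3


@dataclass
class PipelineConfig:
    """Everything a campaign run needs, schema-validated on construction."""

    design: CampaignDesign
    motion: MotionParams = field(default_factory=MotionParams)
    scene: SceneSpec = field(
        default_factory=lambda: SceneSpec(width_px=640, height_px=480)
    )
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    criteria: MotilityCriteria | None = None  # None -> calibrate per campaign
    plate: PlateParams = field(default_factory=PlateParams)
    master_seed: int = 0
    render_images: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        salts = [
            SaltConfig(
                name=s["name"],
                concentrations=tuple(s["concentrations"]),
                survival=SurvivalModel(**s.get("survival", {})),
                motility=MotilityResponseModel(**s.get("motility", {})),
            )
            for s in d["design"].pop("salts")
        ]
        design = CampaignDesign(salts=salts, **{
            k: tuple(v) if k == "timepoints" else v for k, v in d.pop("design").items()
        })
        kwargs: dict = {"design": design}
        if "motion" in d:
            kwargs["motion"] = MotionParams(**d.pop("motion"))
        if "scene" in d:
            kwargs["scene"] = SceneSpec(**d.pop("scene"))
        if "detection" in d:
            kwargs["detection"] = DetectionParams(**d.pop("detection"))
        if "linking" in d:
            kwargs["linking"] = LinkingParams(**d.pop("linking"))
        if "criteria" in d:
            c = d.pop("criteria")
            kwargs["criteria"] = MotilityCriteria(**c) if c else None
        if "plate" in d:
            kwargs["plate"] = PlateParams(**d.pop("plate"))
        for k in ("master_seed", "render_images"):
            if k in d:
                kwargs[k] = d.pop(k)
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(master_seed: int = 0) -> PipelineConfig:
    """The full synthetic campaign mirroring the study design.

    Three salts on their tested concentration grids at 0.01/1/4/24 h, in
    biological and technical triplicates.  Survival and motility-response
    parameters encode the qualitative ordering (chloride least harmful,
    perchlorate most; transient motility stimulation at low chlorate and
    perchlorate concentrations), not any measured values.
    """
    salts = [
        SaltConfig(
            name="NaCl",
            concentrations=SALT_GRIDS["NaCl"],
            survival=SurvivalModel(plateau_fraction=0.45, decay_rate=2.0, label="NaCl"),
            motility=MotilityResponseModel(
                plateau=0.1, decay_rate_per_M_h=1.5, stim_amplitude=0.5
            ),
        ),
        SaltConfig(
            name="NaClO3",
            concentrations=SALT_GRIDS["NaClO3"],
            survival=SurvivalModel(plateau_fraction=0.05, decay_rate=8.0, label="NaClO3"),
            motility=MotilityResponseModel(
                plateau=0.0, decay_rate_per_M_h=4.0, stim_amplitude=1.0
            ),
        ),
        SaltConfig(
            name="NaClO4",
            concentrations=SALT_GRIDS["NaClO4"],
            survival=SurvivalModel(plateau_fraction=0.0, decay_rate=12.0, label="NaClO4"),
            motility=MotilityResponseModel(
                plateau=0.0, decay_rate_per_M_h=6.0, stim_amplitude=0.8
            ),
        ),
    ]
    return PipelineConfig(design=CampaignDesign(salts=salts), master_seed=master_seed)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration, stamped on artifacts."""
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def derive_seed(master_seed: int, *parts) -> int:
    """Deterministic per-recording seed below 2^31 from campaign coordinates."""
    key = "|".join([str(master_seed), *[str(p) for p in parts]])
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big") % (2**31)
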