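"""Configuration objects for simulation and pipeline runs.

All simulation parameters live in :class:`SimulationConfig`; the defaults are
the package's reference cohort: 23 control and 26 stressed mice with a
susceptible fraction of 14/26, imaged at days (-10, 2, 5, 11, 17) relative to
the last defeat day, CSF proteome with group sizes 17/11/10.  Every generator
derives its random stream from ``(seed, stage_tag)`` so adding a stage never
perturbs an earlier one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

__all__ = [
    "ConfigError",
    "BehaviorParams",
    "HillParams",
    "SpineParams",
    "ImageParams",
    "ProteomeParams",
    "SimulationConfig",
    "RunConfig",
    "load_config",
    "config_hash",
]

PHENOTYPES = ("control", "resilient", "susceptible")

#: stable per-stage tags for seed fan-out (never renumber)
STAGE_TAGS = {
    "behavior": 1,
    "rotarod": 2,
    "reaching": 3,
    "spines": 4,
    "microglia": 5,
    "coloc": 6,
    "proteome": 7,
}


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioral test distributions.

    Healthy-component means/sds are module choices sized to typical published
    cohorts; ``effect`` is how far (in natural units) the susceptible-component
    mean lies *beyond* each pathological cutoff.
    """

    healthy_mean: tuple[float, float, float] = (75.0, 4.6, 80.0)
    healthy_sd: tuple[float, float, float] = (8.0, 0.6, 15.0)
    susceptible_sd: tuple[float, float, float] = (8.0, 0.6, 15.0)
    #: mean shift beyond the (60 %, 4, 50 s) cutoffs for susceptible animals
    effect: tuple[float, float, float] = (15.0, 1.5, 30.0)

    def validate(self) -> None:
        for sd in (*self.healthy_sd, *self.susceptible_sd):
            if sd <= 0:
                raise ConfigError(f"behavior sd must be > 0, got {sd}")


@dataclass(frozen=True)
class HillParams:
    """Hill-sigmoid learning-curve parameters for one phenotype."""

    t0: float = 20.0
    tmax: float = 60.0
    ls50: float = 6.0
    h: float = 2.5
    noise_sd: float = 5.0

    def validate(self) -> None:
        if not (0 <= self.t0 <= self.tmax):
            raise ConfigError(f"need 0 <= t0 <= tmax, got t0={self.t0}, tmax={self.tmax}")
        if self.ls50 <= 0 or self.h <= 0:
            raise ConfigError("ls50 and h must be > 0")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class SpineParams:
    """Per-phenotype birth/death parameters of the spine timeline."""

    initial_density_per_um: float = 0.40
    loss_prob: float = 0.10
    gain_rate: float = 0.10
    taskborn_survival: float = 0.60

    def validate(self) -> None:
        for p in (self.loss_prob, self.taskborn_survival):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability out of [0,1]: {p}")
        if self.initial_density_per_um <= 0 or self.gain_rate < 0:
            raise ConfigError("density must be > 0 and gain_rate >= 0")


@dataclass(frozen=True)
class ImageParams:
    """Synthetic confocal field parameters.

    1024 px at 0.44 um/px reproduces a 450 um field of view.
    """

    pixel_size_um: float = 0.44
    image_size_px: int = 1024
    n_cells: int = 5
    n_branches: tuple[int, int] = (3, 6)
    branch_length_px: tuple[int, int] = (50, 110)
    branch_width_px: int = 2
    background_level: int = 12
    foreground_level: int = 140
    noise_sd: float = 4.0
    n_segments: int = 6
    segment_length_px: tuple[int, int] = (80, 160)
    coloc_fraction: float = 0.30

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if not 0 <= self.coloc_fraction <= 1:
            raise ConfigError("coloc_fraction must be in [0,1]")
        if self.n_cells < 0 or self.image_size_px <= 0:
            raise ConfigError("counts must be >= 0 and image size > 0")


@dataclass(frozen=True)
class ProteomeParams:
    """CSF protein-group matrix parameters (group design 17/11/10)."""

    n_proteins: int = 1906
    group_sizes: tuple[int, int, int] = (17, 11, 10)  # control, resilient, susceptible
    base_mean_log2: float = 20.0
    base_sd_log2: float = 2.0
    sample_sd_log2: float = 0.30
    sample_offset_sd_log2: float = 0.20
    missing_rate: float = 0.10
    n_spiked: int = 15
    spike_log2fc: float = 2.0

    def validate(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0,1)")
        if self.n_proteins <= 0 or any(g <= 0 for g in self.group_sizes):
            raise ConfigError("protein and group counts must be > 0")
        if 2 * self.n_spiked > self.n_proteins:
            raise ConfigError("too many spiked proteins for matrix size")


def _phenomap(cls, overrides: Mapping[str, Mapping[str, Any]] | None, defaults):
    out = dict(defaults)
    for k, v in (overrides or {}).items():
        if k not in PHENOTYPES:
            raise ConfigError(f"unknown phenotype {k!r}")
        out[k] = dataclasses.replace(out[k], **v) if isinstance(v, Mapping) else v
    return out


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_control: int = 23
    n_stressed: int = 26
    susceptible_fraction: float = 14 / 26
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    rotarod: Mapping[str, HillParams] = field(
        default_factory=lambda: {
            "control": HillParams(20.0, 60.0, 6.0, 2.5, 5.0),
            "resilient": HillParams(20.0, 75.0, 4.5, 2.5, 5.0),
            "susceptible": HillParams(18.0, 35.0, 5.0, 2.5, 5.0),
        }
    )
    reaching: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "control": (0.10, 0.20, 0.30, 0.38, 0.45),
            "resilient": (0.10, 0.12, 0.15, 0.16, 0.17),
            "susceptible": (0.08, 0.10, 0.12, 0.12, 0.13),
        }
    )
    spines: Mapping[str, SpineParams] = field(
        default_factory=lambda: {
            # loss/gain tuned so expected day-2 normalized densities are
            # ~105 / 91 / 83 % of baseline
            "control": SpineParams(0.40, 0.10, 0.15, 0.70),
            "resilient": SpineParams(0.40, 0.19, 0.10, 0.60),
            "susceptible": SpineParams(0.40, 0.27, 0.10, 0.45),
        }
    )
    session_days: tuple[int, ...] = (-10, 2, 5, 11, 17)
    rois_per_animal: int = 3
    dendrite_length_um: tuple[float, float] = (40.0, 80.0)
    images: ImageParams = field(default_factory=ImageParams)
    proteome: ProteomeParams = field(default_factory=ProteomeParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_control < 0 or self.n_stressed < 0:
            raise ConfigError("cohort sizes must be >= 0")
        if not 0 <= self.susceptible_fraction <= 1:
            raise ConfigError(
                f"susceptible_fraction must be in [0,1], got {self.susceptible_fraction}"
            )
        if len(self.session_days) == 0:
            raise ConfigError("session schedule must not be empty")
        if list(self.session_days) != sorted(set(self.session_days)):
            raise ConfigError("session days must be strictly increasing")
        self.behavior.validate()
        for m in (self.rotarod, self.spines):
            for p in PHENOTYPES:
                if p not in m:
                    raise ConfigError(f"missing phenotype parameters for {p!r}")
        for hp in self.rotarod.values():
            hp.validate()
        for sp in self.spines.values():
            sp.validate()
        for probs in self.reaching.values():
            if any(not 0 <= q <= 1 for q in probs):
                raise ConfigError("reaching success probabilities must be in [0,1]")
        self.images.validate()
        self.proteome.validate()

    def rng(self, stage: str):
        """Independent random generator for one pipeline stage."""
        import numpy as np

        return np.random.default_rng([int(self.seed), STAGE_TAGS[stage]])

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline run configuration."""

    outdir: Path
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = (
        "simulate",
        "classify",
        "motor",
        "spines",
        "glia",
        "proteome",
        "report",
    )
    interaction_cutoff_inclusive: bool = False
    turnover_denominator: str = "previous"  # or "baseline"
    min_valid_scope: str = "all_groups"  # or "any_group"

    def __post_init__(self) -> None:
        object.__setattr__(self, "outdir", Path(self.outdir))
        known = {"simulate", "classify", "motor", "spines", "glia", "proteome", "report"}
        bad = set(self.stages) - known
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")


def _build_sim(d: Mapping[str, Any]) -> SimulationConfig:
    d = dict(d)
    kw: dict[str, Any] = {}
    for key in ("seed", "n_control", "n_stressed", "susceptible_fraction",
                "rois_per_animal"):
        if key in d:
            kw[key] = d.pop(key)
    if "session_days" in d:
        kw["session_days"] = tuple(d.pop("session_days"))
    if "dendrite_length_um" in d:
        kw["dendrite_length_um"] = tuple(d.pop("dendrite_length_um"))
    if "behavior" in d:
        b = dict(d.pop("behavior"))
        for k in list(b):
            if isinstance(b[k], list):
                b[k] = tuple(b[k])
        kw["behavior"] = BehaviorParams(**b)
    if "images" in d:
        im = dict(d.pop("images"))
        for k in list(im):
            if isinstance(im[k], list):
                im[k] = tuple(im[k])
        kw["images"] = ImageParams(**im)
    if "proteome" in d:
        pr = dict(d.pop("proteome"))
        if "group_sizes" in pr:
            pr["group_sizes"] = tuple(pr["group_sizes"])
        kw["proteome"] = ProteomeParams(**pr)
    base = SimulationConfig()
    if "rotarod" in d:
        kw["rotarod"] = _phenomap(HillParams, d.pop("rotarod"), base.rotarod)
    if "spines" in d:
        kw["spines"] = _phenomap(SpineParams, d.pop("spines"), base.spines)
    if "reaching" in d:
        kw["reaching"] = {k: tuple(v) for k, v in {**base.reaching, **d.pop("reaching")}.items()}
    if d:
        raise ConfigError(f"unknown simulation keys: {sorted(d)}")
    return SimulationConfig(**kw)


def load_config(path: str | Path) -> RunConfig:
    """Load a run configuration from TOML (default) or YAML."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
    else:
        data = tomllib.loads(path.read_text())
    if not isinstance(data, Mapping):
        raise ConfigError(f"config root must be a table, got {type(data).__name__}")
    data = dict(data)
    sim = _build_sim(data.pop("simulation", {}))
    kw: dict[str, Any] = {"sim": sim}
    kw["outdir"] = Path(data.pop("outdir", "csdstools-run"))
    if "stages" in data:
        kw["stages"] = tuple(data.pop("stages"))
    for key in ("interaction_cutoff_inclusive", "turnover_denominator", "min_valid_scope"):
        if key in data:
            kw[key] = data.pop(key)
    if data:
        raise ConfigError(f"unknown config keys: {sorted(data)}")
    return RunConfig(**kw)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def config_hash(cfg: RunConfig | SimulationConfig) -> str:
    """Stable short hash of a configuration, for provenance headers.

    The output directory is excluded: the same analysis written elsewhere is
    the same run.
    """
    payload = _jsonable(cfg)
    if isinstance(payload, dict):
        payload.pop("outdir", None)
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
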