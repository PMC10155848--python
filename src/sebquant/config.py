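"""Run configuration: per-stage settings, YAML round-trip, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "SkinStage", "SwatchStage", "SemStage", "StudyStage",
           "load_config", "dump_config"]


@dataclass
class SkinStage:
    """Simulated in-vivo arm: formulae spanning a cleanability range."""

    n_formulae: int = 12
    areas_per_formula: int = 3
    baseline_dark_fraction: float = 40.0
    truth_range: tuple[float, float] = (5.0, 100.0)
    image_shape: tuple[int, int] = (128, 128)
    threshold: str = "otsu"


@dataclass
class SwatchStage:
    """Simulated in-vitro swatch arm."""

    n_formulae: int = 5
    n_replicates: int = 6
    truth_range: tuple[float, float] = (40.0, 80.0)
    L_control: float = 85.0
    L_sebollution: float = 35.0
    noise_sd: float = 1.0


@dataclass
class SemStage:
    """Simulated anti-deposit arm: SEM fields per product and category."""

    products_per_category: int = 1
    fibers_per_product: int = 6
    image_shape: tuple[int, int] = (256, 256)
    pixel_scale: float | None = 0.25  # um/px
    noise_level: float = 0.08
    threshold: str = "otsu"
    min_diameter_um: float = 0.5
    # Category-level true median coverages (percent of fiber surface).
    category_coverage: dict = field(default_factory=lambda: {
        "shampoo": 6.2, "conditioner": 7.5, "mask": 8.8, "leave_on": 9.5,
    })


@dataclass
class StudyStage:
    """Paired-site calibration table."""

    n_formulae: int = 4
    slope: float = 1.0
    intercept: float = 0.0
    noise_sd: float | None = None  # calibrated for target_r2 when None
    target_r2: float = 0.942


@dataclass
class RunConfig:
    """Full end-to-end run configuration.

    A fixed ``seed`` makes the whole pipeline bit-reproducible: every
    stage derives its own random stream from it.
    """

    seed: int = 0
    out_dir: str = "sebq_results"
    log_level: str = "INFO"
    make_plots: bool = True
    skin: SkinStage = field(default_factory=SkinStage)
    swatch: SwatchStage = field(default_factory=SwatchStage)
    sem: SemStage = field(default_factory=SemStage)
    study: StudyStage = field(default_factory=StudyStage)

    def validate(self) -> None:
        if self.sem.pixel_scale is None or self.sem.pixel_scale <= 0:
            raise ValueError(
                "coverage stage: pixel_scale (um/px) is missing or non-positive"
            )
        if self.skin.n_formulae < 2 or self.study.n_formulae < 3:
            raise ValueError("skin stage needs >= 2 and study stage >= 3 formulae")
        if self.swatch.L_control <= self.swatch.L_sebollution:
            raise ValueError("swatch stage: L_control must exceed L_sebollution")

    def to_dict(self) -> dict:
        return asdict(self)


_STAGES = {"skin": SkinStage, "swatch": SwatchStage,
           "sem": SemStage, "study": StudyStage}


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("truth_range", "image_shape"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for name, cls in _STAGES.items():
        section = data.pop(name, {})
        kwargs[name] = _build(cls, section) if isinstance(section, dict) else section
    top_known = {f.name for f in fields(RunConfig)} - set(_STAGES)
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config file; absent sections get their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(config: RunConfig) -> str:
    """YAML text with every effective setting, suitable as a config file."""
    return yaml.safe_dump(config.to_dict(), sort_keys=False)
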