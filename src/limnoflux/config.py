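"""Pipeline configuration: a nested key/value (YAML) file mapped onto
dataclasses with validation at load time."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from limnoflux.agemodel import AgeModelSettings
from limnoflux.errors import ParameterError, SchemaError

__all__ = ["LakeConfig", "PipelineConfig", "load_config"]


@dataclass
class LakeConfig:
    name: str
    dates: str
    proxies: str
    diatoms: str | None = None
    core_depth: float | None = None
    acc_mean: float | None = None


@dataclass
class FluxSettings:
    om_factor: float = 1.724
    density_fallback: float | None = None
    exclude_events: bool = True


@dataclass
class ChangePointSettings:
    min_segment: int = 5
    slope_delta_min: float = 0.1
    basis_dim: int = 10
    smoothing: str = "gcv"
    n_draws: int = 2000
    level: float = 0.95
    variables: tuple[str, ...] = ("toc_flux", "l_flux", "cn", "d13c")


@dataclass
class PCASettings:
    bin_width: float = 25.0
    t0: float = 800.0
    t1: float = 2015.0
    n_members_used: int = 100
    n_components: int = 2
    organic: tuple[str, ...] = ("toc_flux", "cn", "d13c")
    lithogenic: tuple[str, ...] = ("l_flux", "pc1_comp")

    def __post_init__(self) -> None:
        if not self.organic or not self.lithogenic:
            raise ParameterError("PCA variable sets must be non-empty")


@dataclass
class PipelineConfig:
    lakes: list[LakeConfig]
    seed: int = 0
    output_dir: str = "limnoflux_out"
    collection_year: float = 2015.0
    calibration_curve: str | None = None
    agemodel: AgeModelSettings = field(default_factory=AgeModelSettings)
    flux: FluxSettings = field(default_factory=FluxSettings)
    changepoint: ChangePointSettings = field(default_factory=ChangePointSettings)
    pca: PCASettings = field(default_factory=PCASettings)

    def validate_files(self, base: Path | None = None) -> None:
        base = base or Path(".")
        missing = []
        for lake in self.lakes:
            for attr in ("dates", "proxies", "diatoms"):
                p = getattr(lake, attr)
                if p is not None and not (base / p).exists():
                    missing.append(str(base / p))
        if self.calibration_curve and not (base / self.calibration_curve).exists():
            missing.append(str(base / self.calibration_curve))
        if missing:
            raise SchemaError(f"configured file(s) not found: {missing}")

    def as_dict(self) -> dict:
        return asdict(self)


def _build(cls, payload: dict, what: str):
    try:
        return cls(**payload)
    except TypeError as exc:
        raise SchemaError(f"bad {what} configuration: {exc}") from None


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration."""
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"config file not found: {path}")
    raw = yaml.safe_load(p.read_text()) or {}
    if "lakes" not in raw or not raw["lakes"]:
        raise SchemaError("config must list at least one lake")
    lakes = [_build(LakeConfig, lk, "lake") for lk in raw.pop("lakes")]
    cfg = PipelineConfig(
        lakes=lakes,
        seed=int(raw.pop("seed", 0)),
        output_dir=str(raw.pop("output_dir", "limnoflux_out")),
        collection_year=float(raw.pop("collection_year", 2015.0)),
        calibration_curve=raw.pop("calibration_curve", None),
        agemodel=_build(AgeModelSettings, raw.pop("agemodel", {}), "agemodel"),
        flux=_build(FluxSettings, raw.pop("flux", {}), "flux"),
        changepoint=_build(ChangePointSettings, raw.pop("changepoint", {}), "changepoint"),
        pca=_build(PCASettings, raw.pop("pca", {}), "pca"),
    )
    if raw:
        raise SchemaError(f"unknown config keys: {sorted(raw)}")
    cfg.validate_files(p.parent)
    return cfg
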