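"""Configuration loading and validation.

A single YAML file holds every tunable constant of the pipeline
(transient shapes, cell parameters, geometry, hemodynamics,
discretization and the A:B slice bands).  ``load_config`` validates it
against a strict schema (unknown keys rejected) and applies package
defaults for anything omitted.  The fully resolved configuration can be
echoed back to disk for reproducibility.
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path
from typing import Annotated

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config", "package_defaults"]

Positive = Annotated[float, Field(gt=0)]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TransientBlock(_Strict):
    c_dia: Positive
    c_amp: Positive
    tau_rise: Positive
    tau_decay: Positive
    t_cycle: Positive

    @model_validator(mode="after")
    def _rise_before_decay(self):
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        return self


class TransientsBlock(_Strict):
    control: TransientBlock
    stimulated: TransientBlock


class ContractionBlock(_Strict):
    t_ref: Positive
    ca_t50_ref: Positive
    k_xb: Positive
    k_trpn: Positive
    n_trpn: Annotated[float, Field(ge=1)]
    n_xb: Annotated[float, Field(ge=1)]
    beta1: Annotated[float, Field(le=0)]


class GeometryBlock(_Strict):
    n_slices: Annotated[int, Field(ge=6)]
    base_radius: Positive
    length: Positive
    taper: Annotated[float, Field(gt=0, lt=1)]
    wall_ratio_base: Positive
    wall_ratio_apex: Positive
    passive_a: Positive
    passive_b: Positive
    target_edv: Annotated[float, Field(ge=100, le=150)]


class HemodynamicsBlock(_Strict):
    c_art_ml_per_mmhg: Positive
    r_per: Positive
    z_c: Positive
    p_a: Positive
    edp: Positive


class DiscretizationBlock(_Strict):
    dt: Annotated[float, Field(gt=0, le=0.5)]
    n_pacing_cycles: Annotated[int, Field(ge=1)]


class MetricsBlock(_Strict):
    apical_band: tuple[float, float]
    basal_band: tuple[float, float]

    @model_validator(mode="after")
    def _bands_valid(self):
        for name, (lo, hi) in (
            ("apical_band", self.apical_band),
            ("basal_band", self.basal_band),
        ):
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"{name} must satisfy 0 <= lo < hi <= 1")
        if self.apical_band[1] > self.basal_band[0]:
            raise ValueError("apical and basal bands must not overlap")
        return self


class RunConfig(_Strict):
    """Fully resolved pipeline configuration."""

    transients: TransientsBlock
    contraction: ContractionBlock
    geometry: GeometryBlock
    hemodynamics: HemodynamicsBlock
    discretization: DiscretizationBlock
    metrics: MetricsBlock

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        )


@functools.lru_cache(maxsize=1)
def _defaults_text() -> str:
    return resources.files("takolv").joinpath("defaults.yaml").read_text()


def package_defaults() -> dict:
    """The package default configuration as a plain dictionary."""
    return yaml.safe_load(_defaults_text())


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def default_config() -> RunConfig:
    """Validated RunConfig built from the package defaults."""
    return RunConfig.model_validate(package_defaults())


def load_config(path=None, echo_dir=None) -> RunConfig:
    """Load a YAML config, merge over package defaults, validate.

    Parameters
    ----------
    path:
        YAML file with any subset of the configuration blocks; ``None``
        uses the package defaults unchanged.
    echo_dir:
        If given, the fully resolved configuration is written to
        ``<echo_dir>/resolved_config.yaml`` for provenance.
    """
    merged = package_defaults()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        merged = _deep_merge(merged, user)
    cfg = RunConfig.model_validate(merged)
    if echo_dir is not None:
        echo_dir = Path(echo_dir)
        echo_dir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(echo_dir / "resolved_config.yaml")
    return cfg
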