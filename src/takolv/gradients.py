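"""Apex-base activation gradients and mechanism parameter fields.

The normalised coordinate ``z`` runs from 0 at the apex to 1 at the
base.  A gradient is defined by two fractions: ``z_a``, the apical
region that is minimally beta-adrenergically activated (beta = 0), and
``z_b``, the basal region that is maximally activated (beta = 1), with
a linear ramp in between.

Three mechanism models translate the local activation level beta into
cell-level inputs:

* ``transient`` — the calcium transient blends from control (apex) to
  stimulated (base); calcium sensitivity is homogeneously reduced
  (``Ca_T50`` raised), ``T_ref`` normal.
* ``sensitivity`` — the stimulated transient applies everywhere; the
  troponin half-activation ``Ca_T50`` ramps from a high apical value
  (low sensitivity) down to the basal value.
* ``tension`` — the stimulated transient applies everywhere (a
  catecholamine-overload context; configurable); maximal tension
  ``T_ref`` ramps from a reduced apical value up to the normal
  120 kPa, emulating apical cross-bridge inhibition.

The module also enumerates the three sweep grids (72, 90 and 216
configurations; 378 in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .calcium import CalciumTransient, blend_transients

__all__ = [
    "GradientSpec",
    "MechanismConfig",
    "SliceInputs",
    "T_REF_NORMAL",
    "GRADIENT_GRID",
    "beta_of_z",
    "slice_parameters",
    "grid_mechanism_transient",
    "grid_mechanism_sensitivity",
    "grid_mechanism_tension",
    "all_grids",
]

#: Normal maximal active tension, kPa.
T_REF_NORMAL = 120.0

Mechanism = Literal["transient", "sensitivity", "tension"]


@dataclass(frozen=True)
class GradientSpec:
    """Sizes of the minimally activated apical and maximally activated
    basal regions, as fractions of the apex-base axis."""

    z_a: float
    z_b: float

    def __post_init__(self) -> None:
        if self.z_a < 0 or self.z_b < 0:
            raise ValueError("z_a and z_b must be non-negative")
        if self.z_a + self.z_b > 1 + 1e-12:
            raise ValueError("z_a + z_b must not exceed 1")


#: The nine gradient shapes used in every sweep: all combinations of
#: apical/basal region sizes 0, 25 and 50% of the long axis.
GRADIENT_GRID: tuple[GradientSpec, ...] = tuple(
    GradientSpec(z_a=za, z_b=zb) for za in (0.0, 0.25, 0.5) for zb in (0.0, 0.25, 0.5)
)


def beta_of_z(z, spec: GradientSpec):
    """Local beta-adrenergic activation fraction at coordinate ``z``.

    0 for ``z <= z_a``, 1 for ``z >= 1 - z_b``, linear in between.  When
    ``z_a + z_b = 1`` the ramp degenerates to a step at ``z = z_a``.
    Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ValueError("z must lie in [0, 1]")
    span = 1.0 - spec.z_a - spec.z_b
    if span <= 1e-12:
        beta = np.where(z <= spec.z_a, 0.0, 1.0)
    else:
        beta = np.clip((z - spec.z_a) / span, 0.0, 1.0)
    return float(beta) if beta.ndim == 0 else beta


@dataclass(frozen=True)
class MechanismConfig:
    """One point of a mechanism sweep.

    Mechanism-specific fields: ``ca_t50_homog`` (transient & tension),
    ``ca_t50_apex``/``ca_t50_base`` (sensitivity), ``t_ref_apex``
    (tension).  ``beta1`` and ``p_a`` record the length-dependence and
    afterload settings under which the configuration is run.
    """

    mechanism: Mechanism
    gradient: GradientSpec
    ca_t50_homog: float | None = None
    ca_t50_apex: float | None = None
    ca_t50_base: float | None = None
    t_ref_apex: float | None = None
    beta1: float = -1.5
    p_a: float = 9.0
    stimulated_everywhere: bool = True  # mechanism "tension" transient choice

    def __post_init__(self) -> None:
        required = {
            "transient": ("ca_t50_homog",),
            "sensitivity": ("ca_t50_apex", "ca_t50_base"),
            "tension": ("ca_t50_homog", "t_ref_apex"),
        }
        if self.mechanism not in required:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for name in required[self.mechanism]:
            if getattr(self, name) is None:
                raise ValueError(
                    f"mechanism {self.mechanism!r} requires field {name!r}"
                )
        if self.mechanism == "sensitivity" and self.ca_t50_apex < self.ca_t50_base:
            raise ValueError("ca_t50_apex must be >= ca_t50_base")

    @property
    def config_id(self) -> str:
        """Deterministic identifier built from the config fields."""
        parts = [
            self.mechanism,
            f"za{self.gradient.z_a:g}",
            f"zb{self.gradient.z_b:g}",
        ]
        for name in ("ca_t50_homog", "ca_t50_apex", "ca_t50_base", "t_ref_apex"):
            val = getattr(self, name)
            if val is not None:
                parts.append(f"{name.split('_')[-1]}{val:g}")
        parts.append(f"b1{self.beta1:g}")
        parts.append(f"pa{self.p_a:g}")
        return "-".join(parts)


@dataclass(frozen=True)
class SliceInputs:
    """Cell-level inputs for one ventricular slice."""

    transient: CalciumTransient
    ca_t50: float  # uM
    t_ref: float  # kPa
    beta: float = field(default=0.0, compare=False)


def slice_parameters(
    config: MechanismConfig,
    z: float,
    control: CalciumTransient,
    stimulated: CalciumTransient,
) -> SliceInputs:
    """Cell inputs (transient, Ca_T50, T_ref) at apex-base position ``z``."""
    beta = beta_of_z(z, config.gradient)
    if config.mechanism == "transient":
        return SliceInputs(
            transient=blend_transients(control, stimulated, beta),
            ca_t50=config.ca_t50_homog,
            t_ref=T_REF_NORMAL,
            beta=beta,
        )
    if config.mechanism == "sensitivity":
        return SliceInputs(
            transient=stimulated,
            ca_t50=config.ca_t50_apex + beta * (config.ca_t50_base - config.ca_t50_apex),
            t_ref=T_REF_NORMAL,
            beta=beta,
        )
    # tension mechanism
    return SliceInputs(
        transient=stimulated if config.stimulated_everywhere else control,
        ca_t50=config.ca_t50_homog,
        t_ref=config.t_ref_apex + beta * (T_REF_NORMAL - config.t_ref_apex),
        beta=beta,
    )


def grid_mechanism_transient() -> list[MechanismConfig]:
    """Calcium-transient-gradient sweep: 9 gradients x 8 homogeneous
    Ca_T50 values from 0.6 to 1.5 uM (72 configurations)."""
    ca_values = np.linspace(0.6, 1.5, 8)
    return [
        MechanismConfig(mechanism="transient", gradient=g, ca_t50_homog=float(ca))
        for g in GRADIENT_GRID
        for ca in ca_values
    ]


def grid_mechanism_sensitivity() -> list[MechanismConfig]:
    """Calcium-sensitivity-gradient sweep: 9 gradients x 10 apical
    Ca_T50 values from 1.0 to 4.0 uM with basal Ca_T50 = 1.0 uM
    (90 configurations)."""
    ca_values = np.linspace(1.0, 4.0, 10)
    return [
        MechanismConfig(
            mechanism="sensitivity",
            gradient=g,
            ca_t50_apex=float(ca),
            ca_t50_base=1.0,
        )
        for g in GRADIENT_GRID
        for ca in ca_values
    ]


def grid_mechanism_tension() -> list[MechanismConfig]:
    """Maximum-tension-gradient sweep: 9 gradients x 3 apical T_ref
    values {30, 60, 90} kPa x 8 homogeneous Ca_T50 values from 0.6 to
    1.3 uM (216 configurations)."""
    ca_values = np.linspace(0.6, 1.3, 8)
    return [
        MechanismConfig(
            mechanism="tension",
            gradient=g,
            t_ref_apex=t_ref,
            ca_t50_homog=float(ca),
        )
        for g in GRADIENT_GRID
        for t_ref in (30.0, 60.0, 90.0)
        for ca in ca_values
    ]


def all_grids(beta1: float = -1.5, p_a: float = 9.0) -> list[MechanismConfig]:
    """All 378 sweep configurations, optionally re-tagged with a
    length-dependence coefficient and afterload setting."""
    configs = (
        grid_mechanism_transient()
        + grid_mechanism_sensitivity()
        + grid_mechanism_tension()
    )
    if beta1 != -1.5 or p_a != 9.0:
        configs = [replace(c, beta1=beta1, p_a=p_a) for c in configs]
    return configs
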