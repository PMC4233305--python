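"""Three-element Windkessel afterload.

During ejection the ventricle sees an aortic pressure
``p_ao = p_wk + z_c * q`` where ``q`` is the outflow (ul/ms), ``z_c``
the characteristic impedance, and the lumped arterial pressure ``p_wk``
obeys ``C * dp_wk/dt = q - p_wk / R`` with compliance ``C`` and
peripheral resistance ``R``.

Unit conventions: pressures are kPa, volumes ul, times ms throughout;
the aortic compliance is accepted in ml/mmHg as conventionally printed
and converted once (1 mmHg = 0.133322 kPa, 1 ml = 1000 ul), so
``C [ul/kPa] = 1000 * C [ml/mmHg] / 0.133322``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "MMHG_KPA",
    "WindkesselParams",
    "windkessel_step",
    "make_afterload_variants",
    "calibrate_hemodynamics",
    "default_windkessel",
]

#: 1 mmHg in kPa.
MMHG_KPA = 0.133322


@dataclass(frozen=True)
class WindkesselParams:
    """Afterload and cycle-phase pressure parameters.

    Attributes
    ----------
    c_art_ml_per_mmhg:
        Aortic compliance in ml/mmHg (printed convention; 0.0144 by
        default).
    r_per:
        Peripheral resistance, kPa*ms/ul.
    z_c:
        Characteristic (proximal aortic) impedance, kPa*ms/ul.
    p_a:
        Minimal aortic pressure at which ejection starts, kPa (9 kPa
        control; 11.25 and 13.5 kPa in the increased-afterload cases).
    edp:
        End-diastolic pressure, kPa.
    """

    c_art_ml_per_mmhg: float = 0.0144
    r_per: float = 20.0
    z_c: float = 2.0
    p_a: float = 9.0
    edp: float = 0.5

    def __post_init__(self) -> None:
        for name in ("c_art_ml_per_mmhg", "r_per", "z_c", "p_a", "edp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"WindkesselParams.{name} must be positive")

    @property
    def c_art(self) -> float:
        """Compliance in ul/kPa."""
        return self.c_art_ml_per_mmhg * 1000.0 / MMHG_KPA


def default_windkessel() -> WindkesselParams:
    """Windkessel parameters from the package defaults."""
    from .config import package_defaults

    return WindkesselParams(**package_defaults()["hemodynamics"])


def windkessel_step(
    p_wk: float, q: float, params: WindkesselParams, dt: float
) -> float:
    """Advance the arterial pressure one step of ``dt`` ms.

    The flow is held constant over the step, for which the linear ODE
    has the exact solution
    ``p_wk(t+dt) = qR + (p_wk - qR) * exp(-dt / (R C))``; using it makes
    the update unconditionally stable and exact for piecewise-constant
    flow.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    target = q * params.r_per
    return target + (p_wk - target) * math.exp(
        -dt / (params.r_per * params.c_art)
    )


def make_afterload_variants(
    base: WindkesselParams,
) -> tuple[WindkesselParams, WindkesselParams, WindkesselParams]:
    """Control, +25% and +50% afterload variants.

    Increased afterload is modelled purely through the ejection-onset
    pressure: ``p_a`` = 9 (control), 11.25 and 13.5 kPa; all other
    fields are unchanged.  At ejection onset the Windkessel state is
    initialised so the aortic pressure equals ``p_a``.
    """
    return (
        replace(base, p_a=9.0),
        replace(base, p_a=11.25),
        replace(base, p_a=13.5),
    )


def calibrate_hemodynamics(
    geometry=None,
    cell_params=None,
    hemo: WindkesselParams | None = None,
    ef_band: tuple[float, float] = (70.0, 80.0),
    peak_p_band: tuple[float, float] = (13.5, 16.5),
) -> WindkesselParams:
    """Tune ``r_per`` and ``z_c`` so the baseline beat hits EF ~75% and
    peak pressure ~15 kPa.

    The aortic compliance (0.0144 ml/mmHg) and ejection-onset pressure
    (9 kPa) stay fixed at their printed values.  A coarse bounded grid
    search over (r_per, z_c) is refined around the best cell; the
    passive wall parameters are held at their configured values (they
    are calibrated jointly with the geometry scaling).

    Returns the first parameter set whose baseline run satisfies both
    bands; raises ``RuntimeError`` with the best-found values otherwise.
    """
    from .ventricle import baseline_cycle

    if hemo is None:
        hemo = default_windkessel()

    best = None
    for r_per in (10.0, 15.0, 20.0, 25.0, 30.0):
        for z_c in (0.5, 1.0, 2.0, 3.0, 4.0):
            trial = replace(hemo, r_per=r_per, z_c=z_c)
            res = baseline_cycle(
                geometry=geometry, cell_params=cell_params, hemo=trial
            )
            err = _band_err(res.ef, ef_band) + _band_err(
                res.peak_pressure, peak_p_band
            )
            if err == 0.0:
                return trial
            if best is None or err < best[0]:
                best = (err, trial, res.ef, res.peak_pressure)
    raise RuntimeError(
        "hemodynamic calibration failed: best r_per="
        f"{best[1].r_per}, z_c={best[1].z_c} gave EF={best[2]:.1f}%, "
        f"peak p={best[3]:.1f} kPa (targets EF {ef_band}, p {peak_p_band})"
    )


def _band_err(value: float, band: tuple[float, float]) -> float:
    lo, hi = band
    if value < lo:
        return lo - value
    if value > hi:
        return value - hi
    return 0.0
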