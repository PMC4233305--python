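"""Synthetic intracellular calcium transients.

The organ model is driven by prescribed cytosolic Ca2+ transients rather
than by a calcium-handling ODE system: one transient for the unstimulated
(control) myocyte and one for the beta-adrenergically stimulated myocyte,
both at 6-Hz pacing.  The stimulated transient has a higher peak and
relaxes faster, the phenomenological end point of PKA phosphorylation of
the L-type channel, phospholamban/SERCA and troponin I.

Each transient is a product-of-exponentials pulse

    c(t) = c_dia + c_amp * k * (1 - exp(-t/tau_rise)) * exp(-t/tau_decay)

with the normalisation ``k`` chosen so that the maximum increment above
the diastolic level equals ``c_amp`` exactly.  The peak occurs at
``t* = tau_rise * log(1 + tau_decay/tau_rise)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransientParams",
    "CalciumTransient",
    "CYCLE_MS",
    "make_transient",
    "blend_transients",
    "default_transients",
]

#: Cycle length in ms for 6-Hz field stimulation.
CYCLE_MS = 1000.0 / 6.0


@dataclass(frozen=True)
class TransientParams:
    """Shape parameters of one periodic calcium transient.

    Attributes
    ----------
    c_dia:
        Diastolic (resting) calcium concentration, uM.
    c_amp:
        Peak increment above the diastolic level, uM.
    tau_rise:
        Upstroke time constant, ms.
    tau_decay:
        Decay time constant, ms; must exceed ``tau_rise``.
    t_cycle:
        Pacing cycle length, ms (166.7 ms at 6 Hz).
    """

    c_dia: float
    c_amp: float
    tau_rise: float
    tau_decay: float
    t_cycle: float = CYCLE_MS

    def __post_init__(self) -> None:
        for name in ("c_dia", "c_amp", "tau_rise", "tau_decay", "t_cycle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TransientParams.{name} must be positive")
        if self.tau_rise >= self.tau_decay:
            raise ValueError(
                "TransientParams.tau_rise must be smaller than tau_decay "
                "(upstroke faster than decay)"
            )

    @property
    def t_peak(self) -> float:
        """Time of the transient maximum, ms (closed form)."""
        return self.tau_rise * math.log(1.0 + self.tau_decay / self.tau_rise)

    def value(self, t):
        """Evaluate the closed form at time ``t`` (ms) within one cycle."""
        t = np.asarray(t, dtype=float)
        k = 1.0 / (
            (1.0 - math.exp(-self.t_peak / self.tau_rise))
            * math.exp(-self.t_peak / self.tau_decay)
        )
        pulse = (1.0 - np.exp(-t / self.tau_rise)) * np.exp(-t / self.tau_decay)
        return self.c_dia + self.c_amp * k * pulse


@dataclass(frozen=True)
class CalciumTransient:
    """One cycle of a calcium transient sampled on a uniform time grid."""

    times: np.ndarray  # ms, shape (n,)
    values: np.ndarray  # uM, shape (n,)

    def __post_init__(self) -> None:
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(self.values < 0):
            raise ValueError("calcium concentrations must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def t_cycle(self) -> float:
        return float(self.times[-1] + self.dt)

    def to_csv(self, path) -> None:
        """Write the trace as two-column CSV (time_ms, ca_uM)."""
        import pandas as pd

        pd.DataFrame({"time_ms": self.times, "ca_uM": self.values}).to_csv(
            path, index=False
        )


def make_transient(params: TransientParams, dt: float = 0.05) -> CalciumTransient:
    """Sample the closed-form transient on a uniform grid over one cycle.

    Parameters
    ----------
    params:
        Transient shape parameters.
    dt:
        Sample spacing in ms; must satisfy ``dt <= t_cycle / 100``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > params.t_cycle / 100.0:
        raise ValueError("dt must be at most t_cycle/100 for adequate resolution")
    n = int(round(params.t_cycle / dt))
    times = np.arange(n) * dt
    return CalciumTransient(times=times, values=params.value(times))


def blend_transients(
    control: CalciumTransient, stimulated: CalciumTransient, beta: float
) -> CalciumTransient:
    """Linear interpolation between two transients on identical grids.

    ``beta = 0`` returns the control trace, ``beta = 1`` the stimulated
    one; intermediate values mix pointwise as
    ``(1 - beta) * control + beta * stimulated``.
    """
    if control.times.shape != stimulated.times.shape or not np.array_equal(
        control.times, stimulated.times
    ):
        raise ValueError("transients must share an identical time grid")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if beta == 0.0:
        return control
    if beta == 1.0:
        return stimulated
    return CalciumTransient(
        times=control.times,
        values=(1.0 - beta) * control.values + beta * stimulated.values,
    )


def default_transients() -> tuple[TransientParams, TransientParams]:
    """Calibrated control and isoproterenol-stimulated parameter sets.

    Values come from the package default configuration: the stimulated
    transient has a higher peak and a faster decay than control, and both
    return to within 5% of the diastolic level by the end of the 6-Hz
    cycle.
    """
    from .config import package_defaults

    d = package_defaults()["transients"]
    return (
        TransientParams(**d["control"]),
        TransientParams(**d["stimulated"]),
    )
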