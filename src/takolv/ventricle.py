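"""Reduced-order axisymmetric left ventricle.

The chamber is a stack of thick-walled circular slices from apex
(z ~ 0) to base (z ~ 1) plus a hemispherical apical cap, replacing a
full 3-D finite-element solid model.  Each slice carries its own
contraction state and satisfies a Laplace-type quasi-static force
balance with the cavity pressure:

    [ sigma_p(lam(r)) + T_ref * xb ] * h(r) = p * r

where ``h(r) = r_o(r) - r`` is the wall thickness under conserved wall
cross-sectional area (incompressible wall), ``lam`` the midwall
circumferential stretch, and ``sigma_p`` an exponential passive law.
Slices are coupled only through the shared cavity pressure and the
volume constraint; there is no axial coupling or long-axis shortening.
Regional tension deficits therefore translate directly into
pressure-driven regional dilation — the causal chain behind apical
ballooning — at desk scale.

A beat at 6 Hz is integrated through the four classical phases:
isovolumic contraction (volume pinned at EDV, pressure solved), ejection
(coupled to the three-element Windkessel, valve closes on flow
reversal), isovolumic relaxation, and refilling at the end-diastolic
pressure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .calcium import CalciumTransient, make_transient, default_transients
from .contraction import ContractionParams, CA50_FLOOR, default_contraction_params
from .gradients import MechanismConfig, slice_parameters
from .hemodynamics import WindkesselParams, windkessel_step, default_windkessel

__all__ = [
    "SliceGeometry",
    "VentricleGeometry",
    "VentricleState",
    "CycleResult",
    "EquilibriumError",
    "build_geometry",
    "default_geometry",
    "slice_stretch",
    "passive_stress",
    "slice_equilibrium_radius",
    "cavity_volume",
    "run_cycle",
    "baseline_cycle",
]

logger = logging.getLogger(__name__)

PHASES = ("filling", "isovolumic_contraction", "ejection", "isovolumic_relaxation")

#: Stretch below which shortening-deactivation saturates in the organ
#: coupling (the linear LDA law is not extrapolated below this).
LDA_SHORTENING_CLAMP = 0.9


class EquilibriumError(RuntimeError):
    """No mechanical equilibrium found for a slice."""


@dataclass(frozen=True)
class SliceGeometry:
    """Reference (unloaded) geometry of one slice."""

    z: float  # apex-base coordinate, 0-1
    dz_len: float  # axial extent, mm
    r_i0: float  # reference endocardial radius, mm
    r_o0: float  # reference epicardial radius, mm

    def __post_init__(self) -> None:
        if not 0 < self.r_i0 < self.r_o0:
            raise ValueError("slice radii must satisfy 0 < r_i0 < r_o0")

    @property
    def wall_area(self) -> float:
        """Conserved wall cross-sectional area, mm^2."""
        return math.pi * (self.r_o0**2 - self.r_i0**2)

    @property
    def r_m0(self) -> float:
        return 0.5 * (self.r_i0 + self.r_o0)


@dataclass(frozen=True)
class VentricleGeometry:
    """Slice stack, apical cap and passive material constants."""

    slices: tuple[SliceGeometry, ...]
    passive_a: float  # kPa
    passive_b: float  # dimensionless
    edp: float  # kPa, end-diastolic pressure used for calibration

    def __post_init__(self) -> None:
        zs = [s.z for s in self.slices]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("slice z coordinates must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def z(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    @property
    def r_i0(self) -> np.ndarray:
        return np.array([s.r_i0 for s in self.slices])

    @property
    def r_m0(self) -> np.ndarray:
        return np.array([s.r_m0 for s in self.slices])

    @property
    def wall_area(self) -> np.ndarray:
        return np.array([s.wall_area for s in self.slices])

    @property
    def dz_len(self) -> np.ndarray:
        return np.array([s.dz_len for s in self.slices])


@dataclass
class VentricleState:
    """Instantaneous organ state during a beat."""

    r_i: np.ndarray  # per-slice endocardial radius, mm
    trpn: np.ndarray
    xb: np.ndarray
    p: float  # cavity pressure, kPa
    V: float  # cavity volume, ul
    phase: str
    t: float  # ms within the cycle

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class CycleResult:
    """Time series and derived scalars of one simulated beat."""

    times: np.ndarray  # ms
    pressure: np.ndarray  # kPa
    volume: np.ndarray  # ul
    r_i: np.ndarray  # (n_t, n_slices) mm
    tension: np.ndarray  # (n_t, n_slices) kPa, active
    phase: list[str]
    slice_z: np.ndarray
    edv: float
    esv: float
    ef: float  # percent
    t_es: float  # ms, time of minimum volume
    peak_pressure: float  # kPa
    status: str = "ok"  # ok | aborted
    abort_reason: str | None = None
    config_id: str | None = None

    def summary(self) -> dict:
        return {
            "config_id": self.config_id,
            "edv_ul": self.edv,
            "esv_ul": self.esv,
            "ef_percent": self.ef,
            "t_end_systole_ms": self.t_es,
            "peak_pressure_kPa": self.peak_pressure,
            "status": self.status,
        }

    def to_csv(self, path) -> None:
        """Tidy per-time-step CSV (t_ms, p_kPa, V_ul, r_i per slice)."""
        import pandas as pd

        cols = {"t_ms": self.times, "p_kPa": self.pressure, "V_ul": self.volume}
        for j, z in enumerate(self.slice_z):
            cols[f"r_i_z{z:.3f}_mm"] = self.r_i[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# kinematics and constitutive law


def _outer_radius(r_i, wall_area):
    return np.sqrt(np.square(r_i) + wall_area / math.pi)


def slice_stretch(slice_geo: SliceGeometry, r_i: float) -> float:
    """Midwall circumferential stretch at endocardial radius ``r_i``."""
    if r_i <= 0:
        raise ValueError("r_i must be positive")
    r_o = math.sqrt(r_i**2 + slice_geo.wall_area / math.pi)
    return 0.5 * (r_i + r_o) / slice_geo.r_m0


def passive_stress(lam, geometry: VentricleGeometry):
    """Passive circumferential wall stress, kPa (tension-compression
    symmetric exponential; zero at the reference stretch)."""
    lam = np.asarray(lam, dtype=float)
    a, b = geometry.passive_a, geometry.passive_b
    out = np.where(
        lam >= 1.0,
        a * (np.exp(b * (lam - 1.0)) - 1.0),
        -a * (np.exp(b * (1.0 - lam)) - 1.0),
    )
    return float(out) if out.ndim == 0 else out


def _residual_and_derivative(r, p, sigma_a, geom_arrays, passive_a, passive_b):
    """f(r) = (sigma_p + sigma_a) h(r) - p r, and df/dr, vectorized."""
    r_m0, wall_area = geom_arrays
    r_o = _outer_radius(r, wall_area)
    h = r_o - r
    lam = 0.5 * (r + r_o) / r_m0
    dev = lam - 1.0
    sigma_p = np.sign(dev) * passive_a * (np.exp(passive_b * np.abs(dev)) - 1.0)
    dsigma_dlam = passive_a * passive_b * np.exp(passive_b * np.abs(dev))
    dlam_dr = 0.5 * (1.0 + r / r_o) / r_m0
    dh_dr = r / r_o - 1.0
    f = (sigma_p + sigma_a) * h - p * r
    df = dsigma_dlam * dlam_dr * h + (sigma_p + sigma_a) * dh_dr - p
    return f, df


def _solve_radii(p, sigma_a, r_guess, geometry: VentricleGeometry, tol=1e-11):
    """All slice radii at pressure ``p``: vectorized safeguarded Newton.

    A bracket ``[lo, hi]`` with ``f(lo) < 0 < f(hi)`` is maintained per
    slice (``f -> +inf`` as ``r`` grows, by the exponential passive
    term); Newton steps that leave the bracket fall back to bisection,
    so convergence is guaranteed whenever a root exists.  Seeding from
    the previous time step keeps the physically tracked branch when the
    force balance admits several equilibria.  A slice whose residual is
    non-negative even at the collapse bound (cavity shut by active
    tension) has no equilibrium and raises ``EquilibriumError``.
    """
    r_i0 = geometry.r_i0
    geom_arrays = (geometry.r_m0, geometry.wall_area)
    a, b = geometry.passive_a, geometry.passive_b
    lo = 0.02 * r_i0
    hi = 6.0 * r_i0
    f_lo, _ = _residual_and_derivative(lo, p, sigma_a, geom_arrays, a, b)
    if np.any(f_lo >= 0):
        j = int(np.argmax(f_lo >= 0))
        sa = float(np.asarray(sigma_a)[j]) if np.ndim(sigma_a) else float(sigma_a)
        raise EquilibriumError(
            f"no equilibrium for slice z={geometry.slices[j].z:.3f} at "
            f"p={p:.4g} kPa, sigma_a={sa:.4g} kPa (cavity collapse)"
        )
    f_hi, _ = _residual_and_derivative(hi, p, sigma_a, geom_arrays, a, b)
    while np.any(f_hi <= 0):
        hi = np.where(f_hi <= 0, 2.0 * hi, hi)
        f_hi, _ = _residual_and_derivative(hi, p, sigma_a, geom_arrays, a, b)

    r = np.clip(np.asarray(r_guess, dtype=float).copy(), lo, hi)
    scale = np.maximum(p * r_i0, 1.0)
    for _ in range(80):
        f, df = _residual_and_derivative(r, p, sigma_a, geom_arrays, a, b)
        done = np.abs(f) < tol * scale
        if np.all(done | (hi - lo < 1e-13 * r_i0)):
            return r
        lo = np.where(f < 0, r, lo)
        hi = np.where(f > 0, r, hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            newton = r - f / df
        bad = ~np.isfinite(newton) | (newton <= lo) | (newton >= hi) | (df <= 0)
        r = np.where(done, r, np.where(bad, 0.5 * (lo + hi), newton))
    return r


def slice_equilibrium_radius(
    slice_geo: SliceGeometry,
    xb: float,
    t_ref: float,
    p: float,
    r_prev: float,
    geometry: VentricleGeometry,
) -> float:
    """Equilibrium endocardial radius of one slice at pressure ``p``.

    Root of ``(sigma_p(lam(r)) + t_ref * xb) h(r) - p r``, continued
    from ``r_prev`` (the physically tracked branch); the exponential
    passive term guarantees a finite root (bounded ballooning).
    """
    if p < 0:
        raise ValueError("cavity pressure must be non-negative")
    sub = VentricleGeometry(
        slices=(slice_geo,), passive_a=geometry.passive_a,
        passive_b=geometry.passive_b, edp=geometry.edp,
    )
    return float(
        _solve_radii(p, np.array([t_ref * xb]), np.array([r_prev]), sub)[0]
    )


def cavity_volume(r_i, geometry: VentricleGeometry) -> float:
    """Cavity volume in ul: slice cylinders plus the hemispherical cap
    carried by the apical slice radius."""
    r_i = np.asarray(r_i, dtype=float)
    v = float(np.sum(math.pi * np.square(r_i) * geometry.dz_len))
    return v + (2.0 / 3.0) * math.pi * float(r_i[0]) ** 3


# ---------------------------------------------------------------------------
# geometry construction


def build_geometry(
    n_slices: int = 12,
    base_radius: float = 2.5,
    length: float = 11.0,
    taper: float = 0.8,
    wall_ratio_base: float = 0.85,
    wall_ratio_apex: float = 0.85,
    passive_a: float = 1.0,
    passive_b: float = 5.0,
    edp: float = 0.5,
    target_edv: float = 125.0,
    sigma_a_dia: float = 0.0,
) -> VentricleGeometry:
    """Truncated-ellipsoid slice stack scaled to a target EDV.

    The reference endocardial profile is
    ``r_i0(z) = base_radius * sqrt(1 - (1 - z)^2 * taper)``; the wall
    thickness follows the local radius (``h0 = wall_ratio * r_i0``, the
    ratio linearly interpolated apex to base) so the pressure capacity
    ``sigma * h / r`` of a homogeneously activated wall is uniform along
    the axis and a homogeneous ventricle contracts homogeneously.
    All linear dimensions are
    scaled by a single factor so that the chamber inflated to the
    end-diastolic pressure holds ``target_edv`` ul (the printed range
    is 100-150 ul).  ``sigma_a_dia`` is the residual diastolic active
    tension (kPa) present at 6-Hz pacing, included in the inflation so
    the calibrated EDV matches the start of a beat.
    """
    if n_slices < 6:
        raise ValueError("n_slices must be at least 6")
    if not 100.0 <= target_edv <= 150.0:
        raise ValueError("target_edv must lie in the printed 100-150 ul range")

    def make(scale: float) -> VentricleGeometry:
        z = (np.arange(n_slices) + 0.5) / n_slices
        r_i0 = scale * base_radius * np.sqrt(1.0 - (1.0 - z) ** 2 * taper)
        h0 = r_i0 * (wall_ratio_apex + (wall_ratio_base - wall_ratio_apex) * z)
        dz = scale * length / n_slices
        slices = tuple(
            SliceGeometry(z=zj, dz_len=dz, r_i0=rj, r_o0=rj + hj)
            for zj, rj, hj in zip(z, r_i0, h0)
        )
        return VentricleGeometry(
            slices=slices, passive_a=passive_a, passive_b=passive_b, edp=edp
        )

    def edv_of(scale: float) -> float:
        geo = make(scale)
        r = _solve_radii(edp, sigma_a_dia, geo.r_i0, geo)
        return cavity_volume(r, geo)

    try:
        scale = brentq(lambda s: edv_of(s) - target_edv, 0.4, 2.5, xtol=1e-10)
    except ValueError as exc:
        raise RuntimeError(
            f"geometry calibration failed: EDV target {target_edv} ul not "
            "attainable within the scale bracket [0.4, 2.5]"
        ) from exc
    return make(scale)


def diastolic_active_tension(
    cell_params: ContractionParams | None = None, dt: float = 0.05
) -> float:
    """Residual end-diastolic active tension (kPa) of the paced control
    cell at reference stretch.

    At 6-Hz pacing the cross-bridge pool (decay rate ``k_xb``) has not
    fully relaxed by the end of the cycle; this residual tension loads
    the chamber at end diastole and must be included when the geometry
    is scaled to the target EDV.
    """
    from .contraction import simulate_isometric_twitch

    cell_params = (
        cell_params if cell_params is not None else default_contraction_params()
    )
    ctrl = make_transient(default_transients()[0], dt)
    trace = simulate_isometric_twitch(cell_params, ctrl, dt=dt)
    return float(trace.tension[-1])


def default_geometry(cell_params: ContractionParams | None = None) -> VentricleGeometry:
    """Geometry built from the package default configuration, scaled to
    the target EDV under the residual diastolic tension of the paced
    control cell."""
    from .config import package_defaults

    g = package_defaults()["geometry"]
    return build_geometry(
        n_slices=g["n_slices"], base_radius=g["base_radius"], length=g["length"],
        taper=g["taper"], wall_ratio_base=g["wall_ratio_base"],
        wall_ratio_apex=g["wall_ratio_apex"],
        passive_a=g["passive_a"], passive_b=g["passive_b"],
        edp=package_defaults()["hemodynamics"]["edp"],
        target_edv=g["target_edv"],
        sigma_a_dia=diastolic_active_tension(cell_params),
    )


# ---------------------------------------------------------------------------
# full-cycle simulation


def _solve_ejection(p_guess, p_wk, v_prev, sigma_a, r_guess, geometry, z_c, dt):
    """Couple the chamber to the Windkessel for one ejection step.

    Solves ``g(p) = p - p_wk - z_c * q(p) = 0`` with
    ``q(p) = (v_prev - V(p)) / dt``; ``g`` is increasing in ``p`` (both
    terms are), so a bracketed solve is always available when the damped
    Newton iteration stalls on the stiff wall response.
    """

    def parts(pp):
        rr = _solve_radii(pp, sigma_a, r_guess, geometry)
        vv = cavity_volume(rr, geometry)
        q = (v_prev - vv) / dt
        return pp - p_wk - z_c * q, rr, vv, q

    p = max(p_guess, 1e-6)
    p_lo, p_hi = 0.0, math.inf
    for _ in range(120):
        g, rr, vv, q = parts(p)
        if abs(g) < 1e-9 * max(p, 1.0):
            return p, rr, vv, q
        if g < 0:
            p_lo = p
        else:
            p_hi = p
        dv_dp = _volume_derivative(rr, p, sigma_a, geometry)
        dg = 1.0 + z_c * dv_dp / dt
        p_new = p - g / dg if dg > 1e-12 else math.nan
        if not (p_lo < p_new < p_hi) or not math.isfinite(p_new):
            p_new = 0.5 * (p_lo + p_hi) if math.isfinite(p_hi) else 2.0 * p + 1.0
        if math.isfinite(p_hi) and p_hi - p_lo < 1e-14 * max(p_hi, 1.0):
            return p, rr, vv, q
        p = max(p_new, 1e-9)
    raise EquilibriumError("ejection coupling failed to converge")


def _volume_derivative(r, p, sigma_a, geometry):
    """dV/dp along the equilibrium branch (implicit differentiation)."""
    geom_arrays = (geometry.r_m0, geometry.wall_area)
    _, df = _residual_and_derivative(
        r, p, sigma_a, geom_arrays, geometry.passive_a, geometry.passive_b
    )
    with np.errstate(divide="ignore"):
        dr_dp = np.where(np.abs(df) > 1e-300, r / df, 0.0)
    dv = np.sum(2.0 * math.pi * r * geometry.dz_len * dr_dp)
    dv += 2.0 * math.pi * r[0] ** 2 * dr_dp[0]  # cap
    return float(dv)


def _solve_isovolumic(p_guess, v_target, sigma_a, r_guess, geometry):
    """Find p (and radii) so the cavity volume equals ``v_target``.

    The cavity volume is increasing in pressure along the tracked
    branch, so a scalar bracketed Newton on p is safe: the bracket
    expands until it straddles the target volume and Newton steps that
    leave it bisect instead.
    """
    p = max(p_guess, 1e-6)
    r = r_guess
    p_lo, p_hi = 0.0, math.inf
    for _ in range(120):
        r = _solve_radii(p, sigma_a, r, geometry)
        v = cavity_volume(r, geometry)
        if abs(v - v_target) < 1e-8 * v_target:
            return p, r
        if v < v_target:
            p_lo = p
        else:
            p_hi = p
        dv_dp = _volume_derivative(r, p, sigma_a, geometry)
        if dv_dp > 1e-12:
            p_new = p + (v_target - v) / dv_dp
        else:
            p_new = math.nan
        if not (p_lo < p_new < p_hi) or not math.isfinite(p_new):
            p_new = 0.5 * (p_lo + p_hi) if math.isfinite(p_hi) else 2.0 * p + 1.0
        if p_hi - p_lo < 1e-12 * max(p_hi, 1.0):
            # The target volume falls inside a fold of V(p): the slice
            # stack snaps between equilibrium branches at this pressure
            # (no exact isovolumic state exists).  Take the branch
            # closest to the target and continue; the mismatch is
            # transient and resolves as tension evolves.
            logger.debug(
                "isovolumic fold at V=%.1f ul (p=%.3f kPa, dV=%.2f ul)",
                v_target, p, v - v_target,
            )
            return p, r
        p = max(p_new, 1e-9)
    raise EquilibriumError(
        f"isovolumic pressure solve failed at V={v_target:.1f} ul "
        f"(p bracket [{p_lo:.4g}, {p_hi:.4g}] kPa)"
    )


def _pace_cells(ca_mid, ca50, params: ContractionParams, dt, n_cycles):
    """Pace per-slice gating states from rest to periodic steady state."""
    n_steps = ca_mid.shape[1]
    trpn = np.zeros(ca_mid.shape[0])
    xb = np.zeros(ca_mid.shape[0])
    e_xb = math.exp(-params.k_xb * dt)
    for _ in range(n_cycles):
        for i in range(n_steps):
            phi = (ca_mid[:, i] / ca50) ** params.n_trpn
            b = params.k_trpn * (1.0 + phi)
            trpn_inf = phi / (1.0 + phi)
            trpn_new = trpn_inf + (trpn - trpn_inf) * np.exp(-b * dt)
            src = 0.5 * (trpn**params.n_xb + trpn_new**params.n_xb)
            xb = src + (xb - src) * e_xb
            trpn = trpn_new
    return trpn, xb


def run_cycle(
    config: MechanismConfig | None,
    geometry: VentricleGeometry | None = None,
    cell_params: ContractionParams | None = None,
    hemo: WindkesselParams | None = None,
    transients: tuple[CalciumTransient, CalciumTransient] | None = None,
    dt: float = 0.05,
    n_pacing_cycles: int = 12,
) -> CycleResult:
    """Simulate one 6-Hz beat of the coupled ventricle.

    ``config=None`` runs the homogeneous control baseline (control
    transient, reference sensitivity and tension everywhere).  Per-slice
    cell states are first paced to periodic steady state at the
    end-diastolic stretch; the analysed beat then starts at end diastole
    (p = EDP, V = EDV) and proceeds through isovolumic contraction
    (until the cavity pressure reaches the ejection-onset pressure
    ``p_a``), Windkessel-coupled ejection (until flow reversal),
    isovolumic relaxation (until p falls back to EDP) and refilling.

    Equilibrium failures abort the run and are reported through
    ``status="aborted"`` rather than raising, so parameter sweeps can
    continue past mechanically degenerate corners.
    """
    geometry = geometry if geometry is not None else default_geometry()
    cell_params = (
        cell_params if cell_params is not None else default_contraction_params()
    )
    hemo = hemo if hemo is not None else default_windkessel()
    if transients is None:
        ctrl_p, stim_p = default_transients()
        transients = (make_transient(ctrl_p, dt), make_transient(stim_p, dt))
    control, stimulated = transients

    n_s = geometry.n_slices
    t_cycle = control.t_cycle
    n_steps = int(round(t_cycle / dt))
    t_mid = (np.arange(n_steps) + 0.5) * dt

    # per-slice cell inputs
    if config is None:
        ca_mid = np.tile(
            np.interp(t_mid, control.times, control.values), (n_s, 1)
        )
        ca50_ref = np.full(n_s, cell_params.ca_t50_ref)
        t_ref = np.full(n_s, cell_params.t_ref)
        beta1 = cell_params.beta1
        config_id = "baseline-control"
        p_a = hemo.p_a
    else:
        rows = []
        ca50_ref = np.empty(n_s)
        t_ref = np.empty(n_s)
        for j, z in enumerate(geometry.z):
            inputs = slice_parameters(config, float(z), control, stimulated)
            rows.append(np.interp(t_mid, inputs.transient.times, inputs.transient.values))
            ca50_ref[j] = inputs.ca_t50
            t_ref[j] = inputs.t_ref
        ca_mid = np.vstack(rows)
        beta1 = config.beta1
        config_id = config.config_id
        p_a = config.p_a

    edp = hemo.edp

    def ca50_of(lam_cell):
        # The linear LDA law is trusted over a sarcomere-like strain
        # range only: the slice surrogate's circumferential shortening
        # (lam down to ~0.6 at end systole) far exceeds the range over
        # which Ca_T50(lam) is linear, and extrapolating there swamps
        # the stretch-side Frank-Starling compensation the mechanism
        # studies probe.  Shortening-deactivation saturates at
        # LDA_SHORTENING_CLAMP; the stretch side keeps the CA50_FLOOR.
        lam_eff = np.maximum(lam_cell, LDA_SHORTENING_CLAMP)
        return ca50_ref * np.maximum(CA50_FLOOR, 1.0 + beta1 * (lam_eff - 1.0))

    def lam_of(r):
        r_o = _outer_radius(r, geometry.wall_area)
        return 0.5 * (r + r_o) / geometry.r_m0

    try:
        # End-diastolic configuration; length-dependent activation is
        # referenced to it (the analogue of an image-derived reference
        # state): a cell's reference length is its end-diastolic length,
        # so lam_cell = lam / lam_ed equals 1 at end diastole.
        r_ed = _solve_radii(edp, 0.0, geometry.r_i0, geometry)
        lam_ed = lam_of(r_ed)
        trpn, xb = _pace_cells(
            ca_mid, ca50_of(np.ones(n_s)), cell_params, dt, n_pacing_cycles
        )
        # start of beat: p = EDP with the residual diastolic cross-bridge
        # tension included; this equilibrium defines the beat's EDV and
        # the end-diastolic stretch reference for LDA
        p = edp
        r = _solve_radii(p, t_ref * xb, r_ed, geometry)
        edv = cavity_volume(r, geometry)
        lam_ed = lam_of(r)
    except EquilibriumError as exc:
        return _aborted_result(geometry, config_id, str(exc))

    times = np.arange(n_steps + 1) * dt
    pressure = np.empty(n_steps + 1)
    volume = np.empty(n_steps + 1)
    radii = np.empty((n_steps + 1, n_s))
    tension = np.empty((n_steps + 1, n_s))
    phases: list[str] = []

    phase = "isovolumic_contraction"
    p_wk = None
    v = edv
    pressure[0], volume[0], radii[0] = p, v, r
    tension[0] = t_ref * xb
    phases.append(phase)

    e_xb = math.exp(-cell_params.k_xb * dt)
    try:
        for i in range(n_steps):
            # cell update at current stretch (relative to end diastole)
            lam = lam_of(r) / lam_ed
            phi = (ca_mid[:, i] / ca50_of(lam)) ** cell_params.n_trpn
            b = cell_params.k_trpn * (1.0 + phi)
            trpn_inf = phi / (1.0 + phi)
            trpn_new = trpn_inf + (trpn - trpn_inf) * np.exp(-b * dt)
            src = 0.5 * (trpn**cell_params.n_xb + trpn_new**cell_params.n_xb)
            xb = src + (xb - src) * e_xb
            trpn = trpn_new
            sigma_a = t_ref * xb

            if phase == "isovolumic_contraction":
                p, r = _solve_isovolumic(p, edv, sigma_a, r, geometry)
                v = edv
                if p >= p_a:
                    phase = "ejection"
                    p_wk = p_a  # aortic pressure equals p_a at zero flow
            elif phase == "ejection":
                v_prev = v
                p_new, rr, vv, q = _solve_ejection(
                    p, p_wk, v_prev, sigma_a, r, geometry, hemo.z_c, dt
                )
                if q < 0.0:
                    # valve closes; hold volume for this step instead
                    phase = "isovolumic_relaxation"
                    p, r = _solve_isovolumic(p, v_prev, sigma_a, r, geometry)
                    v = v_prev
                else:
                    p, r, v = p_new, rr, vv
                    p_wk = windkessel_step(p_wk, q, hemo, dt)
            elif phase == "isovolumic_relaxation":
                p, r = _solve_isovolumic(p, v, sigma_a, r, geometry)
                p_wk = windkessel_step(p_wk, 0.0, hemo, dt)
                if p > p_wk:
                    # chamber pressure exceeds aortic again: valve reopens
                    phase = "ejection"
                elif p <= edp:
                    phase = "filling"
            else:  # filling
                p = edp
                r = _solve_radii(p, sigma_a, r, geometry)
                v = cavity_volume(r, geometry)

            pressure[i + 1], volume[i + 1], radii[i + 1] = p, v, r
            tension[i + 1] = sigma_a
            phases.append(phase)
    except EquilibriumError as exc:
        return _aborted_result(
            geometry, config_id, f"{exc} (phase {phase}, t={times[i+1]:.2f} ms)"
        )

    i_es = int(np.argmin(volume))
    esv = float(volume[i_es])
    ef = 100.0 * (edv - esv) / edv
    return CycleResult(
        times=times,
        pressure=pressure,
        volume=volume,
        r_i=radii,
        tension=tension,
        phase=phases,
        slice_z=geometry.z,
        edv=float(edv),
        esv=esv,
        ef=float(ef),
        t_es=float(times[i_es]),
        peak_pressure=float(np.max(pressure)),
        status="ok",
        config_id=config_id,
    )


def _aborted_result(geometry, config_id, reason) -> CycleResult:
    logger.warning("run %s aborted: %s", config_id, reason)
    nan = np.array([math.nan])
    return CycleResult(
        times=nan, pressure=nan, volume=nan,
        r_i=np.full((1, geometry.n_slices), math.nan),
        tension=np.full((1, geometry.n_slices), math.nan),
        phase=["filling"], slice_z=geometry.z,
        edv=math.nan, esv=math.nan, ef=math.nan, t_es=math.nan,
        peak_pressure=math.nan, status="aborted", abort_reason=reason,
        config_id=config_id,
    )


def baseline_cycle(geometry=None, cell_params=None, hemo=None, **kwargs) -> CycleResult:
    """Homogeneous-control beat used for calibration and as reference."""
    return run_cycle(None, geometry=geometry, cell_params=cell_params, hemo=hemo, **kwargs)
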