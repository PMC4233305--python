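"""Reduced-order ventricle: kinematics, equilibrium, geometry, full beat."""

import math

import numpy as np
import pytest

from takolv.ventricle import (
    EquilibriumError,
    SliceGeometry,
    VentricleGeometry,
    build_geometry,
    cavity_volume,
    passive_stress,
    slice_equilibrium_radius,
    slice_stretch,
)


@pytest.fixture(scope="module")
def one_slice():
    return SliceGeometry(z=0.5, dz_len=1.0, r_i0=3.0, r_o0=5.0)


@pytest.fixture(scope="module")
def slab(one_slice):
    return VentricleGeometry(
        slices=(one_slice,), passive_a=2.0, passive_b=8.0, edp=0.5
    )


class TestKinematics:
    def test_reference_radius_gives_unit_stretch(self, one_slice):
        assert slice_stretch(one_slice, one_slice.r_i0) == pytest.approx(1.0)

    def test_stretch_matches_closed_form(self, one_slice):
        r_i = 1.2 * one_slice.r_i0
        r_o = math.sqrt(r_i**2 + one_slice.wall_area / math.pi)
        expected = 0.5 * (r_i + r_o) / (0.5 * (3.0 + 5.0))
        assert slice_stretch(one_slice, r_i) == pytest.approx(expected, rel=1e-12)

    def test_wall_thins_as_cavity_dilates(self, one_slice):
        radii = np.linspace(1.0, 6.0, 50)
        thickness = [
            math.sqrt(r**2 + one_slice.wall_area / math.pi) - r for r in radii
        ]
        assert np.all(np.diff(thickness) < 0)

    def test_wall_area_definition(self, one_slice):
        assert one_slice.wall_area == pytest.approx(
            math.pi * (5.0**2 - 3.0**2), rel=1e-12
        )


class TestPassiveStress:
    def test_stress_free_reference(self, slab):
        assert passive_stress(1.0, slab) == 0.0

    def test_closed_form_at_ten_percent_stretch(self, slab):
        assert passive_stress(1.1, slab) == pytest.approx(
            2.0 * (math.exp(0.8) - 1.0), rel=1e-12
        )

    def test_increasing_and_convex_in_tension(self, slab):
        lam = np.linspace(1.0, 1.4, 100)
        sigma = passive_stress(lam, slab)
        assert np.all(np.diff(sigma) > 0)
        assert np.all(np.diff(sigma, 2) > 0)

    def test_compressive_below_reference(self, slab):
        assert passive_stress(0.9, slab) < 0


class TestSliceEquilibrium:
    def test_unloaded_passive_reference(self, one_slice, slab):
        r = slice_equilibrium_radius(one_slice, xb=0.0, t_ref=120.0, p=0.0,
                                     r_prev=one_slice.r_i0, geometry=slab)
        assert r == pytest.approx(one_slice.r_i0, rel=1e-9)

    def test_root_matches_brute_force_scan(self, one_slice, slab):
        """Equilibrium radius against a 1e5-point residual grid scan."""
        xb, t_ref, p = 0.1, 120.0, 2.0
        r_root = slice_equilibrium_radius(one_slice, xb=xb, t_ref=t_ref, p=p,
                                          r_prev=one_slice.r_i0, geometry=slab)
        grid = np.linspace(0.2 * one_slice.r_i0, 3.0 * one_slice.r_i0, 100_000)
        r_o = np.sqrt(grid**2 + one_slice.wall_area / math.pi)
        lam = 0.5 * (grid + r_o) / one_slice.r_m0
        sigma = passive_stress(lam, slab) + t_ref * xb
        residual = sigma * (r_o - grid) - p * grid
        crossings = grid[np.nonzero(np.diff(np.sign(residual)))[0]]
        assert np.min(np.abs(crossings - r_root)) < (grid[1] - grid[0])

    def test_continued_root_monotone_in_pressure(self, one_slice, slab):
        r_prev = one_slice.r_i0
        roots = []
        for p in np.linspace(0.0, 5.0, 21):
            r_prev = slice_equilibrium_radius(one_slice, xb=0.05, t_ref=120.0,
                                              p=p, r_prev=r_prev, geometry=slab)
            roots.append(r_prev)
        assert np.all(np.diff(roots) >= -1e-12)

    def test_collapse_raises_equilibrium_error(self, one_slice, slab):
        # full activation at zero pressure: tension shuts the cavity
        with pytest.raises(EquilibriumError):
            slice_equilibrium_radius(one_slice, xb=1.0, t_ref=120.0, p=0.0,
                                     r_prev=one_slice.r_i0, geometry=slab)


class TestCavityVolume:
    def test_single_slice_cylinder(self):
        s = SliceGeometry(z=0.5, dz_len=10.0, r_i0=3.0, r_o0=5.0)
        geo = VentricleGeometry(slices=(s,), passive_a=1.0, passive_b=8.0, edp=0.5)
        v = cavity_volume(np.array([3.0]), geo)
        # cylinder 90*pi plus the hemispherical cap 2/3*pi*27
        assert v == pytest.approx(90 * math.pi + 18 * math.pi, rel=1e-12)

    def test_scaling_of_slice_and_cap_parts(self, geometry):
        r = geometry.r_i0
        v1 = cavity_volume(r, geometry)
        v2 = cavity_volume(2 * r, geometry)
        slice_part = float(np.sum(math.pi * r**2 * geometry.dz_len))
        cap_part = (2.0 / 3.0) * math.pi * r[0] ** 3
        assert v2 == pytest.approx(4 * slice_part + 8 * cap_part, rel=1e-12)


class TestGeometryCalibration:
    def test_basal_slice_matches_profile_endpoint(self):
        geo = build_geometry(n_slices=12)
        # top slice sits at z = 23/24, just inside the valve plane
        z_top = geo.slices[-1].z
        ratio = geo.slices[-1].r_i0 / math.sqrt(1 - (1 - z_top) ** 2 * 0.8)
        profile = [
            s.r_i0 / math.sqrt(1 - (1 - s.z) ** 2 * 0.8) for s in geo.slices
        ]
        np.testing.assert_allclose(profile, ratio, rtol=1e-9)

    def test_calibrated_volume_hits_target(self):
        geo = build_geometry(target_edv=125.0)
        from takolv.ventricle import _solve_radii

        r = _solve_radii(geo.edp, 0.0, geo.r_i0, geo)
        assert cavity_volume(r, geo) == pytest.approx(125.0, rel=1e-6)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="n_slices"):
            build_geometry(n_slices=4)

    def test_target_outside_printed_range_rejected(self):
        with pytest.raises(ValueError, match="target_edv"):
            build_geometry(target_edv=200.0)


class TestFullCycle:
    def test_baseline_hits_calibration_targets(self, baseline_result):
        assert 100.0 <= baseline_result.edv <= 150.0
        assert 70.0 <= baseline_result.ef <= 80.0
        assert 13.5 <= baseline_result.peak_pressure <= 16.5

    def test_isovolumic_phases_conserve_volume(self, baseline_result):
        res = baseline_result
        phases = np.array(res.phase)
        for name in ("isovolumic_contraction", "isovolumic_relaxation"):
            idx = np.nonzero(phases == name)[0]
            if len(idx) < 2:
                continue
            segment = res.volume[idx]
            assert np.max(np.abs(np.diff(segment))) / res.edv < 1e-6

    def test_ejection_flow_never_negative(self, baseline_result):
        res = baseline_result
        phases = np.array(res.phase)
        in_ej = np.nonzero(phases == "ejection")[0]
        dv = np.diff(res.volume)
        # every step taken while ejecting removes volume
        assert np.all(dv[in_ej[1:] - 1] <= 1e-9)

    def test_wall_area_conserved_along_the_beat(self, baseline_result, geometry):
        r_i = baseline_result.r_i
        r_o = np.sqrt(r_i**2 + geometry.wall_area / math.pi)
        area = math.pi * (r_o**2 - r_i**2)
        np.testing.assert_allclose(
            area, np.broadcast_to(geometry.wall_area, area.shape), rtol=1e-9
        )

    def test_passive_ventricle_cannot_eject(self, geometry, hemo, cell_params):
        from dataclasses import replace

        from takolv.ventricle import baseline_cycle

        weak = replace(cell_params, t_ref=1e-6)
        res = baseline_cycle(geometry=geometry, cell_params=weak, hemo=hemo)
        assert res.status == "ok"
        assert res.ef < 5.0

    def test_halving_dt_changes_ef_little(self, geometry, hemo, baseline_result):
        from takolv.ventricle import baseline_cycle

        fine = baseline_cycle(geometry=geometry, hemo=hemo, dt=0.025)
        assert abs(fine.ef - baseline_result.ef) < 0.5

    def test_sharp_tension_gradient_dilates_apex_relative_to_base(
        self, tension_mechanism_results, baseline_result, geometry
    ):
        """75% apical cross-bridge inhibition with a sharp mid-ventricular
        transition leaves the apex relatively dilated at end systole while
        the hypercontractile base shortens well below it."""
        res = tension_mechanism_results[30.0]
        i_es = int(np.argmin(res.volume))
        lam_es = np.array(
            [slice_stretch(s, res.r_i[i_es, j]) for j, s in enumerate(geometry.slices)]
        )
        lam_ed = np.array(
            [slice_stretch(s, res.r_i[0, j]) for j, s in enumerate(geometry.slices)]
        )
        rel = lam_es / lam_ed
        apex, base = rel[:6], rel[6:]
        assert np.min(apex) > np.max(base)  # apex systolic shortening deficit
        assert np.min(base) < 1.0  # base genuinely shortens
        # and the shape change shows up as apical ballooning vs baseline
        from takolv.metrics import ab_timecourse

        assert (
            ab_timecourse(res).ab_end_systole
            > ab_timecourse(baseline_result).ab_end_systole + 0.5
        )
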