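"""Droplet geometry, force resolution and material-property operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gumfoot import mechanics as M
from gumfoot.mechanics import (
    DegenerateCurveError,
    ExtensionSeries,
    StressStrainCurve,
    SupportLine,
)


class TestDropletGeometry:
    @pytest.mark.parametrize(
        "DL, DW, expected",
        [
            (1.0, 1.0, 2 * math.pi / 15),
            (3.0, 2.0, 8 * math.pi / 5),
        ],
    )
    def test_droplet_volume(self, DL, DW, expected):
        assert M.droplet_volume(DL, DW) == pytest.approx(expected, rel=1e-12)

    @given(
        DL=st.floats(0.1, 1e3),
        DW=st.floats(0.1, 1e3),
        k=st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_volume_homogeneity(self, DL, DW, k):
        """Scaling both linear dimensions by k scales the volume by k^3."""
        v1 = M.droplet_volume(DL, DW)
        v2 = M.droplet_volume(k * DL, k * DW)
        assert v2 == pytest.approx(k**3 * v1, rel=1e-9)

    def test_volume_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            M.droplet_volume(0.0, 1.0)

    @pytest.mark.parametrize(
        "DV, area, expected", [(10.0, 5.0, 2.0), (0.0, 3.0, 0.0),
                               (8 * math.pi / 5, 4.0, 2 * math.pi / 5)]
    )
    def test_thickness(self, DV, area, expected):
        assert M.droplet_thickness(DV, area) == pytest.approx(expected)

    def test_thickness_zero_area(self):
        with pytest.raises(ValueError):
            M.droplet_thickness(1.0, 0.0)

    def test_core_volume_product_and_consistency(self):
        assert M.core_volume(3.0, 2.0) == 6.0
        # core area equal to droplet area recovers the full droplet volume
        geom = M.droplet_geometry(3.0, 2.0, 4.0, 4.0)
        assert geom.core_volume == pytest.approx(geom.DV, rel=1e-12)

    def test_core_exceeding_droplet_area_rejected(self):
        with pytest.raises(ValueError):
            M.droplet_geometry(3.0, 2.0, 4.0, 5.0)

    @pytest.mark.parametrize(
        "vc, convention, expected",
        [
            (4 * math.pi / 3, "radius", 1.0),
            (4 * math.pi / 3, "diameter", 2.0),
            (36 * math.pi, "radius", 3.0),
        ],
    )
    def test_initial_filament_length(self, vc, convention, expected):
        assert M.initial_filament_length(vc, convention) == pytest.approx(expected)

    @given(vc=st.floats(1e-3, 1e9))
    @settings(max_examples=30, deadline=None)
    def test_diameter_is_twice_radius(self, vc):
        assert M.initial_filament_length(vc, "diameter") == pytest.approx(
            2 * M.initial_filament_length(vc, "radius")
        )


class TestForceResolution:
    @pytest.mark.parametrize(
        "theta, expected",
        [(0.0, 0.0), (60.0, 1.0)],
    )
    def test_support_line_strain(self, theta, expected):
        assert M.support_line_strain(theta) == pytest.approx(expected, abs=1e-12)

    def test_strain_inversion_roundtrip(self):
        """A 17 um elongation of a 2400 um half-span inverts and round-trips."""
        eps = 17.0 / 2400.0
        theta = M.deflection_from_strain(eps)
        assert 6.5 < theta < 7.0
        assert M.support_line_strain(theta) == pytest.approx(eps, rel=1e-12)

    def test_strain_domain_error(self):
        with pytest.raises(ValueError):
            M.support_line_strain(90.0)

    def test_force_zero_at_zero_deflection(self):
        line = SupportLine(fiber_count=2, fiber_diameter=3.0, fiber_modulus=1e4)
        assert M.droplet_force(0.0, line) == 0.0

    def test_force_worked_example(self):
        # 2 fibers of 3 um at 10 GPa deflected 10 degrees
        line = SupportLine(fiber_count=2, fiber_diameter=3.0, fiber_modulus=1e4)
        expected = (
            2 * 2 * (math.pi * 9 / 4) * 1e4
            * (1 / math.cos(math.radians(10)) - 1) * math.sin(math.radians(10))
        )
        assert M.droplet_force(10.0, line) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(757.5, abs=0.5)

    def test_force_linear_in_fiber_count(self):
        l1 = SupportLine(fiber_count=1, fiber_diameter=3.0, fiber_modulus=1e4)
        l2 = SupportLine(fiber_count=2, fiber_diameter=3.0, fiber_modulus=1e4)
        assert M.droplet_force(25.0, l2) == pytest.approx(
            2 * M.droplet_force(25.0, l1)
        )

    @pytest.mark.parametrize(
        "F, vc, L, expected", [(10.0, 50.0, 10.0, 2.0), (15.0, 100.0, 20.0, 3.0)]
    )
    def test_true_stress(self, F, vc, L, expected):
        assert M.true_stress(F, M.filament_csa(vc, L)) == pytest.approx(expected)

    def test_stress_doubles_when_length_doubles(self):
        csa1 = M.filament_csa(100.0, 10.0)
        csa2 = M.filament_csa(100.0, 20.0)
        assert M.true_stress(7.0, csa2) == pytest.approx(
            2 * M.true_stress(7.0, csa1)
        )

    @pytest.mark.parametrize(
        "L, L0, expected",
        [(10.0, 10.0, 0.0), (10.0 * math.e, 10.0, 1.0), (50.0, 10.0, math.log(5))],
    )
    def test_true_strain(self, L, L0, expected):
        assert M.true_strain(L, L0) == pytest.approx(expected)

    def test_percent_elongation_worked_examples(self):
        assert round(M.percent_elongation(17.0), 1) == 0.7
        assert round(M.percent_elongation(94.0), 1) == 3.9


def _linear_curve(E=2.0, s0=0.5, eps_max=1.0, n=6):
    frac = np.linspace(0, 1, n)
    eps = eps_max * frac
    sig = s0 + E * eps
    return StressStrainCurve(
        fractions=tuple(frac), strain=tuple(eps), stress=tuple(sig),
        initial_stress=s0,
    )


class TestCurveAndProperties:
    def test_modulus_two_point_window(self):
        curve = StressStrainCurve(
            fractions=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
            strain=(0.0, 0.1, 0.3, 0.5, 0.7, 0.9),
            stress=(0.0, 0.2, 0.6, 1.0, 1.4, 1.8),
            initial_stress=0.0,
        )
        # window (0.6, 0.8): sigma (1.0 -> 1.4) over eps (0.5 -> 0.7)
        assert M.elastic_modulus(curve, (0.6, 0.8)) == pytest.approx(2.0)

    def test_modulus_of_linear_curve_any_window(self):
        curve = _linear_curve(E=3.5)
        for window in [(0.6, 0.8), (0.8, 1.0), (0.0, 1.0)]:
            assert M.elastic_modulus(curve, window) == pytest.approx(3.5)

    def test_flat_stress_zero_modulus(self):
        curve = _linear_curve(E=0.0, s0=1.0)
        assert M.elastic_modulus(curve, (0.6, 0.8)) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_window_raises(self):
        curve = StressStrainCurve(
            fractions=(0.0, 0.6, 0.8), strain=(0.0, 0.5, 0.5),
            stress=(0.0, 1.0, 1.2), initial_stress=0.0,
        )
        with pytest.raises(DegenerateCurveError):
            M.elastic_modulus(curve, (0.6, 0.8))

    def test_toughness_constant_stress_is_zero(self):
        """Pre-stress rectangle exactly cancels a flat curve's area."""
        curve = _linear_curve(E=0.0, s0=0.8)
        assert M.toughness(curve) == pytest.approx(0.0, abs=1e-12)

    def test_toughness_triangle(self):
        # sigma rising 0 -> 2 over eps 0 -> 1: area 1.0, no pre-stress
        curve = _linear_curve(E=2.0, s0=0.0, n=100)
        assert M.toughness(curve) == pytest.approx(1.0, rel=1e-12)

    def test_toughness_zero_stress(self):
        curve = _linear_curve(E=0.0, s0=0.0)
        assert M.toughness(curve) == 0.0

    def test_toughness_matches_dense_integral_piecewise(self):
        """Rectangle-sum toughness equals the analytic integral for a dense
        piecewise-linear stress profile."""
        rng = np.random.default_rng(5)
        eps = np.sort(np.concatenate([[0.0], rng.uniform(0, 2, 400)]))
        sig = 0.3 + np.abs(np.sin(3 * eps)) + 0.2 * eps
        curve = StressStrainCurve(
            fractions=tuple(np.linspace(0, 1, eps.size)),
            strain=tuple(eps), stress=tuple(sig), initial_stress=float(sig[0]),
        )
        expected = np.trapezoid(sig, eps) - sig[0] * (eps[-1] - eps[0])
        assert M.toughness(curve) == pytest.approx(float(expected), rel=1e-9)


class TestPipeline:
    def test_noise_free_curve_lies_on_generating_line(self, noisefree_experiment):
        cfg, line, geom, series, truth = noisefree_experiment
        curve = M.build_stress_strain_curve(series, geom, line)
        eps = np.asarray(curve.strain)
        sig = np.asarray(curve.stress)
        assert np.allclose(sig, cfg.initial_stress + cfg.true_modulus * eps,
                           rtol=1e-9)

    def test_diameter_convention_shifts_strain_by_ln2(self, noisefree_experiment):
        _, line, geom, series, _ = noisefree_experiment
        cr = M.build_stress_strain_curve(series, geom, line, "radius")
        cd = M.build_stress_strain_curve(series, geom, line, "diameter")
        # ln(L/2r) = ln(L/r) - ln 2 for every measured point
        for er, ed in zip(cr.strain[1:], cd.strain[1:]):
            assert ed == pytest.approx(er - math.log(2), rel=1e-9)

    def test_modulus_invariant_under_convention_for_linear_curve(
        self, noisefree_experiment
    ):
        cfg, line, geom, series, _ = noisefree_experiment
        # strains shift by -ln2 but stresses at measured points are
        # unchanged, so the two-point slope within a window is identical
        er = M.elastic_modulus(
            M.build_stress_strain_curve(series, geom, line, "radius"), (0.6, 0.8)
        )
        ed = M.elastic_modulus(
            M.build_stress_strain_curve(series, geom, line, "diameter"), (0.6, 0.8)
        )
        assert ed == pytest.approx(er, rel=1e-9)

    def test_constant_angle_growing_length_raises_stress(self):
        line = SupportLine(fiber_count=2, fiber_diameter=2.5, fiber_modulus=800.0)
        geom = M.droplet_geometry(100.0, 60.0, 8000.0, 6000.0)
        series = ExtensionSeries(
            fractions=(0.0, 0.5, 1.0),
            lengths=(30.0, 60.0, 120.0),
            angles=(20.0, 20.0, 20.0),
        )
        curve = M.build_stress_strain_curve(series, geom, line)
        assert curve.stress[2] > curve.stress[1]

    def test_missing_initial_angle_warns_and_zeroes_sigma0(self):
        line = SupportLine(fiber_count=2, fiber_diameter=2.5, fiber_modulus=800.0)
        geom = M.droplet_geometry(100.0, 60.0, 8000.0, 6000.0)
        series = ExtensionSeries(
            fractions=(0.0, 1.0), lengths=(30.0, 90.0),
            angles=(float("nan"), 20.0),
        )
        with pytest.warns(UserWarning, match="initial stress"):
            curve = M.build_stress_strain_curve(series, geom, line)
        assert curve.initial_stress == 0.0

    def test_sensitivity_scales_modulus_and_toughness(self, noisefree_experiment):
        cfg, line, geom, series, truth = noisefree_experiment
        base = M.material_properties(series, geom, line, window=(0.6, 0.8))
        up, down = M.modulus_sensitivity(series, geom, line, delta=0.1,
                                         window=(0.6, 0.8))
        assert up.elastic_modulus == pytest.approx(
            1.1 * base.elastic_modulus, rel=1e-9
        )
        assert down.elastic_modulus == pytest.approx(
            0.9 * base.elastic_modulus, rel=1e-9
        )
        assert up.toughness == pytest.approx(1.1 * base.toughness, rel=1e-9)
        assert down.toughness == pytest.approx(0.9 * base.toughness, rel=1e-9)

    def test_sensitivity_delta_zero_identity(self, noisefree_experiment):
        _, line, geom, series, _ = noisefree_experiment
        up, down = M.modulus_sensitivity(series, geom, line, delta=0.0)
        assert up == down

    def test_sensitivity_delta_minus_one_degenerate(self, noisefree_experiment):
        _, line, geom, series, _ = noisefree_experiment
        with pytest.raises(ValueError):
            M.modulus_sensitivity(series, geom, line, delta=-1.0)

    def test_extension_and_area_per_volume(self):
        geom = M.droplet_geometry(100.0, 60.0, 8000.0, 6000.0)
        L0 = M.initial_filament_length(geom.core_volume)
        series = ExtensionSeries(
            fractions=(0.0, 0.8, 1.0),
            lengths=(L0, L0 + 0.2 * geom.core_volume, L0 + 30.0),
            angles=(0.0, 10.0, 12.0),
        )
        assert M.extension_per_volume(series, geom, 0.8) == pytest.approx(0.2)
        assert M.area_per_volume(geom) == pytest.approx(
            6000.0 / geom.core_volume
        )
        with pytest.raises(ValueError):
            M.extension_per_volume(series, geom, 0.7)

    def test_extension_per_volume_halves_when_volume_doubles(self):
        g1 = M.droplet_geometry(100.0, 60.0, 8000.0, 6000.0)
        g2 = M.droplet_geometry(200.0, 60.0, 16000.0, 12000.0)
        assert g2.core_volume == pytest.approx(2 * g1.core_volume)
        L = 500.0
        s1 = ExtensionSeries((0.0, 0.8), (10.0, L), (0.0, 10.0))
        # same absolute extension from each core's own starting length
        L01, L02 = (M.initial_filament_length(g.core_volume) for g in (g1, g2))
        s1 = ExtensionSeries((0.0, 0.8), (L01, L01 + 40.0), (0.0, 10.0))
        s2 = ExtensionSeries((0.0, 0.8), (L02, L02 + 40.0), (0.0, 10.0))
        assert M.extension_per_volume(s2, g2, 0.8) == pytest.approx(
            0.5 * M.extension_per_volume(s1, g1, 0.8)
        )


class TestCompareGroups:
    def test_identical_normal_samples_take_t_branch(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        res = M.compare_groups(a, a.copy())
        assert res.branch == "t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_heavy_tailed_samples_take_nonparametric_branch(self):
        rng = np.random.default_rng(1)
        a = rng.standard_cauchy(200)
        b = rng.standard_cauchy(200)
        res = M.compare_groups(a, b)
        assert res.branch == "wilcoxon"

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            M.compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
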