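import numpy as np
import pytest

from eprshape.errors import QuadratureError
from eprshape.lineshape_models import (
    LineshapeSpec,
    evaluate_lineshape,
    gaussian_derivative,
    lorentzian_derivative,
    normalize_lineshape,
    relaxation_cutoff_time,
    relaxation_function,
    simulate_stretched_lorentzian,
    stretched_derivative_raw,
    stretched_peak_position,
)
from eprshape.preprocessing import extract_classical_params


class TestAnalyticForms:
    def test_gaussian_values(self):
        spec = LineshapeSpec(family="gaussian", App=1.0, DeltaBpp=1.0, Bres=0.0)
        assert gaussian_derivative(0.0, spec) == 0.0
        assert gaussian_derivative(-0.5, spec) == pytest.approx(0.5, rel=1e-12)
        assert gaussian_derivative(0.5, spec) == pytest.approx(-0.5, rel=1e-12)
        # u = 1 evaluates to -exp(-3/2)
        assert gaussian_derivative(1.0, spec) == pytest.approx(
            -np.exp(-1.5), rel=1e-12
        )

    def test_lorentzian_extrema(self):
        spec = LineshapeSpec(family="lorentzian", App=2.0, DeltaBpp=4.0, Bres=10.0)
        assert lorentzian_derivative(10.0 - 2.0, spec) == pytest.approx(1.0)
        assert lorentzian_derivative(10.0 + 2.0, spec) == pytest.approx(-1.0)

    def test_lorentzian_two_parameterizations_agree(self):
        rng = np.random.default_rng(1)
        spec = LineshapeSpec(family="lorentzian", App=3.0, DeltaBpp=2.5, Bres=3450.0)
        B = 3450.0 + rng.uniform(-20, 20, 1000)
        a = lorentzian_derivative(B, spec, form="reduced")
        b = lorentzian_derivative(B, spec, form="expanded")
        assert np.max(np.abs(a - b)) <= 1e-12 * spec.App

    def test_lorentzian_wing_decay_is_cubic(self):
        spec = LineshapeSpec(family="lorentzian")
        u = np.array([50.0, 100.0, 200.0])
        vals = np.abs(lorentzian_derivative(u, spec))
        ratios = vals[:-1] / vals[1:]
        np.testing.assert_allclose(ratios, 8.0, rtol=0.05)
        assert vals[-1] < 1e-5

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="family"):
            LineshapeSpec(family="voigt")
        with pytest.raises(ValueError, match="d in"):
            LineshapeSpec(family="stretched")
        with pytest.raises(ValueError, match="App"):
            LineshapeSpec(family="gaussian", App=-1.0)


class TestRelaxationFunction:
    def test_known_values(self):
        assert relaxation_function(3, 1.0, 0.0) == 1.0
        assert relaxation_function(3, 1.0, 1.0) == pytest.approx(np.exp(-1.0))
        assert relaxation_function(1, 2.0, 8.0) == pytest.approx(np.exp(-4.0))

    @pytest.mark.parametrize("d", [1, 2, 3])
    @pytest.mark.parametrize("a", [0.3, 1.0, 4.0])
    def test_monotone_decreasing(self, d, a):
        t = np.linspace(0.0, 50.0, 500)
        g = relaxation_function(d, a, t)
        assert (np.diff(g) < 0).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="t >= 0"):
            relaxation_function(2, 1.0, -0.5)

    def test_cutoff_time_reaches_floor(self):
        for d in (1, 2, 3):
            t_max = relaxation_cutoff_time(d, 1.0)
            assert relaxation_function(d, 1.0, t_max) == pytest.approx(1e-10)


class TestStretchedQuadrature:
    def test_d3_matches_lorentzian_closed_form(self):
        """Quadrature oracle: d = 3 has the analytic Lorentzian derivative."""
        dstar = stretched_peak_position(3)
        assert dstar == pytest.approx(1 / np.sqrt(3), rel=1e-6)
        u = np.linspace(-3.17, 3.17, 401)
        num = stretched_derivative_raw(u * 2 * dstar, 3)
        num /= 2 * abs(stretched_derivative_raw(dstar, 3))
        spec = LineshapeSpec(family="lorentzian", App=1.0, DeltaBpp=1.0, Bres=0.0)
        exact = lorentzian_derivative(u, spec)
        assert np.max(np.abs(num - exact)) <= 0.01 * np.max(np.abs(exact))

    def test_trapezoid_path_matches_adaptive(self):
        for d, scale in ((2, 1.0), (1, 0.03)):
            delta = np.linspace(-1.5, 1.5, 41) * scale
            fa = stretched_derivative_raw(delta, d)
            ft = stretched_derivative_raw(delta, d, method="trapezoid")
            assert np.max(np.abs(fa - ft)) <= 1e-6 * np.max(np.abs(fa))

    def test_antisymmetric_about_center(self, stretched_lines):
        for d, (s, _) in stretched_lines.items():
            y = s.intensity
            assert np.max(np.abs(y + y[::-1])) <= 1e-9 * np.max(np.abs(y))

    def test_d2_wings_heavier_than_d3(self, stretched_lines):
        s2, p2 = stretched_lines[2]
        s3, p3 = stretched_lines[3]
        for s, p in ((s2, p2), (s3, p3)):
            assert p.App == pytest.approx(1.0, abs=1e-3)
        u2 = (s2.field - p2.Bres) / p2.DeltaBpp
        u3 = (s3.field - p3.Bres) / p3.DeltaBpp
        grid = np.linspace(2.0, 3.2, 25)
        w2 = np.interp(grid, u2, np.abs(s2.intensity))
        w3 = np.interp(grid, u3, np.abs(s3.intensity))
        assert (w2 > w3).all()

    def test_wing_ordering_across_families(self, stretched_lines):
        """|F_gauss| < |F_3| < |F_2| < |F_1| far from the center."""
        grid = np.linspace(2.5, 3.2, 15)
        wings = {}
        for d, (s, p) in stretched_lines.items():
            u = (s.field - p.Bres) / p.DeltaBpp
            wings[d] = np.interp(grid, u, np.abs(s.intensity) / p.App)
        g = LineshapeSpec(family="gaussian")
        wings["gauss"] = np.abs(gaussian_derivative(grid, g))
        assert (wings["gauss"] < wings[3]).all()
        assert (wings[3] < wings[2]).all()
        assert (wings[2] < wings[1]).all()

    def test_insufficient_cutoff_raises_with_diagnostic(self):
        with pytest.raises(QuadratureError, match="increase t_max"):
            stretched_derivative_raw(0.5, 1, t_max=10.0)

    def test_min_points_enforced(self):
        spec = LineshapeSpec(family="stretched", d=2)
        with pytest.raises(ValueError, match="1024"):
            simulate_stretched_lorentzian(spec, n_points=512)


class TestSimulationAndNormalization:
    def test_simulated_line_has_requested_parameters(self, stretched_lines):
        for d, (s, p) in stretched_lines.items():
            step = float(s.field[1] - s.field[0])
            assert p.App == pytest.approx(1.0, abs=1e-3)
            assert p.DeltaBpp == pytest.approx(1.0, abs=step)
            assert p.Bres == pytest.approx(0.0, abs=step / 2)
            assert s.baseline_corrected

    def test_normalize_is_identity_on_normalized_curve(self):
        spec = LineshapeSpec(family="lorentzian", App=2.0, DeltaBpp=1.0, Bres=0.0)
        # grid hits the center and the extrema exactly
        u = np.arange(-320, 321) * 0.01
        y = lorentzian_derivative(u, spec)
        out = normalize_lineshape(u, y, App=2.0, DeltaBpp=1.0, Bres=0.0)
        np.testing.assert_allclose(out.field, u, atol=1e-10)
        np.testing.assert_allclose(out.intensity, y, atol=1e-10)

    def test_normalized_shape_independent_of_a(self):
        """a only rescales the field axis; normalization removes it."""
        curves = {}
        for a in (1.0, 2.0):
            spec = LineshapeSpec(family="stretched", d=2, a=a)
            curves[a] = simulate_stretched_lorentzian(spec, n_points=1024, x_max=10.0)
        np.testing.assert_allclose(curves[1.0].field, curves[2.0].field, atol=1e-9)
        np.testing.assert_allclose(
            curves[1.0].intensity, curves[2.0].intensity, atol=1e-6
        )

    def test_normalize_rejects_degenerate_curve(self):
        from eprshape.errors import ExtractionError

        x = np.linspace(0.0, 1.0, 64)
        with pytest.raises(ExtractionError):
            normalize_lineshape(x, x.copy(), App=1.0, DeltaBpp=1.0, Bres=0.5)

    def test_roundtrip_through_extraction(self, stretched_lines):
        for d, (s, _) in stretched_lines.items():
            p = extract_classical_params(s)
            renorm = normalize_lineshape(s.field, s.intensity, App=3.0,
                                         DeltaBpp=2.0, Bres=100.0)
            q = extract_classical_params(renorm)
            step = float(renorm.field[1] - renorm.field[0])
            assert q.App == pytest.approx(3.0, rel=1e-9)
            assert q.DeltaBpp == pytest.approx(2.0, abs=step)
            assert q.Bres == pytest.approx(100.0, abs=step)


class TestEvaluateLineshapeDispatch:
    def test_all_families_vanish_at_center_and_are_odd(self):
        B = np.linspace(-3.0, 3.0, 601)
        for fam, d in (("gaussian", None), ("lorentzian", None),
                       ("stretched", 2)):
            spec = LineshapeSpec(family=fam, d=d)
            y = evaluate_lineshape(B, spec)
            assert abs(y[300]) <= 1e-12
            np.testing.assert_allclose(y, -y[::-1], atol=1e-9)
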