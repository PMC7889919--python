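import math

import numpy as np
import pytest

from agederm.em_solver import PlaneWaveExposure, analyze
from agederm.thermal_solver import (
    ThermalBoundary,
    VolumetricSource,
    fd_reference_solution,
    solve_steady_bioheat,
    temperature_rise,
)
from agederm.tissue_model import ComplexPermittivity, TissueLayer


def perfused_halfspace(perfusion=2550.0, lam=0.49):
    return [
        TissueLayer(
            "muscle",
            math.inf,
            {60e9: ComplexPermittivity(12.86, 15.83)},
            thermal_conductivity=lam,
            density=1090.0,
            perfusion=perfusion,
        )
    ]


@pytest.fixture(scope="module")
def adult_rise(adult_stack, adult_em):
    return temperature_rise(adult_stack, adult_em)


class TestClosedForms:
    """Constant-coefficient single-layer cases with pencil-and-paper
    solutions of the steady Pennes equation."""

    Q0 = 1000.0

    def test_insulated_surface_uniform_rise(self):
        layers = perfused_halfspace()
        src = VolumetricSource.uniform(layers, [self.Q0])
        sol = solve_steady_bioheat(
            layers, src, ThermalBoundary(h_convective=0.0), difference_problem=True
        )
        z = np.array([0.0, 1e-3, 1e-2, 5e-2])
        assert np.allclose(sol.evaluate(z), self.Q0 / 2550.0, rtol=1e-9)

    def test_cold_surface_exponential_profile(self):
        """h -> infinity pins the surface rise to zero, leaving
        (q0/B)(1 - exp(-m z))."""
        layers = perfused_halfspace()
        src = VolumetricSource.uniform(layers, [self.Q0])
        sol = solve_steady_bioheat(
            layers, src, ThermalBoundary(h_convective=1e12), difference_problem=True
        )
        m = math.sqrt(2550.0 / 0.49)
        z = np.linspace(0, 0.05, 40)
        expected = self.Q0 / 2550.0 * (1 - np.exp(-m * z))
        assert np.allclose(sol.evaluate(z), expected, atol=1e-8)

    def test_finite_h_robin_closed_form(self):
        layers = perfused_halfspace()
        src = VolumetricSource.uniform(layers, [self.Q0])
        h, lam, B = 7.0, 0.49, 2550.0
        m = math.sqrt(B / lam)
        sol = solve_steady_bioheat(
            layers, src, ThermalBoundary(h_convective=h), difference_problem=True
        )
        c = -h * (self.Q0 / B) / (lam * m + h)
        z = np.linspace(0, 0.05, 40)
        assert np.allclose(sol.evaluate(z), self.Q0 / B + c * np.exp(-m * z), rtol=1e-9)


class TestBaseline:
    def test_zero_source_no_rise(self, adult_stack):
        src = VolumetricSource.zero(adult_stack.thermal_view)
        sol = solve_steady_bioheat(adult_stack, src, difference_problem=True)
        z = np.linspace(0, 0.03, 60)
        assert np.allclose(sol.evaluate(z), 0.0, atol=1e-12)

    def test_baseline_between_air_and_blood(self, adult_stack):
        """Maximum principle: with no source the profile is bracketed by
        the ambient and blood temperatures."""
        src = VolumetricSource.zero(adult_stack.thermal_view)
        sol = solve_steady_bioheat(adult_stack, src)
        z = np.linspace(0, 0.05, 200)
        temps = sol.evaluate(z)
        assert np.all(temps >= 20.0 - 1e-9) and np.all(temps <= 37.0 + 1e-9)
        assert np.all(np.diff(temps) >= -1e-12)  # warms monotonically with depth

    def test_baseline_residuals_small(self, adult_stack):
        src = VolumetricSource.zero(adult_stack.thermal_view)
        sol = solve_steady_bioheat(adult_stack, src)
        assert max(abs(v) for v in sol.boundary_residuals().values()) < 1e-9

    def test_terminal_must_be_perfused(self):
        layers = perfused_halfspace(perfusion=0.0)
        src = VolumetricSource.zero(layers)
        with pytest.raises(ValueError, match="perfused"):
            solve_steady_bioheat(layers, src)


class TestTemperatureRise:
    def test_residuals_below_1e9(self, adult_rise):
        assert max(abs(v) for v in adult_rise.boundary_residuals().values()) < 1e-9

    def test_rise_nonnegative(self, adult_rise):
        z = np.linspace(0, 0.05, 400)
        assert np.all(adult_rise.evaluate(z) >= -1e-12)

    def test_two_routes_agree(self, adult_stack, adult_em):
        a = temperature_rise(adult_stack, adult_em, method="difference")
        b = temperature_rise(adult_stack, adult_em, method="two_solves")
        z = np.linspace(0, 0.03, 200)
        assert np.max(np.abs(a.evaluate(z) - b.evaluate(z))) < 1e-9

    def test_linear_in_ipd(self, adult_stack, frequency):
        e1 = analyze(adult_stack, PlaneWaveExposure(frequency, 10.0), grid_step=5e-6)
        e2 = analyze(adult_stack, PlaneWaveExposure(frequency, 20.0), grid_step=5e-6)
        r1 = temperature_rise(adult_stack, e1)
        r2 = temperature_rise(adult_stack, e2)
        z = np.linspace(0, 0.02, 100)
        assert np.allclose(r2.evaluate(z), 2.0 * r1.evaluate(z), rtol=1e-12)

    def test_more_perfusion_less_heating(self, adult_stack, adult_em):
        cooler = [
            TissueLayer(
                l.name, l.thickness, l.permittivity, l.thermal_conductivity,
                l.density, l.perfusion * (3.0 if l.name == "dermis" else 1.0),
            )
            for l in adult_stack.thermal_view
        ]
        base = temperature_rise(adult_stack, adult_em).peak()[0]
        cooled = temperature_rise(cooler, adult_em).peak()[0]
        assert cooled < base

    def test_60ghz_heats_more_than_26ghz(self):
        from agederm.tissue_model import build_adult_stack

        peaks = {}
        for f in (26e9, 60e9):
            st = build_adult_stack(f)
            em = analyze(st, PlaneWaveExposure(f, 10.0), grid_step=2e-6)
            peaks[f] = temperature_rise(st, em).peak()[0]
        assert peaks[60e9] > peaks[26e9]

    def test_unknown_method(self, adult_stack, adult_em):
        with pytest.raises(ValueError):
            temperature_rise(adult_stack, adult_em, method="nope")


class TestSourceMapping:
    def test_source_nonnegative_and_continuous_within_layers(self, adult_stack, adult_em):
        src = VolumetricSource.from_em(
            adult_em.solution, adult_stack.thermal_view, 10.0
        )
        z = np.linspace(0, 0.01, 500)
        q = src.evaluate(z)
        assert np.all(q >= -1e-9)

    def test_source_matches_rho_sar(self, adult_stack, adult_em, frequency):
        """q(z) must equal sigma |E|^2 / 2 = rho * SAR pointwise."""
        from agederm.em_solver import sar_at

        src = VolumetricSource.from_em(
            adult_em.solution, adult_stack.thermal_view, 10.0
        )
        exp = PlaneWaveExposure(frequency, 10.0)
        for z in (5e-6, 1e-4, 1e-3, 2e-3, 6e-3):
            lf, _ = adult_em.solution.locate(z)
            expected = lf.density * sar_at(
                adult_stack, frequency, exp, z, solution=adult_em.solution
            )
            assert src.evaluate(z) == pytest.approx(expected, rel=1e-9)

    def test_integral_consistency(self, adult_stack, adult_em):
        """The analytic segment integral must agree with dense quadrature."""
        src = VolumetricSource.from_em(
            adult_em.solution, adult_stack.thermal_view, 10.0
        )
        # integrate per layer: q jumps at interfaces, so quadrature must
        # not straddle them
        numeric, z_top = 0.0, 0.0
        for h in src.thicknesses[:-1]:
            z = np.linspace(z_top, z_top + h - 1e-13, 4001)
            numeric += np.trapezoid(src.evaluate(z), z)
            z_top += h
        assert src.integrate(0.0, z_top) == pytest.approx(numeric, rel=1e-6)


class TestFDReference:
    def test_zero_source_zero_rise(self, adult_stack):
        src = VolumetricSource.zero(adult_stack.thermal_view)
        fd = fd_reference_solution(adult_stack, src, grid_step=1e-5, difference_problem=True)
        # bounded by solve round-off: the tridiagonal system mixes
        # lambda/dz^2 ~ 1e9 with B ~ 1e3 entries
        assert np.max(np.abs(fd.values)) < 5e-8

    def test_reproduces_truncated_closed_form(self):
        layers = perfused_halfspace()
        q0, h, lam, B, L = 1000.0, 7.0, 0.49, 2550.0, 0.06
        m = math.sqrt(B / lam)
        src = VolumetricSource.uniform(layers, [q0])
        # exact solution of the truncated problem (Robin top, u(L)=0)
        A = np.array([[math.exp(m * L), math.exp(-m * L)], [lam * m - h, -lam * m - h]])
        ca, cb = np.linalg.solve(A, np.array([-q0 / B, h * q0 / B]))
        fd = fd_reference_solution(
            layers, src, ThermalBoundary(h_convective=h), grid_step=1e-5,
            difference_problem=True,
        )
        exact = q0 / B + ca * np.exp(m * fd.depths) + cb * np.exp(-m * fd.depths)
        assert np.max(np.abs(fd.values - exact)) < 1e-6

    def test_grid_convergence_second_order(self):
        """On a sinusoidal manufactured source (numerically cell-averaged)
        halving the grid step reduces the error at least threefold."""
        layers = perfused_halfspace()
        h, lam, B, L = 7.0, 0.49, 2550.0, 0.06
        m = math.sqrt(B / lam)
        q0, omega = 1e6, 2 * math.pi / 1e-3

        def q(z):
            return q0 * (1 + np.sin(omega * np.asarray(z)))

        # particular: q0/B + (q0/lam)/(omega^2 + m^2) sin(omega z)
        amp = (q0 / lam) / (omega**2 + m**2)

        def exact(z, ca, cb):
            return (
                q0 / B + amp * np.sin(omega * z) + ca * np.exp(m * z) + cb * np.exp(-m * z)
            )

        # boundary rows for the homogeneous coefficients
        part0, dpart0 = q0 / B, amp * omega
        partL = q0 / B + amp * math.sin(omega * L)
        A = np.array([[math.exp(m * L), math.exp(-m * L)], [lam * m - h, -lam * m - h]])
        b = np.array([-partL, h * part0 - lam * dpart0])
        ca, cb = np.linalg.solve(A, b)

        errs = []
        for gs in (1e-5, 5e-6):
            fd = fd_reference_solution(
                layers, q, ThermalBoundary(h_convective=h), grid_step=gs,
                difference_problem=True,
            )
            errs.append(np.max(np.abs(fd.values - exact(fd.depths, ca, cb))))
        assert errs[0] / errs[1] >= 3.0

    def test_truncation_insensitive_peak(self, adult_stack, adult_em):
        src = VolumetricSource.from_em(
            adult_em.solution, adult_stack.thermal_view,
            adult_em.incident_power_density,
        )
        p60 = fd_reference_solution(
            adult_stack, src, grid_step=1e-5, truncation_depth=0.06,
            difference_problem=True,
        ).peak()[0]
        p120 = fd_reference_solution(
            adult_stack, src, grid_step=1e-5, truncation_depth=0.12,
            difference_problem=True,
        ).peak()[0]
        assert abs(p60 - p120) < 1e-4

    def test_matches_analytic_on_adult_stack(self, adult_stack, adult_em, adult_rise):
        src = VolumetricSource.from_em(
            adult_em.solution, adult_stack.thermal_view,
            adult_em.incident_power_density,
        )
        fd = fd_reference_solution(
            adult_stack, src, grid_step=5e-6, truncation_depth=0.12,
            difference_problem=True,
        )
        assert abs(fd.peak()[0] - adult_rise.peak()[0]) <= 1e-3
        profile_err = np.max(np.abs(fd.values - adult_rise.evaluate(fd.depths)))
        assert profile_err <= 1e-3

    def test_grid_step_guard(self, adult_stack):
        src = VolumetricSource.zero(adult_stack.thermal_view)
        with pytest.raises(ValueError):
            fd_reference_solution(adult_stack, src, grid_step=1e-4)


class TestProfileExports:
    def test_thermal_profile_frame_consistency(self, adult_stack, adult_em):
        from agederm.thermal_solver import thermal_profile_frame

        frame = thermal_profile_frame(adult_stack, adult_em)
        assert list(frame.columns) == [
            "depth_m", "T_baseline_C", "T_exposed_C", "delta_T_C",
        ]
        assert np.allclose(
            frame["delta_T_C"], frame["T_exposed_C"] - frame["T_baseline_C"]
        )
        rise = temperature_rise(adult_stack, adult_em)
        assert np.allclose(
            frame["delta_T_C"], rise.evaluate(frame["depth_m"].to_numpy()), atol=1e-9
        )

    def test_em_profile_frame(self, adult_em):
        frame = adult_em.profile_frame()
        assert {"depth_m", "E_abs", "SAR_W_per_kg"} == set(frame.columns)
        assert frame["SAR_W_per_kg"].max() == pytest.approx(adult_em.peak_sar)
        summary = adult_em.summary_dict()
        assert summary["tc"] == adult_em.transmission_coefficient
        assert sum(summary["fractions"].values()) == pytest.approx(1.0, abs=1e-9)
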