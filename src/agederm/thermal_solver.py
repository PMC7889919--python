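"""Steady-state Pennes bioheat solver for the layered thermal stack.

The 1-D steady Pennes equation in layer *i* (local coordinate
``z_i in [0, h_i]``) is

    lambda_i T_i'' = B_i (T_i - T_blood) - q_i(z_i),

where ``B_i = BF_i rho_b C_b`` is the perfusion heat-sink coefficient and
``q_i = rho_i SAR_i = sigma_i |E|^2 / 2`` the electromagnetic heat source.
Interfaces impose continuity of temperature and conductive flux; the
terminal (muscle) layer relaxes to the blood temperature at depth, and the
surface exchanges heat with air through a convective coefficient
(``lambda_1 T'(0) = h (T(0) - T_air)``, outward-normal convention, so the
surface loses heat to cooler air).

The solver is fully analytic: in each layer the homogeneous solution is a
pair of exponentials ``exp(+-m z)`` with ``m = sqrt(B/lambda)`` (an affine
function when B = 0), and the EM source -- a sum of complex exponentials in
depth -- admits particular solutions by undetermined coefficients, with a
polynomial lift in the resonant case where a source exponent coincides
with ``+-m``.  A finite-difference solver on a truncated domain is
provided as an independent numerical reference.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from . import constants
from .em_solver import EMResult, FieldSolution
from .tissue_model import TissueLayer, TissueStack

__all__ = [
    "ThermalBoundary",
    "VolumetricSource",
    "TemperatureSolution",
    "FDTemperature",
    "solve_steady_bioheat",
    "temperature_rise",
    "thermal_profile_frame",
    "fd_reference_solution",
]

#: |m - g| threshold (m^-1) below which a source exponent is treated as
#: resonant with the homogeneous rate and the polynomial lift is used.
RESONANCE_TOL = 1e-6


@dataclass(frozen=True)
class ThermalBoundary:
    """Surface convection and reference temperatures."""

    h_convective: float = constants.HEAT_TRANSFER_COEFFICIENT  # W m^-2 degC^-1
    t_air: float = constants.T_AIR  # degC
    t_blood: float = constants.T_BLOOD  # degC

    def __post_init__(self) -> None:
        if self.h_convective < 0:
            raise ValueError("h_convective must be >= 0")


@dataclass(frozen=True)
class _SourceTerm:
    """One complex-exponential source component c * exp(g z)."""

    c: complex
    g: complex


@dataclass(frozen=True)
class VolumetricSource:
    """Per-layer heat source q(z) as sums of complex exponentials.

    The terms of each layer sum to a real, non-negative q; they arise from
    ``sigma |E|^2 / 2`` with E a forward+backward wave pair, which expands
    into two real-exponent terms and a conjugate pair of oscillatory ones.
    """

    layer_terms: tuple[tuple[_SourceTerm, ...], ...]
    z_tops: tuple[float, ...]
    thicknesses: tuple[float, ...]

    @classmethod
    def zero(cls, layers: Sequence[TissueLayer]) -> "VolumetricSource":
        z_tops, z = [], 0.0
        for l in layers:
            z_tops.append(z)
            z += l.thickness
        return cls(
            layer_terms=tuple(() for _ in layers),
            z_tops=tuple(z_tops),
            thicknesses=tuple(l.thickness for l in layers),
        )

    @classmethod
    def from_em(
        cls,
        solution: FieldSolution,
        thermal_layers: Sequence[TissueLayer],
        incident_power_density: float,
    ) -> "VolumetricSource":
        """Map an EM field solution onto a (possibly finer) thermal stack.

        Each thermal layer is located inside the EM layer containing it
        (the ED layer covers both viable epidermis and dermis); the wave
        amplitudes are shifted to the thermal layer's own origin.
        """
        e0_sq = 2.0 * constants.FREE_SPACE_IMPEDANCE * incident_power_density
        terms_all: list[tuple[_SourceTerm, ...]] = []
        z_tops: list[float] = []
        z = 0.0
        for tl in thermal_layers:
            z_tops.append(z)
            mid = z + (min(tl.thickness, 1e-3) * 0.5)
            lf, _ = solution.locate(mid)
            d = z - lf.z_top  # offset of thermal-layer top inside EM layer
            pref = lf.sigma * e0_sq / 2.0
            f, b, k = lf.forward, lf.backward, lf.k
            raw = [
                (pref * abs(f) ** 2, 2.0 * k.imag),
                (pref * abs(b) ** 2, -2.0 * k.imag),
                (pref * f * b.conjugate(), -2j * k.real),
                (pref * f.conjugate() * b, 2j * k.real),
            ]
            terms = tuple(
                _SourceTerm(c * cmath.exp(g * d), g)
                for c, g in raw
                if c != 0
            )
            terms_all.append(terms)
            z += tl.thickness
        return cls(
            layer_terms=tuple(terms_all),
            z_tops=tuple(z_tops),
            thicknesses=tuple(l.thickness for l in thermal_layers),
        )

    @classmethod
    def uniform(
        cls, layers: Sequence[TissueLayer], q_per_layer: Sequence[float]
    ) -> "VolumetricSource":
        """Constant source density per layer (useful for closed-form tests)."""
        z_tops, z = [], 0.0
        for l in layers:
            z_tops.append(z)
            z += l.thickness
        return cls(
            layer_terms=tuple(
                (_SourceTerm(complex(q), 0.0),) if q else () for q in q_per_layer
            ),
            z_tops=tuple(z_tops),
            thicknesses=tuple(l.thickness for l in layers),
        )

    def evaluate(self, depth) -> np.ndarray | float:
        """q at global depth(s), W m^-3."""
        depths = np.atleast_1d(np.asarray(depth, dtype=float))
        out = np.zeros(depths.shape)
        ends = np.cumsum(self.thicknesses)
        for i, zg in enumerate(depths):
            idx = int(np.searchsorted(ends[:-1], zg, side="right"))
            zloc = zg - self.z_tops[idx]
            q = sum(
                t.c * cmath.exp(t.g * zloc) for t in self.layer_terms[idx]
            )
            out[i] = q.real if q != 0 else 0.0
        return out if np.ndim(depth) else float(out[0])

    def integrate(self, z1: float, z2: float) -> float:
        """Exact integral of q over a global-depth interval, W m^-2."""
        if z2 <= z1:
            return 0.0
        ends = np.cumsum(self.thicknesses)
        total = 0.0
        for idx, terms in enumerate(self.layer_terms):
            lo = self.z_tops[idx]
            hi = ends[idx]
            a, b = max(z1, lo), min(z2, hi)
            if b <= a:
                continue
            la, lb = a - lo, b - lo
            for t in terms:
                if t.g == 0:
                    total += (t.c * (lb - la)).real
                else:
                    total += (t.c / t.g * (cmath.exp(t.g * lb) - cmath.exp(t.g * la))).real
        return total


@dataclass(frozen=True)
class _PolyExpTerm:
    """c * z**p * exp(g z) building block of a particular solution."""

    c: complex
    g: complex
    p: int

    def value(self, z: float) -> complex:
        return self.c * z**self.p * cmath.exp(self.g * z)

    def deriv(self, z: float) -> complex:
        base = self.c * cmath.exp(self.g * z)
        poly = self.g * z**self.p
        if self.p > 0:
            poly += self.p * z ** (self.p - 1)
        return base * poly


def _particular(terms: Sequence[_SourceTerm], lam: float, m: float) -> tuple[_PolyExpTerm, ...]:
    """Particular solution of u'' - m^2 u = -q/lambda for exponential q."""
    out = []
    for t in terms:
        g = t.g
        rhs = -t.c / lam
        if m > 0 and min(abs(g - m), abs(g + m)) < RESONANCE_TOL:
            out.append(_PolyExpTerm(rhs / (2.0 * g), g, 1))
        elif m == 0 and abs(g) < RESONANCE_TOL:
            out.append(_PolyExpTerm(rhs / 2.0, 0.0, 2))
        else:
            out.append(_PolyExpTerm(rhs / (g * g - m * m), g, 0))
    return tuple(out)


def _part_value(terms: Sequence[_PolyExpTerm], z: float) -> float:
    return float(sum(t.value(z) for t in terms).real) if terms else 0.0


def _part_deriv(terms: Sequence[_PolyExpTerm], z: float) -> float:
    return float(sum(t.deriv(z) for t in terms).real) if terms else 0.0


@dataclass(frozen=True)
class _LayerSolution:
    """u(z) = a phi1 + b phi2 + particular, u = T - T_blood (or Delta T)."""

    name: str
    z_top: float
    thickness: float
    lam: float
    m: float  # sqrt(B/lambda), 0 for unperfused
    a: float
    b: float
    part: tuple[_PolyExpTerm, ...]

    def _hom(self, z: float) -> float:
        if math.isinf(self.thickness):
            return self.b * math.exp(-self.m * z)
        if self.m > 0:
            # bounded basis: both exponentials referenced to their decaying end
            return self.a * math.exp(-self.m * (self.thickness - z)) + self.b * math.exp(
                -self.m * z
            )
        return self.a + self.b * z

    def _hom_deriv(self, z: float) -> float:
        if math.isinf(self.thickness):
            return -self.m * self.b * math.exp(-self.m * z)
        if self.m > 0:
            return self.m * self.a * math.exp(
                -self.m * (self.thickness - z)
            ) - self.m * self.b * math.exp(-self.m * z)
        return self.b

    def u(self, z: float) -> float:
        return self._hom(z) + _part_value(self.part, z)

    def u_deriv(self, z: float) -> float:
        return self._hom_deriv(z) + _part_deriv(self.part, z)


@dataclass(frozen=True)
class TemperatureSolution:
    """Piecewise-analytic solution; ``kind`` is "absolute" (T in degC) or
    "rise" (temperature elevation above the unexposed state)."""

    kind: str
    layers: tuple[_LayerSolution, ...]
    boundary: ThermalBoundary

    @property
    def _offset(self) -> float:
        return self.boundary.t_blood if self.kind == "absolute" else 0.0

    def _locate(self, depth: float) -> tuple[_LayerSolution, float]:
        if depth < 0:
            raise ValueError("depth must be >= 0")
        for ls in self.layers[:-1]:
            if depth <= ls.z_top + ls.thickness:
                return ls, depth - ls.z_top
        last = self.layers[-1]
        return last, depth - last.z_top

    def evaluate(self, depth) -> np.ndarray | float:
        depths = np.atleast_1d(np.asarray(depth, dtype=float))
        out = np.empty(depths.shape)
        for i, z in enumerate(depths):
            ls, zloc = self._locate(float(z))
            out[i] = ls.u(zloc) + self._offset
        return out if np.ndim(depth) else float(out[0])

    def __call__(self, depth):
        return self.evaluate(depth)

    def peak(self, *, grid_step: float = 2e-6) -> tuple[float, float]:
        """(value, depth) of the maximum over a dense per-layer grid."""
        best, best_z = -math.inf, 0.0
        for ls in self.layers:
            if math.isinf(ls.thickness):
                span = 6.0 / ls.m if ls.m > 0 else 0.05
            else:
                span = ls.thickness
            n = min(max(int(span / grid_step) + 1, 101), 4001)
            z = np.linspace(0.0, span, n)
            vals = np.array([ls.u(zz) for zz in z]) + self._offset
            i = int(np.argmax(vals))
            if vals[i] > best:
                best, best_z = float(vals[i]), float(z[i] + ls.z_top)
        return best, best_z

    def boundary_residuals(self) -> dict[str, float]:
        """Residuals of the surface, interface and deep conditions."""
        bc = self.boundary
        first = self.layers[0]
        t_air_eff = bc.t_air if self.kind == "absolute" else 0.0
        offset = self._offset
        res = {
            "surface": first.lam * first.u_deriv(0.0)
            - bc.h_convective * (first.u(0.0) + offset - t_air_eff)
        }
        for i in range(len(self.layers) - 1):
            lo, hi = self.layers[i], self.layers[i + 1]
            res[f"T_{lo.name}|{hi.name}"] = lo.u(lo.thickness) - hi.u(0.0)
            res[f"flux_{lo.name}|{hi.name}"] = lo.lam * lo.u_deriv(
                lo.thickness
            ) - hi.lam * hi.u_deriv(0.0)
        # deep condition: the homogeneous part must decay (no growing mode),
        # so at depth only the bounded particular response remains
        last = self.layers[-1]
        z_deep = 40.0 / last.m if last.m > 0 else 1.0
        res["deep"] = last.u(z_deep) - _part_value(last.part, z_deep)
        return res


def _thermal_layers(stack: TissueStack | Sequence[TissueLayer]) -> tuple[TissueLayer, ...]:
    if isinstance(stack, TissueStack):
        if not stack.thermal_view:
            raise ValueError("stack has no thermal view")
        return stack.thermal_view
    return tuple(stack)


def solve_steady_bioheat(
    stack: TissueStack | Sequence[TissueLayer],
    source: VolumetricSource,
    bc: ThermalBoundary | None = None,
    *,
    difference_problem: bool = False,
) -> TemperatureSolution:
    """Solve the layered steady Pennes problem analytically.

    With ``difference_problem=True`` the surface condition is homogeneous
    (``lambda dU/dz|0 = h U(0)``, ``U(inf) = 0``) and the returned solution
    is the temperature rise produced by the source; otherwise the absolute
    temperature field toward ``t_air``/``t_blood`` is returned.
    """
    layers = _thermal_layers(stack)
    bc = bc or ThermalBoundary()
    n = len(layers)
    term = layers[-1]
    if term.perfusion <= 0:
        raise ValueError("terminal layer must be perfused (B > 0) so T -> T_blood")

    ms, parts = [], []
    for i, l in enumerate(layers):
        m = math.sqrt(l.perfusion / l.thermal_conductivity)
        ms.append(m)
        parts.append(_particular(source.layer_terms[i], l.thermal_conductivity, m))

    # unknowns: [a_0, b_0, ..., a_{n-2}, b_{n-2}, b_{n-1}]
    n_unknown = 2 * (n - 1) + 1
    col = [2 * i for i in range(n - 1)] + [2 * (n - 1)]

    def basis(i: int, z: float) -> tuple[list[float], list[float]]:
        """(values, derivs) of layer i's homogeneous basis at local z."""
        l, m = layers[i], ms[i]
        if i == n - 1:
            e = math.exp(-m * z)
            return [e], [-m * e]
        if m > 0:
            h = l.thickness
            e1, e2 = math.exp(-m * (h - z)), math.exp(-m * z)
            return [e1, e2], [m * e1, -m * e2]
        return [1.0, z], [0.0, 1.0]

    A = np.zeros((n_unknown, n_unknown))
    rhs = np.zeros(n_unknown)
    row = 0

    # surface: lam u'(0) - h u(0) = h (T_blood - T_air)  [full problem]
    vals, ders = basis(0, 0.0)
    for j, (v, d) in enumerate(zip(vals, ders)):
        A[row, col[0] + j] = layers[0].thermal_conductivity * d - bc.h_convective * v
    drive = 0.0 if difference_problem else bc.h_convective * (bc.t_blood - bc.t_air)
    rhs[row] = drive - layers[0].thermal_conductivity * _part_deriv(
        parts[0], 0.0
    ) + bc.h_convective * _part_value(parts[0], 0.0)
    row += 1

    for i in range(n - 1):
        h_i = layers[i].thickness
        v_lo, d_lo = basis(i, h_i)
        v_hi, d_hi = basis(i + 1, 0.0)
        # temperature continuity
        for j, v in enumerate(v_lo):
            A[row, col[i] + j] = v
        for j, v in enumerate(v_hi):
            A[row, col[i + 1] + j] = -v
        rhs[row] = _part_value(parts[i + 1], 0.0) - _part_value(parts[i], h_i)
        row += 1
        # flux continuity
        lam_lo = layers[i].thermal_conductivity
        lam_hi = layers[i + 1].thermal_conductivity
        for j, d in enumerate(d_lo):
            A[row, col[i] + j] = lam_lo * d
        for j, d in enumerate(d_hi):
            A[row, col[i + 1] + j] = -lam_hi * d
        rhs[row] = lam_hi * _part_deriv(parts[i + 1], 0.0) - lam_lo * _part_deriv(
            parts[i], h_i
        )
        row += 1

    try:
        x = np.linalg.solve(A, rhs)
        # one step of iterative refinement: the system mixes O(1) value rows
        # with O(lambda m) flux rows, and this recovers ~machine residuals
        x += np.linalg.solve(A, rhs - A @ x)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular bioheat system: {exc}") from exc

    sols = []
    z_top = 0.0
    for i, l in enumerate(layers):
        if i == n - 1:
            a, b = 0.0, float(x[col[i]])
        else:
            a, b = float(x[col[i]]), float(x[col[i] + 1])
        sols.append(
            _LayerSolution(
                name=l.name,
                z_top=z_top,
                thickness=l.thickness,
                lam=l.thermal_conductivity,
                m=ms[i],
                a=a,
                b=b,
                part=parts[i],
            )
        )
        z_top += l.thickness
    return TemperatureSolution(
        kind="rise" if difference_problem else "absolute",
        layers=tuple(sols),
        boundary=bc,
    )


def temperature_rise(
    stack: TissueStack | Sequence[TissueLayer],
    em_result: EMResult,
    bc: ThermalBoundary | None = None,
    *,
    method: str = "difference",
) -> TemperatureSolution:
    """Steady-state temperature elevation produced by an EM exposure.

    ``method="difference"`` solves the homogeneous-boundary difference
    problem directly; ``method="two_solves"`` subtracts the unexposed from
    the exposed absolute solution.  By linearity the two agree to solver
    precision.
    """
    layers = _thermal_layers(stack)
    bc = bc or ThermalBoundary()
    source = VolumetricSource.from_em(
        em_result.solution, layers, em_result.incident_power_density
    )
    if method == "difference":
        return solve_steady_bioheat(layers, source, bc, difference_problem=True)
    if method != "two_solves":
        raise ValueError(f"unknown method {method!r}")
    exposed = solve_steady_bioheat(layers, source, bc)
    baseline = solve_steady_bioheat(layers, VolumetricSource.zero(layers), bc)
    diff_layers = tuple(
        _LayerSolution(
            name=e.name,
            z_top=e.z_top,
            thickness=e.thickness,
            lam=e.lam,
            m=e.m,
            a=e.a - b.a,
            b=e.b - b.b,
            part=e.part,  # baseline has no particular terms
        )
        for e, b in zip(exposed.layers, baseline.layers)
    )
    return TemperatureSolution(kind="rise", layers=diff_layers, boundary=bc)


def thermal_profile_frame(
    stack: TissueStack | Sequence[TissueLayer],
    em_result: EMResult,
    bc: ThermalBoundary | None = None,
    depths=None,
):
    """Tidy profile table (depth_m, T_baseline_C, T_exposed_C, delta_T_C)."""
    import pandas as pd

    layers = _thermal_layers(stack)
    bc = bc or ThermalBoundary()
    if depths is None:
        finite = sum(l.thickness for l in layers[:-1])
        depths = np.linspace(0.0, finite + 0.01, 2001)
    depths = np.asarray(depths, dtype=float)
    source = VolumetricSource.from_em(
        em_result.solution, layers, em_result.incident_power_density
    )
    baseline = solve_steady_bioheat(layers, VolumetricSource.zero(layers), bc)
    exposed = solve_steady_bioheat(layers, source, bc)
    t_base = baseline.evaluate(depths)
    t_exp = exposed.evaluate(depths)
    return pd.DataFrame(
        {
            "depth_m": depths,
            "T_baseline_C": t_base,
            "T_exposed_C": t_exp,
            "delta_T_C": t_exp - t_base,
        }
    )


@dataclass(frozen=True)
class FDTemperature:
    """Finite-difference solution on a truncated uniform grid."""

    kind: str
    depths: np.ndarray
    values: np.ndarray

    def evaluate(self, depth):
        return np.interp(depth, self.depths, self.values)

    def __call__(self, depth):
        return self.evaluate(depth)

    def peak(self) -> tuple[float, float]:
        i = int(np.argmax(self.values))
        return float(self.values[i]), float(self.depths[i])


def fd_reference_solution(
    stack: TissueStack | Sequence[TissueLayer],
    source: VolumetricSource | Callable[[np.ndarray], np.ndarray],
    bc: ThermalBoundary | None = None,
    grid_step: float = 5e-6,
    truncation_depth: float = 0.06,
    *,
    difference_problem: bool = False,
) -> FDTemperature:
    """Conservative finite-volume reference for the same problem.

    Control volumes centred on a uniform node grid; the face conductance is
    the exact series (thickness-weighted harmonic) conductance across any
    material interface the face interval straddles, the perfusion and
    source terms are exact cell averages, the surface condition enters as
    the convective flux on the first half-cell, and a Dirichlet
    ``T = T_blood`` condition at ``truncation_depth`` stands in for the
    semi-infinite muscle (decay length sqrt(lambda/B) ~ 14 mm, so 60 mm
    truncation is immaterial).  Entirely independent of the analytic
    route; used as a numerical oracle.
    """
    layers = _thermal_layers(stack)
    bc = bc or ThermalBoundary()
    if grid_step > 1e-5:
        raise ValueError("grid_step must be <= 10 um")
    if truncation_depth < sum(l.thickness for l in layers[:-1]):
        raise ValueError("truncation_depth must contain all finite layers")

    n_nodes = int(round(truncation_depth / grid_step)) + 1
    z = np.linspace(0.0, truncation_depth, n_nodes)
    dz = z[1] - z[0]

    ends_fin = np.cumsum([l.thickness for l in layers[:-1]])
    bounds = np.concatenate([[0.0], ends_fin, [math.inf]])
    lam_by_layer = np.array([l.thermal_conductivity for l in layers])
    perf_by_layer = np.array([l.perfusion for l in layers])

    def seg_split(a: float, b: float):
        """(length, layer index) pieces of [a, b] split at interfaces."""
        pieces = []
        lo = a
        while lo < b - 1e-18:
            i = int(np.searchsorted(bounds[1:-1], lo, side="right"))
            hi = min(b, bounds[i + 1])
            pieces.append((hi - lo, i))
            lo = hi
        return pieces

    def face_conductance(a: float, b: float) -> float:
        resistance = sum(d / lam_by_layer[i] for d, i in seg_split(a, b))
        return (b - a) / resistance

    def cell_perfusion(a: float, b: float) -> float:
        return sum(d * perf_by_layer[i] for d, i in seg_split(a, b)) / (b - a)

    if isinstance(source, VolumetricSource):
        def cell_source(a: float, b: float) -> float:
            return source.integrate(a, b) / (b - a)
    else:
        def cell_source(a: float, b: float) -> float:
            zz = np.linspace(a, b, 9)
            return float(np.trapezoid(np.asarray(source(zz), float), zz) / (b - a))

    t_air_eff = bc.t_blood if difference_problem else bc.t_air

    # tridiagonal system over nodes 0 .. n-2 (bottom node is Dirichlet)
    n_un = n_nodes - 1
    ab = np.zeros((3, n_un))
    b_vec = np.zeros(n_un)

    lam_e = face_conductance(0.0, dz)
    q0 = cell_source(0.0, 0.5 * dz)
    b0 = cell_perfusion(0.0, 0.5 * dz)
    w0 = 0.5 * dz
    ab[1, 0] = -lam_e / (dz * w0) - bc.h_convective / w0 - b0
    ab[0, 1] = lam_e / (dz * w0)
    b_vec[0] = -q0 - (bc.h_convective / w0) * t_air_eff - b0 * bc.t_blood

    for j in range(1, n_un):
        lam_w = lam_e
        lam_e = face_conductance(z[j], z[j + 1])
        bj = cell_perfusion(z[j] - 0.5 * dz, z[j] + 0.5 * dz)
        qj = cell_source(z[j] - 0.5 * dz, z[j] + 0.5 * dz)
        ab[1, j] = -(lam_w + lam_e) / dz**2 - bj
        ab[2, j - 1] = lam_w / dz**2
        if j + 1 < n_un:
            ab[0, j + 1] = lam_e / dz**2
        else:
            b_vec[j] -= (lam_e / dz**2) * bc.t_blood
        b_vec[j] += -qj - bj * bc.t_blood

    t_inner = scipy.linalg.solve_banded((1, 1), ab, b_vec)
    temp = np.concatenate([t_inner, [bc.t_blood]])
    if difference_problem:
        return FDTemperature(kind="rise", depths=z, values=temp - bc.t_blood)
    return FDTemperature(kind="absolute", depths=z, values=temp)
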