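"""Normal-incidence plane-wave solver for a stratified absorbing stack.

Conventions
-----------
Time convention ``e^{+j omega t}``, permittivity ``eps* = eps' - j eps''``,
refractive index ``n = sqrt(eps*)`` on the principal branch (Re n > 0,
Im n <= 0), so a forward wave ``e^{-j k z}`` decays with depth.  Depth
``z = 0`` at the air/tissue interface, increasing into the tissue; each
layer additionally carries a local coordinate ``z_i in [0, h_i]``.

The field in every layer is the sum of a forward and a backward wave.  The
backward amplitudes follow from the cascade (total) reflection
coefficients, computed by the inward-to-outward recursion

    R_i = (r_i + R_{i+1} p) / (1 + r_i R_{i+1} p),  p = e^{-2 j k_{i+1} h_{i+1}}

seeded at the deepest interface with its elementary Fresnel coefficient
(the terminal layer is reflection-free).  Forward amplitudes follow from
field continuity across each interface.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import constants
from .tissue_model import ComplexPermittivity, TissueLayer, TissueStack

__all__ = [
    "PlaneWaveExposure",
    "LayerFields",
    "FieldSolution",
    "EMResult",
    "complex_wavenumber",
    "elementary_reflection",
    "cascade_reflection",
    "solve_fields",
    "field_profile",
    "transmission_coefficient",
    "absorbed_power_density",
    "sar_at",
    "layer_power_fractions",
    "penetration_depth",
    "no_reflection_peak_sar",
    "analyze",
]


@dataclass(frozen=True)
class PlaneWaveExposure:
    """Normally incident TEM plane wave."""

    frequency: float  # Hz
    incident_power_density: float = 10.0  # W m^-2

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.incident_power_density < 0:
            raise ValueError("incident power density must be >= 0")

    @property
    def incident_field_amplitude(self) -> float:
        """|E0+| from IPD = |E0+|^2 / (2 eta0), V m^-1."""
        return math.sqrt(
            2.0 * constants.FREE_SPACE_IMPEDANCE * self.incident_power_density
        )


def complex_wavenumber(frequency: float, eps: ComplexPermittivity | complex) -> complex:
    """k = (2 pi f / c) * sqrt(eps*), principal branch, rad m^-1."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    eps_c = eps.as_complex if isinstance(eps, ComplexPermittivity) else complex(eps)
    k0 = 2.0 * math.pi * frequency / constants.SPEED_OF_LIGHT
    return k0 * cmath.sqrt(eps_c)


def elementary_reflection(n_upper: complex, n_lower: complex) -> complex:
    """Fresnel amplitude reflection (n_upper - n_lower) / (n_upper + n_lower)."""
    denom = n_upper + n_lower
    if denom == 0:
        raise ZeroDivisionError("degenerate interface: n_upper + n_lower = 0")
    return (n_upper - n_lower) / denom


def _em_layers(stack: TissueStack | Sequence[TissueLayer]) -> tuple[TissueLayer, ...]:
    layers = tuple(stack.em_view if isinstance(stack, TissueStack) else stack)
    if not layers or not layers[-1].is_semi_infinite:
        raise ValueError("stack must end in a semi-infinite layer")
    return layers


@dataclass(frozen=True)
class LayerFields:
    """Per-layer wave solution, amplitudes relative to the incident E0+."""

    name: str
    z_top: float  # global depth of layer top, m
    thickness: float  # m (inf for terminal)
    k: complex  # rad m^-1
    forward: complex  # forward amplitude at layer top
    backward: complex  # backward amplitude referenced to layer top
    gamma: complex  # cascade reflection at the layer's bottom interface
    sigma: float  # S m^-1
    density: float  # kg m^-3

    def field(self, z_local):
        """Total E / E0+ at local depth(s) z_local in [0, thickness]."""
        z = np.asarray(z_local, dtype=float)
        return self.forward * np.exp(-1j * self.k * z) + self.backward * np.exp(
            1j * self.k * z
        )

    def poynting_raw(self, z_local):
        """Re[k* (E_f + E_b)(E_f - E_b)*]; divide by k0 Re(n_inc) for S/IPD."""
        z = np.asarray(z_local, dtype=float)
        e_f = self.forward * np.exp(-1j * self.k * z)
        e_b = self.backward * np.exp(1j * self.k * z)
        return np.real(np.conj(self.k) * (e_f + e_b) * np.conj(e_f - e_b))


@dataclass(frozen=True)
class FieldSolution:
    """Full multilayer field solution for one stack and frequency."""

    frequency: float
    layers: tuple[LayerFields, ...]
    r0: complex  # cascade reflection seen from the incident medium
    elementary: tuple[complex, ...]  # per-interface Fresnel coefficients
    incident_index: complex  # refractive index of the incident half-space

    @property
    def k0(self) -> float:
        return 2.0 * math.pi * self.frequency / constants.SPEED_OF_LIGHT

    def locate(self, depth: float) -> tuple[LayerFields, float]:
        """Layer containing a global depth, and the local coordinate."""
        if depth < 0:
            raise ValueError("depth must be >= 0 (into tissue)")
        for lf in self.layers[:-1]:
            if depth <= lf.z_top + lf.thickness:
                return lf, depth - lf.z_top
        last = self.layers[-1]
        return last, depth - last.z_top

    def field_at(self, depth) -> np.ndarray | complex:
        """Total E(z)/E0+ at global depth(s)."""
        depths = np.atleast_1d(np.asarray(depth, dtype=float))
        out = np.empty(depths.shape, dtype=complex)
        for i, z in enumerate(depths):
            lf, zloc = self.locate(float(z))
            out[i] = lf.field(zloc)
        return out if np.ndim(depth) else complex(out[0])

    def poynting_at(self, layer_index: int, z_local: float) -> float:
        """Normalised time-averaged Poynting flux S/IPD inside a layer."""
        raw = self.layers[layer_index].poynting_raw(z_local)
        return float(raw) / (self.k0 * self.incident_index.real)


def solve_fields(
    stack: TissueStack | Sequence[TissueLayer],
    frequency: float,
    *,
    incident_eps: ComplexPermittivity | complex | None = None,
) -> FieldSolution:
    """Solve the stratified-medium problem; amplitudes relative to E0+.

    ``incident_eps`` replaces the incident half-space (air by default),
    which is how the no-reflection condition is constructed.
    """
    layers = _em_layers(stack)
    n_layers = len(layers)
    k0 = 2.0 * math.pi * frequency / constants.SPEED_OF_LIGHT

    if incident_eps is None:
        n_inc = 1.0 + 0.0j
    else:
        eps_c = (
            incident_eps.as_complex
            if isinstance(incident_eps, ComplexPermittivity)
            else complex(incident_eps)
        )
        n_inc = cmath.sqrt(eps_c)

    eps_list = [l.eps_at(frequency) for l in layers]
    # media 0..n_layers: incident half-space then the tissue layers
    n = [n_inc] + [cmath.sqrt(e.as_complex) for e in eps_list]
    k = [k0 * ni for ni in n]
    h = [0.0] + [l.thickness for l in layers]

    # interface i sits between media i and i+1
    r = [elementary_reflection(n[i], n[i + 1]) for i in range(n_layers)]

    gamma = [0j] * n_layers
    gamma[-1] = r[-1]
    for i in range(n_layers - 2, -1, -1):
        p = cmath.exp(-2j * k[i + 1] * h[i + 1])
        gamma[i] = (r[i] + gamma[i + 1] * p) / (1 + r[i] * gamma[i + 1] * p)

    # forward amplitudes at each medium's top, from field continuity.
    # In medium j the backward/forward ratio at the top is
    # gamma[j] * exp(-2j k_j h_j) (zero in the terminal medium).
    forward = [1.0 + 0j]
    for j in range(n_layers):
        if j == 0:
            upper = forward[0] * (1 + gamma[0])
        else:
            upper = forward[j] * cmath.exp(-1j * k[j] * h[j]) * (1 + gamma[j])
        if j + 1 < n_layers:
            g_next = gamma[j + 1] * cmath.exp(-2j * k[j + 1] * h[j + 1])
        else:
            g_next = 0j
        forward.append(upper / (1 + g_next))

    layer_fields = []
    z_top = 0.0
    for idx, layer in enumerate(layers):
        j = idx + 1  # medium index
        if idx < n_layers - 1:
            backward = forward[j] * gamma[j] * cmath.exp(-2j * k[j] * h[j])
            g_bottom = gamma[j]
        else:
            backward = 0j
            g_bottom = 0j
        layer_fields.append(
            LayerFields(
                name=layer.name,
                z_top=z_top,
                thickness=layer.thickness,
                k=k[j],
                forward=forward[j],
                backward=backward,
                gamma=g_bottom,
                sigma=eps_list[idx].conductivity(frequency),
                density=layer.density,
            )
        )
        z_top += layer.thickness
    return FieldSolution(
        frequency=frequency,
        layers=tuple(layer_fields),
        r0=gamma[0],
        elementary=tuple(r),
        incident_index=n_inc,
    )


def cascade_reflection(
    stack: TissueStack | Sequence[TissueLayer],
    frequency: float,
    *,
    incident_eps: ComplexPermittivity | complex | None = None,
) -> tuple[complex, ...]:
    """Cascade (total) reflection coefficients at every interface.

    Element 0 is the reflection seen from the incident medium; the last
    element equals the deepest interface's elementary Fresnel coefficient.
    """
    sol = solve_fields(stack, frequency, incident_eps=incident_eps)
    return (sol.r0,) + tuple(lf.gamma for lf in sol.layers[:-1])


def field_profile(
    stack: TissueStack | Sequence[TissueLayer],
    frequency: float,
    exposure: PlaneWaveExposure | None,
    depth,
) -> np.ndarray | complex:
    """Total electric field at global depth(s), relative to E0+, or in
    V m^-1 when an exposure is given."""
    sol = solve_fields(stack, frequency)
    rel = sol.field_at(depth)
    if exposure is None:
        return rel
    return rel * exposure.incident_field_amplitude


def transmission_coefficient(
    stack: TissueStack | Sequence[TissueLayer],
    frequency: float,
    *,
    incident_eps: ComplexPermittivity | complex | None = None,
) -> float:
    """Power transmission coefficient TC = 1 - |R0|^2."""
    sol = solve_fields(stack, frequency, incident_eps=incident_eps)
    return 1.0 - abs(sol.r0) ** 2


def absorbed_power_density(tc: float, ipd: float) -> float:
    """APD = TC * IPD, W m^-2 (power crossing the air/skin interface)."""
    if not (0.0 <= tc <= 1.0):
        raise ValueError(f"transmission coefficient must lie in [0, 1], got {tc}")
    if ipd < 0:
        raise ValueError("incident power density must be >= 0")
    return tc * ipd


def sar_at(
    stack: TissueStack | Sequence[TissueLayer],
    frequency: float,
    exposure: PlaneWaveExposure,
    depth,
    *,
    solution: FieldSolution | None = None,
) -> np.ndarray | float:
    """SAR(z) = sigma |E(z)|^2 / (2 rho), W kg^-1 (|E| is peak amplitude,
    so E_rms^2 = |E|^2 / 2)."""
    sol = solution if solution is not None else solve_fields(stack, frequency)
    e0 = exposure.incident_field_amplitude
    depths = np.atleast_1d(np.asarray(depth, dtype=float))
    out = np.empty(depths.shape)
    for i, z in enumerate(depths):
        lf, zloc = sol.locate(float(z))
        out[i] = lf.sigma * abs(lf.field(zloc)) ** 2 * e0**2 / (2.0 * lf.density)
    return out if np.ndim(depth) else float(out[0])


def _terminal_span(lf: LayerFields) -> float:
    """Depth span sampled in the terminal layer (3 field decay lengths)."""
    decay = -lf.k.imag
    return 3.0 / decay if decay > 0 else 5e-3


def layer_power_fractions(
    stack: TissueStack | Sequence[TissueLayer],
    frequency: float,
    *,
    solution: FieldSolution | None = None,
) -> dict[str, float]:
    """Fraction of the power entering the tissue absorbed in each layer.

    Computed from the time-averaged Poynting flux difference across each
    finite layer; the terminal layer takes the residual flux (all power
    reaching it is dissipated there).  Fractions sum to one by telescoping.
    """
    sol = solution if solution is not None else solve_fields(stack, frequency)
    s_top = [sol.poynting_at(i, 0.0) for i in range(len(sol.layers))]
    s_in = s_top[0]
    if s_in <= 0:
        raise ValueError("no power enters the tissue")
    fractions: dict[str, float] = {}
    for i, lf in enumerate(sol.layers[:-1]):
        fractions[lf.name] = (s_top[i] - s_top[i + 1]) / s_in
    fractions[sol.layers[-1].name] = s_top[-1] / s_in
    return fractions


def penetration_depth(eps: ComplexPermittivity, frequency: float) -> float:
    """Amplitude 1/e penetration depth 1/(k0 |Im n|), m.

    Returns ``math.inf`` for a lossless medium.
    """
    n = cmath.sqrt(eps.as_complex)
    k0 = 2.0 * math.pi * frequency / constants.SPEED_OF_LIGHT
    if n.imag == 0.0:
        return math.inf
    return 1.0 / (k0 * abs(n.imag))


@dataclass(frozen=True)
class EMResult:
    """Summary of the electromagnetic solution for one stack/exposure."""

    frequency: float
    incident_power_density: float
    transmission_coefficient: float
    absorbed_power_density: float
    peak_sar: float  # W kg^-1
    peak_sar_depth: float  # m
    layer_fractions: dict[str, float]
    sar_depths: np.ndarray  # m
    sar_values: np.ndarray  # W kg^-1
    e_abs: np.ndarray  # |E| at sar_depths, V m^-1
    solution: FieldSolution

    def profile_frame(self):
        """Tidy per-depth profile (depth_m, E_abs, SAR_W_per_kg)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "depth_m": self.sar_depths,
                "E_abs": self.e_abs,
                "SAR_W_per_kg": self.sar_values,
            }
        )

    def summary_dict(self) -> dict:
        return {
            "tc": self.transmission_coefficient,
            "apd_W_m2": self.absorbed_power_density,
            "peak_sar": self.peak_sar,
            "peak_sar_depth_m": self.peak_sar_depth,
            "fractions": dict(self.layer_fractions),
        }


def analyze(
    stack: TissueStack | Sequence[TissueLayer],
    exposure: PlaneWaveExposure,
    *,
    grid_step: float = 1e-6,
    incident_eps: ComplexPermittivity | complex | None = None,
) -> EMResult:
    """Full EM characterisation: TC, APD, SAR profile, peak, layer budget.

    The SAR profile is sampled on a ``grid_step`` grid within each layer
    (interfaces included on both sides); with monotone decay inside lossy
    layers the global peak lies at an interface, and the grid guards
    against standing-wave maxima in low-loss layers.
    """
    sol = solve_fields(stack, exposure.frequency, incident_eps=incident_eps)
    e0 = exposure.incident_field_amplitude
    tc = 1.0 - abs(sol.r0) ** 2

    depths_all, sar_all, eabs_all = [], [], []
    peak, peak_z = 0.0, 0.0
    for lf in sol.layers:
        h = _terminal_span(lf) if math.isinf(lf.thickness) else lf.thickness
        n_pts = min(max(int(round(h / grid_step)) + 1, 9), 20001)
        z = np.linspace(0.0, h, n_pts)
        e_abs = np.abs(lf.field(z)) * e0
        s = lf.sigma * e_abs**2 / (2.0 * lf.density)
        depths_all.append(z + lf.z_top)
        sar_all.append(s)
        eabs_all.append(e_abs)
        i_max = int(np.argmax(s))
        if s[i_max] > peak:
            peak, peak_z = float(s[i_max]), float(z[i_max] + lf.z_top)

    fractions = layer_power_fractions(stack, exposure.frequency, solution=sol)
    return EMResult(
        frequency=exposure.frequency,
        incident_power_density=exposure.incident_power_density,
        transmission_coefficient=tc,
        absorbed_power_density=tc * exposure.incident_power_density,
        peak_sar=peak,
        peak_sar_depth=peak_z,
        layer_fractions=fractions,
        sar_depths=np.concatenate(depths_all),
        sar_values=np.concatenate(sar_all),
        e_abs=np.concatenate(eabs_all),
        solution=sol,
    )


def no_reflection_peak_sar(
    stack: TissueStack | Sequence[TissueLayer],
    frequency: float,
    exposure: PlaneWaveExposure,
    *,
    grid_step: float = 1e-6,
) -> float:
    """Peak SAR with the air/skin mismatch removed, normalised.

    The incident half-space is assigned the ED (skin) permittivity so that
    essentially no reflection occurs at the surface; the returned value is
    the resulting peak SAR divided by the with-reflection peak.
    """
    layers = _em_layers(stack)
    ed = next(
        (l for l in layers if l.name in ("ED", "skin")),
        layers[min(1, len(layers) - 1)],
    )
    with_refl = analyze(stack, exposure, grid_step=grid_step)
    no_refl = analyze(
        stack, exposure, grid_step=grid_step, incident_eps=ed.eps_at(frequency)
    )
    return no_refl.peak_sar / with_refl.peak_sar
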