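"""Tissue dielectric/thermal parameters and their dependence on age.

The near-surface tissue model is a planar stack of stratum corneum (SC),
viable epidermis + dermis (treated as a single electromagnetic layer, ED,
because the two sublayers have nearly identical water content), subcutaneous
fat, and a semi-infinite muscle layer.  For the thermal problem the ED layer
is split into a non-perfused viable epidermis and a perfused dermis.

Ageing enters through three physiological drivers:

* hydration — tissue water content, summarised by the hydration rate
  ``alpha = TBW * rho`` (total body water in L/kg times tissue density in
  g/cm^3), drives the complex permittivity through the Lichtenecker
  logarithmic mixing law;
* skin thickness — the ED layer thins/thickens with age while the ~15 um SC
  is age-invariant;
* dermal blood flow — declines linearly with age, reducing the skin's
  ability to carry heat away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import constants

__all__ = [
    "ComplexPermittivity",
    "TissueLayer",
    "TissueStack",
    "AgeProfile",
    "TISSUE_TABLE",
    "hydration_rate",
    "age_permittivity",
    "blood_flow_dermis",
    "perfusion_coefficient",
    "build_adult_stack",
    "build_age_stack",
]


@dataclass(frozen=True)
class ComplexPermittivity:
    """Relative complex permittivity eps* = eps' - j eps''.

    ``eps_imag`` is stored positive; the physical quantity carries the minus
    sign under the e^{+j omega t} time convention.
    """

    eps_real: float
    eps_imag: float

    def __post_init__(self) -> None:
        if self.eps_real <= 0:
            raise ValueError(f"eps_real must be positive, got {self.eps_real}")
        if self.eps_imag < 0:
            raise ValueError(f"eps_imag must be non-negative, got {self.eps_imag}")

    @property
    def as_complex(self) -> complex:
        return complex(self.eps_real, -self.eps_imag)

    @property
    def loss_tangent(self) -> float:
        return self.eps_imag / self.eps_real

    def conductivity(self, frequency: float) -> float:
        """Equivalent conductivity sigma = 2 pi f eps0 eps'', S m^-1."""
        return 2.0 * math.pi * frequency * constants.VACUUM_PERMITTIVITY * self.eps_imag

    @classmethod
    def from_complex(cls, value: complex) -> "ComplexPermittivity":
        return cls(value.real, -value.imag)


@dataclass(frozen=True)
class TissueLayer:
    """One stratum of the planar tissue model.

    ``thickness`` is in metres; ``math.inf`` marks the terminal
    (semi-infinite) layer.  ``permittivity`` maps frequency (Hz) to
    :class:`ComplexPermittivity`.  ``perfusion`` is the Pennes coefficient
    B = BF * rho_b * C_b in W m^-3 degC^-1.
    """

    name: str
    thickness: float
    permittivity: Mapping[float, ComplexPermittivity]
    thermal_conductivity: float = math.nan
    density: float = math.nan
    perfusion: float = 0.0

    def __post_init__(self) -> None:
        if not (self.thickness > 0):
            raise ValueError(f"layer {self.name!r}: thickness must be positive")
        if self.perfusion < 0:
            raise ValueError(f"layer {self.name!r}: perfusion must be >= 0")

    @property
    def is_semi_infinite(self) -> bool:
        return math.isinf(self.thickness)

    def eps_at(self, frequency: float) -> ComplexPermittivity:
        try:
            return self.permittivity[frequency]
        except KeyError:
            raise KeyError(
                f"layer {self.name!r} has no permittivity tabulated at "
                f"{frequency / 1e9:g} GHz"
            ) from None


def _check_terminal(layers: Sequence[TissueLayer], label: str) -> None:
    if not layers:
        raise ValueError(f"{label} is empty")
    if not layers[-1].is_semi_infinite:
        raise ValueError(f"{label} must end in a semi-infinite layer")
    if any(l.is_semi_infinite for l in layers[:-1]):
        raise ValueError(f"{label} has a semi-infinite layer before the last")


@dataclass(frozen=True)
class TissueStack:
    """Paired electromagnetic (4-layer) and thermal (5-layer) views.

    Both views describe the same physical column: the EM view merges viable
    epidermis and dermis into one ED layer; the thermal view keeps them
    separate because only the dermis is perfused.
    """

    em_view: tuple[TissueLayer, ...]
    thermal_view: tuple[TissueLayer, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "em_view", tuple(self.em_view))
        object.__setattr__(self, "thermal_view", tuple(self.thermal_view))
        _check_terminal(self.em_view, "em_view")
        if self.thermal_view:
            _check_terminal(self.thermal_view, "thermal_view")
            em_finite = sum(l.thickness for l in self.em_view[:-1])
            th_finite = sum(l.thickness for l in self.thermal_view[:-1])
            if not math.isclose(em_finite, th_finite, rel_tol=1e-12, abs_tol=1e-15):
                raise ValueError(
                    "EM and thermal views disagree on total finite depth: "
                    f"{em_finite} vs {th_finite} m"
                )


@dataclass(frozen=True)
class AgeProfile:
    """Age-dependent scalar inputs for one individual/age."""

    age: float
    tbw: float  # total body water, L kg^-1 (numerically the mass fraction)
    skin_thickness: float  # ED total thickness, mm
    blood_flow_dermis: float  # s^-1

    def __post_init__(self) -> None:
        if not (0.0 < self.tbw < 1.0):
            raise ValueError(f"tbw must lie in (0, 1), got {self.tbw}")
        if self.skin_thickness <= 0:
            raise ValueError("skin_thickness must be positive")
        if self.blood_flow_dermis < 0:
            raise ValueError("blood_flow_dermis must be >= 0")


# ---------------------------------------------------------------------------
# Tabulated adult tissue parameters (typical middle-aged male, forearm).
# Permittivities per frequency; thickness in mm; lambda W m^-1 degC^-1;
# rho kg m^-3; perfusion W m^-3 degC^-1 ("dermis" resolved from the
# blood-flow regression at build time).
# ---------------------------------------------------------------------------
TISSUE_TABLE: dict[str, dict] = {
    "SC": {
        "eps": {26e9: (3.62, 0.74), 60e9: (3.15, 0.50)},
        "thickness_mm": 0.015,
        "lambda": 0.37,
        "rho": 1500.0,
        "perfusion": 0.0,
    },
    "ED": {
        "eps": {26e9: (17.71, 16.87), 60e9: (7.98, 10.90)},
        "thickness_mm": 1.396,
        "lambda": 0.37,
        "rho": 1109.0,
        "perfusion": "dermis_age",
    },
    "fat": {
        "eps": {26e9: (3.76, 1.10), 60e9: (3.13, 0.84)},
        "thickness_mm": 4.0,
        "lambda": 0.21,
        "rho": 911.0,
        "perfusion": 1900.0,
    },
    "muscle": {
        "eps": {26e9: (25.85, 21.84), 60e9: (12.86, 15.83)},
        "thickness_mm": math.inf,
        "lambda": 0.49,
        "rho": 1090.0,
        "perfusion": 2550.0,
    },
}

#: Default thickness of the non-perfused viable-epidermis sublayer (mm) used
#: when splitting ED for the thermal view.  The alternative
#: ``literal_table_split`` assigns 1.396 mm to the viable epidermis and
#: 0.060 mm to the dermis, which puts the blood supply in an anatomically
#: implausible 60 um sliver; the default treats 0.060 mm as the viable
#: epidermis instead.
VIABLE_EPIDERMIS_MM = 0.060


def hydration_rate(tbw: float, density: float) -> float:
    """Hydration rate alpha = TBW * rho.

    Parameters
    ----------
    tbw : total body water, L kg^-1 (numerically the body-water mass
        fraction).
    density : tissue mass density in g cm^-3, so that alpha is
        dimensionless.
    """
    if tbw < 0:
        raise ValueError(f"tbw must be >= 0, got {tbw}")
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    alpha = tbw * density
    if alpha >= 1.0:
        raise ValueError(
            f"unphysical hydration rate alpha = {alpha:.4f} >= 1 "
            f"(tbw={tbw}, density={density} g/cm^3)"
        )
    return alpha


def age_permittivity(
    eps_adult: ComplexPermittivity,
    eps_water_real: float,
    alpha: float,
    alpha_adult: float,
) -> ComplexPermittivity:
    """Rescale an adult tissue permittivity to a different hydration rate.

    Lichtenecker's logarithmic mixing law gives
    ``eps' = eps'_W**alpha * eps'_T**(1-alpha)`` with the (unknown) organic
    permittivity eliminated using the adult value, leading to

        eps* = eps'_W**((alpha-alpha_A)/(1-alpha_A))
               * eps'_A**((1-alpha)/(1-alpha_A)) * (1 - j eps''_A/eps'_A)

    The loss tangent is age-invariant by construction (sigma/(eps' eps0)
    does not depend on age), so the output inherits the adult loss tangent
    exactly.
    """
    if not (0.0 < alpha_adult < 1.0):
        raise ValueError(f"alpha_adult must lie in (0, 1), got {alpha_adult}")
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    if eps_water_real <= 0:
        raise ValueError("eps_water_real must be positive")
    exponent = (alpha - alpha_adult) / (1.0 - alpha_adult)
    eps_real = eps_water_real**exponent * eps_adult.eps_real ** (
        (1.0 - alpha) / (1.0 - alpha_adult)
    )
    return ComplexPermittivity(eps_real, eps_real * eps_adult.loss_tangent)


def blood_flow_dermis(age: float) -> float:
    """Dermal volumetric blood-flow rate BF_D(age), s^-1.

    Linear regression on measured forearm skin blood flow at rest; the
    forearm is among the least perfused body sites, so the resulting heating
    is a worst case.
    """
    if not (0.0 <= age <= 120.0):
        raise ValueError(f"age {age} outside the supported range [0, 120] years")
    bf = constants.BLOOD_FLOW_INTERCEPT - age * constants.BLOOD_FLOW_SLOPE
    if bf < 0:
        raise ValueError(f"regression yields negative blood flow at age {age}")
    return bf


def perfusion_coefficient(bf: float) -> float:
    """Pennes perfusion coefficient B = BF * rho_b * C_b, W m^-3 degC^-1."""
    if bf < 0:
        raise ValueError(f"blood flow must be >= 0, got {bf}")
    return bf * constants.BLOOD_DENSITY * constants.BLOOD_HEAT_CAPACITY


def _layer_eps(entry: dict) -> dict[float, ComplexPermittivity]:
    return {f: ComplexPermittivity(re, im) for f, (re, im) in entry["eps"].items()}


def _assemble_stack(
    frequency: float,
    ed_thickness_mm: float,
    eps_by_tissue: Mapping[str, ComplexPermittivity],
    dermal_perfusion: float,
    literal_table_split: bool = False,
) -> TissueStack:
    """Build the paired EM/thermal stack from resolved per-tissue inputs."""
    mm = 1e-3

    def layer(name: str, thickness_m: float, eps: ComplexPermittivity,
              perfusion: float, rho: float | None = None) -> TissueLayer:
        entry = TISSUE_TABLE[name if name in TISSUE_TABLE else "ED"]
        return TissueLayer(
            name=name,
            thickness=thickness_m,
            permittivity={frequency: eps},
            thermal_conductivity=entry["lambda"],
            density=rho if rho is not None else entry["rho"],
            perfusion=perfusion,
        )

    em = (
        layer("SC", TISSUE_TABLE["SC"]["thickness_mm"] * mm, eps_by_tissue["SC"], 0.0,
              TISSUE_TABLE["SC"]["rho"]),
        layer("ED", ed_thickness_mm * mm, eps_by_tissue["ED"], dermal_perfusion),
        layer("fat", TISSUE_TABLE["fat"]["thickness_mm"] * mm, eps_by_tissue["fat"],
              TISSUE_TABLE["fat"]["perfusion"], TISSUE_TABLE["fat"]["rho"]),
        layer("muscle", math.inf, eps_by_tissue["muscle"],
              TISSUE_TABLE["muscle"]["perfusion"], TISSUE_TABLE["muscle"]["rho"]),
    )

    ve_mm = min(VIABLE_EPIDERMIS_MM, 0.5 * ed_thickness_mm)
    if literal_table_split:
        # Literal table reading: thick non-perfused "viable epidermis",
        # 60 um perfused dermis at the bottom of ED.
        dermis_mm = min(0.060, 0.5 * ed_thickness_mm)
        ve_mm = ed_thickness_mm - dermis_mm
    dermis_mm = ed_thickness_mm - ve_mm

    thermal = (
        em[0],
        layer("viable_epidermis", ve_mm * mm, eps_by_tissue["ED"], 0.0),
        layer("dermis", dermis_mm * mm, eps_by_tissue["ED"], dermal_perfusion),
        em[2],
        em[3],
    )
    return TissueStack(em_view=em, thermal_view=thermal)


def build_adult_stack(
    frequency: float,
    *,
    reference_age: float = constants.ADULT_REFERENCE_AGE,
    literal_table_split: bool = False,
) -> TissueStack:
    """Tissue stack with the tabulated adult (middle-aged) parameters.

    Built-in permittivities exist at 26 and 60 GHz; other frequencies
    require user-supplied permittivities via :func:`build_age_stack`
    overrides.
    """
    if frequency not in TISSUE_TABLE["SC"]["eps"]:
        raise ValueError(
            f"no built-in permittivities at {frequency / 1e9:g} GHz; "
            "supported: 26 GHz and 60 GHz"
        )
    eps = {name: _layer_eps(entry)[frequency] for name, entry in TISSUE_TABLE.items()}
    dermal_b = perfusion_coefficient(blood_flow_dermis(reference_age))
    return _assemble_stack(
        frequency,
        TISSUE_TABLE["ED"]["thickness_mm"],
        eps,
        dermal_b,
        literal_table_split=literal_table_split,
    )


def build_age_stack(
    age: float,
    frequency: float,
    age_tables: Mapping[str, object],
    *,
    eps_water_real: float | None = None,
    reference_age: float = constants.ADULT_REFERENCE_AGE,
    vary_thickness: bool = True,
    vary_permittivity: bool = True,
    vary_blood_flow: bool = True,
    tbw_override: float | None = None,
    skin_thickness_override_mm: float | None = None,
    literal_table_split: bool = False,
) -> TissueStack:
    """Tissue stack for a given age.

    ED, fat and muscle permittivities are rescaled through the hydration
    model using the whole-body TBW curve and each tissue's own density; the
    SC permittivity is age-invariant (it is governed by environment, not
    hydration).  The ED thickness follows the age skin-thickness table (the
    15 um SC is constant and additional); dermal perfusion follows the
    blood-flow regression.

    ``vary_*`` toggles pin individual factors to their adult reference
    values, which is how single-factor scenarios are built.  Overrides allow
    Monte Carlo sampling of individual inputs.

    ``age_tables`` maps ``"skin_thickness_mm"`` and ``"tbw"`` to objects
    with a ``mean(age)`` method (see :mod:`agederm.synthetic_data`).
    """
    if eps_water_real is None:
        try:
            eps_water_real = constants.WATER_EPS_REAL[frequency]
        except KeyError:
            raise ValueError(
                f"no built-in water permittivity at {frequency / 1e9:g} GHz; "
                "pass eps_water_real explicitly"
            ) from None

    thickness_age = age if vary_thickness else reference_age
    if skin_thickness_override_mm is not None:
        ed_mm = skin_thickness_override_mm
    elif vary_thickness:
        ed_mm = float(age_tables["skin_thickness_mm"].mean(thickness_age))
    else:
        ed_mm = TISSUE_TABLE["ED"]["thickness_mm"]

    eps: dict[str, ComplexPermittivity] = {
        "SC": _layer_eps(TISSUE_TABLE["SC"])[frequency]
    }
    if vary_permittivity:
        tbw = tbw_override if tbw_override is not None else float(
            age_tables["tbw"].mean(age)
        )
        tbw_adult = float(age_tables["tbw"].mean(reference_age))
        for name in ("ED", "fat", "muscle"):
            rho_gcc = TISSUE_TABLE[name]["rho"] / 1000.0
            eps[name] = age_permittivity(
                _layer_eps(TISSUE_TABLE[name])[frequency],
                eps_water_real,
                hydration_rate(tbw, rho_gcc),
                hydration_rate(tbw_adult, rho_gcc),
            )
    else:
        for name in ("ED", "fat", "muscle"):
            eps[name] = _layer_eps(TISSUE_TABLE[name])[frequency]

    bf_age = age if vary_blood_flow else reference_age
    dermal_b = perfusion_coefficient(blood_flow_dermis(bf_age))

    return _assemble_stack(
        frequency, ed_mm, eps, dermal_b, literal_table_split=literal_table_split
    )
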