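"""Synthetic age-dependent input tables and inter-individual sampling.

The analysis needs three age curves that in practice come from published
anthropometric measurements: forearm skin (ED) thickness, total body water
(TBW, body-water mass fraction), and body weight.  This module generates
tables with the qualitative structure those literature curves share --
growth through youth, a mid-adult plateau, and late-life change -- plus a
per-age Gaussian inter-individual spread for Monte Carlo use.  The default
fixture is synthetic: apart from the 1.396 mm mid-adult skin thickness (a
typical middle-aged male value) and the adult tie-point of the hydration
model, its numbers are calibration-free placeholders, not measured data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, interp1d

__all__ = [
    "AgeParameterTable",
    "make_age_tables",
    "sample_individual",
    "default_fixture",
]

#: Physical truncation bounds per parameter for Gaussian sampling.
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "skin_thickness_mm": (0.1, math.inf),
    "tbw": (0.05, 0.95),
    "body_weight_kg": (1.0, math.inf),
}

#: Coefficient of variation assumed when a table carries no explicit SD.
DEFAULT_CV = 0.10


@dataclass(frozen=True)
class AgeParameterTable:
    """One age-dependent input parameter with anchors and interpolants.

    The interpolant passes exactly through the anchors and is
    shape-preserving between them (monotone anchor runs stay monotone):
    PCHIP by default, piecewise-linear on request.
    """

    name: str
    ages: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    shape: str = "monotone-spline"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if ages.size < 2:
            raise ValueError(f"{self.name}: need at least 2 anchors")
        if np.any(np.diff(ages) <= 0):
            raise ValueError(f"{self.name}: anchor ages must be strictly increasing")
        if np.any(means <= 0):
            raise ValueError(f"{self.name}: anchor means must be positive")
        if np.any(sds < 0):
            raise ValueError(f"{self.name}: anchor SDs must be >= 0")
        if self.name == "tbw" and np.any((means <= 0) | (means >= 1)):
            raise ValueError("tbw means must lie in (0, 1)")
        if self.shape not in ("monotone-spline", "piecewise-linear"):
            raise ValueError(f"unknown shape {self.shape!r}")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    def _interp(self, values: np.ndarray):
        if self.shape == "piecewise-linear":
            return interp1d(self.ages, values, kind="linear")
        return PchipInterpolator(self.ages, values)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    @property
    def bounds(self) -> tuple[float, float]:
        return PARAMETER_BOUNDS.get(self.name, (0.0, math.inf))

    def _check_domain(self, age) -> None:
        lo, hi = self.domain
        a = np.asarray(age, dtype=float)
        if np.any((a < lo) | (a > hi)):
            raise ValueError(
                f"{self.name}: age {age} outside table domain [{lo:g}, {hi:g}]"
            )

    def mean(self, age):
        self._check_domain(age)
        out = self._interp(self.means)(age)
        return float(out) if np.ndim(age) == 0 else np.asarray(out, dtype=float)

    def sd(self, age):
        self._check_domain(age)
        out = self._interp(self.sds)(age)
        return float(out) if np.ndim(age) == 0 else np.asarray(out, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.name,
                "age": self.ages,
                "mean": self.means,
                "sd": self.sds,
            }
        )


def make_age_tables(
    anchors: Mapping[str, Sequence[tuple[float, float] | tuple[float, float, float]]],
    shape: str = "monotone-spline",
) -> dict[str, AgeParameterTable]:
    """Build parameter tables from ``{name: [(age, mean[, sd]), ...]}``.

    Anchors without an explicit SD get ``DEFAULT_CV`` times the mean.
    """
    tables = {}
    for name, rows in anchors.items():
        ages, means, sds = [], [], []
        for row in rows:
            age, mean = row[0], row[1]
            sd = row[2] if len(row) > 2 else DEFAULT_CV * mean
            ages.append(age)
            means.append(mean)
            sds.append(sd)
        tables[name] = AgeParameterTable(
            name=name,
            ages=np.array(ages),
            means=np.array(means),
            sds=np.array(sds),
            shape=shape,
        )
    return tables


def sample_individual(
    table: AgeParameterTable,
    age: float,
    rng: np.random.Generator | int | None = None,
    *,
    max_rejects: int = 10_000,
) -> float:
    """One Gaussian draw of the parameter at an age, truncated to its
    physical bounds by rejection; reproducible given a seed or Generator."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mu, sd = table.mean(age), table.sd(age)
    if sd == 0:
        return float(mu)
    lo, hi = table.bounds
    for _ in range(max_rejects):
        x = rng.normal(mu, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError(
        f"{table.name}: all {max_rejects} draws rejected by bounds ({lo}, {hi})"
    )


# Synthetic default anchors (see module docstring): rise through youth to
# the 1.396 mm mid-adult skin thickness then slight late-life decline; TBW
# declining with age through the adult tie-point at the reference age.
_DEFAULT_ANCHORS = {
    "skin_thickness_mm": [
        (5, 0.96), (7, 1.02), (12, 1.15), (30, 1.38), (35, 1.396),
        (45, 1.39), (65, 1.33), (70, 1.29),
    ],
    "tbw": [
        (5, 0.620), (7, 0.615), (12, 0.610), (30, 0.602), (35, 0.600),
        (45, 0.585), (65, 0.520), (70, 0.500),
    ],
    "body_weight_kg": [
        (5, 19.0), (7, 23.0), (12, 40.0), (30, 70.0), (35, 72.0),
        (45, 74.0), (65, 70.0), (70, 68.0),
    ],
}


def default_fixture(shape: str = "monotone-spline") -> dict[str, AgeParameterTable]:
    """Synthetic default age tables over ages 5-70.

    The skin-thickness curve passes through 1.396 mm at the adult
    reference age (so the adult stack is recovered there), and the TBW
    curve declines with age so that the hydration rate at the reference
    age equals the adult value alpha_A by construction.
    """
    return make_age_tables(_DEFAULT_ANCHORS, shape=shape)
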