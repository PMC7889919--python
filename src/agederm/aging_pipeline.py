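"""Age sweeps, exposure-limit levels, factor decomposition, Monte Carlo.

Orchestrates the tissue, electromagnetic and thermal models over age:
single-factor scenarios (skin thickness only, permittivity only, blood
flow only) pin the remaining inputs at their adult reference values, so
the age dependence of each physiological driver can be separated; the
combined scenario varies all three.  Inter-individual variability is
propagated by Monte Carlo over Gaussian input distributions at anchor
ages, summarised as the sample mean and the central 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import constants
from .em_solver import PlaneWaveExposure, analyze, no_reflection_peak_sar
from .synthetic_data import AgeParameterTable, sample_individual
from .thermal_solver import ThermalBoundary, temperature_rise
from .tissue_model import build_age_stack

__all__ = [
    "ExposureScenario",
    "SweepResult",
    "UncertaintySpec",
    "MonteCarloSummary",
    "ALL_FACTORS",
    "icnirp_local_limit",
    "resolve_ipd",
    "sweep_age",
    "relative_change",
    "monte_carlo_uncertainty",
    "make_report",
]

ALL_FACTORS = frozenset({"thickness", "permittivity", "blood_flow"})

#: Anchor ages with literature information on all Monte Carlo inputs.
DEFAULT_ANCHOR_AGES = (7.0, 12.0, 30.0, 45.0, 65.0)


def icnirp_local_limit(frequency_ghz: float, population: str = "general") -> float:
    """Local-exposure incident power density limit, W m^-2.

    ``55 f^-0.177`` (general public) or ``275 f^-0.177`` (occupational),
    valid for 6-300 GHz, frequency in GHz.
    """
    lo, hi = constants.ICNIRP_FREQ_RANGE_GHZ
    if not (lo <= frequency_ghz <= hi):
        raise ValueError(
            f"local limits are defined for {lo:g}-{hi:g} GHz, got {frequency_ghz} GHz"
        )
    coeff = {
        "general": constants.ICNIRP_COEFF_GENERAL,
        "occupational": constants.ICNIRP_COEFF_OCCUPATIONAL,
    }.get(population)
    if coeff is None:
        raise ValueError(f"population must be 'general' or 'occupational', got {population!r}")
    return coeff * frequency_ghz**constants.ICNIRP_EXPONENT


@dataclass(frozen=True)
class ExposureScenario:
    """One exposure/factor configuration.

    ``ipd_mode`` is a fixed level in W m^-2 (float) or one of
    ``"icnirp_general"`` / ``"icnirp_occupational"``; ``factors`` lists the
    age-dependent drivers (subset of thickness, permittivity, blood_flow);
    ``no_reflection`` additionally evaluates the peak SAR with the air/skin
    mismatch removed.
    """

    frequency: float  # Hz
    ipd_mode: float | str = 10.0
    factors: frozenset[str] = ALL_FACTORS
    no_reflection: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", frozenset(self.factors))
        unknown = self.factors - ALL_FACTORS
        if unknown:
            raise ValueError(f"unknown factors: {sorted(unknown)}")
        resolve_ipd(self.ipd_mode, self.frequency)  # validate eagerly

    @property
    def ipd(self) -> float:
        return resolve_ipd(self.ipd_mode, self.frequency)


def resolve_ipd(ipd_mode: float | str, frequency: float) -> float:
    """Resolve an IPD specification to W m^-2."""
    if isinstance(ipd_mode, str):
        try:
            population = {"icnirp_general": "general",
                          "icnirp_occupational": "occupational"}[ipd_mode]
        except KeyError:
            raise ValueError(f"unknown ipd_mode {ipd_mode!r}") from None
        return icnirp_local_limit(frequency / 1e9, population)
    if ipd_mode < 0:
        raise ValueError("fixed IPD must be >= 0")
    return float(ipd_mode)


@dataclass(frozen=True)
class SweepResult:
    """Tidy per-age outputs of one scenario."""

    scenario: ExposureScenario
    table: pd.DataFrame  # one row per age

    def __post_init__(self) -> None:
        if not self.table["age"].is_monotonic_increasing:
            raise ValueError("ages must be sorted")
        values = self.table.drop(columns=["age"]).to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite quantity in sweep result")


def _age_outputs(
    age: float,
    scenario: ExposureScenario,
    tables: Mapping[str, AgeParameterTable],
    *,
    bc: ThermalBoundary | None = None,
    with_thermal: bool = True,
    grid_step: float = 1e-6,
    overrides: Mapping[str, float] | None = None,
) -> dict[str, float]:
    overrides = overrides or {}
    stack = build_age_stack(
        age,
        scenario.frequency,
        tables,
        vary_thickness="thickness" in scenario.factors,
        vary_permittivity="permittivity" in scenario.factors,
        vary_blood_flow="blood_flow" in scenario.factors,
        tbw_override=overrides.get("tbw"),
        skin_thickness_override_mm=overrides.get("skin_thickness_mm"),
    )
    exposure = PlaneWaveExposure(scenario.frequency, scenario.ipd)
    em = analyze(stack, exposure, grid_step=grid_step)
    row = {
        "age": age,
        "tc": em.transmission_coefficient,
        "apd_W_m2": em.absorbed_power_density,
        "peak_sar_W_kg": em.peak_sar,
        "peak_sar_depth_m": em.peak_sar_depth,
    }
    for name, frac in em.layer_fractions.items():
        row[f"fraction_{name}"] = frac
    if scenario.no_reflection:
        row["no_reflection_peak_sar_norm"] = no_reflection_peak_sar(
            stack, scenario.frequency, exposure, grid_step=grid_step
        )
    if with_thermal:
        rise = temperature_rise(stack, em, bc)
        peak, depth = rise.peak()
        row["peak_delta_T_C"] = peak
        row["peak_delta_T_depth_m"] = depth
    return row


def sweep_age(
    ages: Sequence[float],
    scenario: ExposureScenario,
    tables: Mapping[str, AgeParameterTable],
    *,
    bc: ThermalBoundary | None = None,
    with_thermal: bool = True,
    grid_step: float = 1e-6,
) -> SweepResult:
    """Run the full pipeline over a list of ages for one scenario.

    Factors not listed in the scenario are pinned to adult reference
    values (1.396 mm ED thickness, tabulated adult permittivities, adult
    blood flow).
    """
    rows = [
        _age_outputs(
            float(age), scenario, tables,
            bc=bc, with_thermal=with_thermal, grid_step=grid_step,
        )
        for age in sorted(float(a) for a in ages)
    ]
    return SweepResult(scenario=scenario, table=pd.DataFrame(rows))


def relative_change(value_young: float, value_old: float) -> float:
    """Percent change 100 * (old - young) / young."""
    if value_young == 0:
        raise ZeroDivisionError("relative change undefined for zero reference")
    return 100.0 * (value_old - value_young) / value_young


@dataclass(frozen=True)
class UncertaintySpec:
    """Monte Carlo inputs: which parameters to sample, where, how often.

    Gaussian per-age input distributions are taken from the parameter
    tables (mean and SD at the anchor age), truncated to physical bounds.
    """

    tables: Mapping[str, AgeParameterTable]
    anchor_ages: tuple[float, ...] = DEFAULT_ANCHOR_AGES
    n_trials: int = 1_000_000
    seed: int | None = None
    include_delta_t: bool = False

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class MonteCarloSummary:
    """Per-quantity mean and central 95% interval at one anchor age."""

    anchor_age: float
    n_trials: int
    stats: pd.DataFrame  # index: quantity; columns: mean, lo95, hi95


def monte_carlo_uncertainty(
    spec: UncertaintySpec,
    scenario: ExposureScenario,
    anchor_age: float,
    *,
    bc: ThermalBoundary | None = None,
    grid_step: float = 5e-6,
) -> MonteCarloSummary:
    """Propagate inter-individual input spread at one anchor age.

    Each trial draws skin thickness, TBW and body weight from their
    truncated Gaussians, rebuilds the stack and recomputes TC, APD and
    peak SAR (optionally the peak temperature rise).  Body weight is
    carried as a sampled input but enters the tissue model only through
    the TBW ratio.  The interval is the central 95% (2.5th-97.5th
    percentiles); results are bit-reproducible given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    quantities = ["tc", "apd_W_m2", "peak_sar_W_kg"]
    if spec.include_delta_t:
        quantities.append("peak_delta_T_C")
    samples = {q: np.empty(spec.n_trials) for q in quantities}
    for t in range(spec.n_trials):
        overrides = {}
        if "skin_thickness_mm" in spec.tables:
            overrides["skin_thickness_mm"] = sample_individual(
                spec.tables["skin_thickness_mm"], anchor_age, rng
            )
        if "tbw" in spec.tables:
            overrides["tbw"] = sample_individual(spec.tables["tbw"], anchor_age, rng)
        if "body_weight_kg" in spec.tables:
            sample_individual(spec.tables["body_weight_kg"], anchor_age, rng)
        row = _age_outputs(
            anchor_age, scenario, spec.tables,
            bc=bc, with_thermal=spec.include_delta_t,
            grid_step=grid_step, overrides=overrides,
        )
        for q in quantities:
            samples[q][t] = row[q]
    stats = pd.DataFrame(
        {
            "mean": {q: float(np.mean(v)) for q, v in samples.items()},
            "lo95": {q: float(np.percentile(v, 2.5)) for q, v in samples.items()},
            "hi95": {q: float(np.percentile(v, 97.5)) for q, v in samples.items()},
        }
    )
    return MonteCarloSummary(anchor_age=anchor_age, n_trials=spec.n_trials, stats=stats)


def make_report(
    results: SweepResult | Sequence[SweepResult],
    uncertainty: Sequence[MonteCarloSummary] | None = None,
    out_dir: str | Path = "report",
    *,
    make_plots: bool = True,
) -> list[Path]:
    """Emit per-scenario CSV tables, layer-fraction percentages, endpoint
    relative changes, Monte Carlo bars, and simple figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sweeps = [results] if isinstance(results, SweepResult) else list(results)

    for i, sw in enumerate(sweeps):
        tag = (
            f"{sw.scenario.frequency / 1e9:g}GHz_"
            + ("-".join(sorted(sw.scenario.factors)) or "none")
        )
        path = out / f"sweep_{tag}.csv"
        sw.table.to_csv(path, index=False)
        written.append(path)

        frac_cols = [c for c in sw.table.columns if c.startswith("fraction_")]
        if frac_cols:
            frac = sw.table[["age"] + frac_cols].copy()
            frac[frac_cols] = 100.0 * frac[frac_cols]
            frac_path = out / f"fractions_percent_{tag}.csv"
            frac.to_csv(frac_path, index=False)
            written.append(frac_path)

        if len(sw.table) >= 2:
            young, old = sw.table.iloc[0], sw.table.iloc[-1]
            changes = {
                col: relative_change(young[col], old[col])
                for col in ("tc", "apd_W_m2", "peak_sar_W_kg", "peak_delta_T_C")
                if col in sw.table.columns and young[col] != 0
            }
            ch_path = out / f"relative_change_{tag}.csv"
            pd.Series(changes, name="percent_change").rename_axis("quantity").to_csv(ch_path)
            written.append(ch_path)

        if make_plots:
            fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
            for ax, col, label in zip(
                axes,
                ("tc", "peak_sar_W_kg", "peak_delta_T_C"),
                ("power transmission coeff.", "peak SAR (W/kg)", "peak ΔT (°C)"),
            ):
                if col in sw.table.columns:
                    ax.plot(sw.table["age"], sw.table[col])
                ax.set_xlabel("age (years)")
                ax.set_ylabel(label)
            fig.suptitle(tag)
            fig.tight_layout()
            fig_path = out / f"sweep_{tag}.png"
            fig.savefig(fig_path, dpi=120)
            plt.close(fig)
            written.append(fig_path)

    if uncertainty:
        rows = []
        for mc in uncertainty:
            df = mc.stats.reset_index(names="quantity")
            df.insert(0, "anchor_age", mc.anchor_age)
            df["n_trials"] = mc.n_trials
            rows.append(df)
        mc_path = out / "monte_carlo.csv"
        pd.concat(rows, ignore_index=True).to_csv(mc_path, index=False)
        written.append(mc_path)
    return written
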