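"""Seeded generators of instrument-like DSC and ITC datasets.

Each generator produces data with the statistical structure the analysis
assumes — additive Gaussian noise on an ideal model curve, optionally a
linear instrumental baseline — together with a ground-truth record, so
every fitter in the package can be exercised end-to-end without any
instrument.  The built-in scenarios cover the three chaperonin variants
(Pf-CD1, the humanized Pf-H, and the pathogenic mutant Pf-R) at their
published central parameter values for thermal denaturation, hexadecamer
dissociation, and ATP binding.

Determinism contract: identical seed + config → bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dsc import Thermogram, dissociative_excess_cp, two_state_excess_cp
from .itc_binding import BindingSystem, TitrationProtocol, simulate_titration
from .itc_dilution import DilutionProtocol, simulate_dilution
from .oligomer import OligomerSystem, critical_transition_concentration
from .series import InjectionSeries
from .thermo import celsius_to_kelvin

__all__ = [
    "GeneratorConfig",
    "DSC_SCENARIOS",
    "DILUTION_SCENARIOS",
    "BINDING_SCENARIOS",
    "make_dsc_dataset",
    "make_dilution_dataset",
    "make_binding_dataset",
    "default_dilution_protocol",
    "default_titration_protocol",
    "DSC_CONC_LADDER_M",
]

# Published central values, per subunit (heat denaturation: midpoint °C,
# calorimetric and van't Hoff enthalpies kcal/mol; uncertainties where given).
DSC_SCENARIOS: dict[str, dict] = {
    "Pf-CD1": {"tm_celsius": 102.6, "delta_h_cal": 515.0, "delta_h_vh": 214.2},
    "Pf-H": {"tm_celsius": 103.2, "delta_h_cal": 308.0, "delta_h_vh": 197.2},
    "Pf-R": {"tm_celsius": 102.7, "delta_h_cal": 182.0, "delta_h_vh": 160.3},
    "Pf-CD1-Mg-ATP": {"tm_celsius": 102.5, "delta_h_cal": 365.0, "delta_h_vh": 239.0},
    "Pf-H-Mg-ATP": {"tm_celsius": 99.6, "delta_h_cal": 518.0, "delta_h_vh": 156.0},
    "Pf-R-Mg-ATP": {"tm_celsius": 99.7, "delta_h_cal": 157.0, "delta_h_vh": 200.0},
}

# Hexadecamer-monomer equilibria: per-subunit kd (M) and dissociation
# enthalpy (kcal/mol subunit), with the published uncertainties.
DILUTION_SCENARIOS: dict[str, dict] = {
    "Pf-CD1": {"kd": 0.31e-6, "kd_err": 0.06e-6, "delta_h_d": -350.0, "dh_err": 5.0},
    "Pf-H": {"kd": 0.43e-6, "kd_err": 0.05e-6, "delta_h_d": -250.0, "dh_err": 7.0},
    "Pf-R": {"kd": 0.10e-6, "kd_err": 0.05e-6, "delta_h_d": -49.0, "dh_err": 1.7},
}

# One-set-of-sites ATP binding, per monomer (sites/subunit, kd M, ΔH kcal/mol
# ligand).  Pf-R uses the tabulated −26.7.
BINDING_SCENARIOS: dict[str, dict] = {
    "Pf-CD1": {"n_sites": 0.93, "n_err": 0.15, "kd": 0.32e-6, "kd_err": 0.05e-6,
               "delta_h": 5.0, "dh_err": 1.5},
    "Pf-H": {"n_sites": 0.95, "n_err": 0.06, "kd": 0.30e-6, "kd_err": 0.02e-6,
             "delta_h": 7.0, "dh_err": 0.7},
    "Pf-R": {"n_sites": 1.16, "n_err": 0.05, "kd": 0.20e-6, "kd_err": 0.01e-6,
             "delta_h": -26.7, "dh_err": 1.3},
}

#: Concentration ladder used for the concentration-dependence scans, mol/L
#: subunit (the published 1.7 / 3.5 / 7 μM series).
DSC_CONC_LADDER_M = (1.7e-6, 3.5e-6, 7.0e-6)


def _check_scenario(name: str, table: dict[str, dict]) -> dict:
    if name not in table:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {sorted(table)}"
        )
    return table[name]


@dataclass(frozen=True)
class GeneratorConfig:
    """Scenario + noise model + seed for one synthetic dataset.

    Noise defaults: DSC σ = 1% of peak height; ITC σ = 1% of the largest
    injection heat plus a 0.1 μcal floor — typical for low-volume
    calorimeters.  ``overrides`` replaces individual scenario parameters
    for custom runs.
    """

    scenario: str = "Pf-CD1"
    seed: int = 0
    dsc_sigma_fraction: float = 0.01
    itc_sigma_fraction: float = 0.01
    itc_sigma_floor_ucal: float = 0.1
    overrides: dict = field(default_factory=dict)


def make_dsc_dataset(
    config: GeneratorConfig,
    model: str = "dissociative",
    n: int = 16,
    total_subunit_conc: float = 7.0e-6,
    grid_celsius: tuple[float, float, float] = (20.0, 125.0, 0.1),
    linear_baseline: tuple[float, float] | None = None,
) -> tuple[Thermogram, dict]:
    """Synthetic DSC scan plus its ground-truth record.

    The default emulates a hexadecamer scan at 7 μM subunit with the
    dissociation-coupled model; ``model="two_state"`` produces the
    monomolecular reference shape.  ``linear_baseline`` (intercept at the
    grid start and slope, both in trace units) adds an instrumental ramp
    for exercising baseline subtraction.
    """
    p = dict(_check_scenario(config.scenario, DSC_SCENARIOS))
    p.update(config.overrides)
    lo, hi, step = grid_celsius
    t = celsius_to_kelvin(np.arange(lo, hi + 0.5 * step, step))
    tm = celsius_to_kelvin(p["tm_celsius"])
    if model == "two_state":
        clean = two_state_excess_cp(tm, p["delta_h_vh"], p["delta_h_cal"], t)
    elif model == "dissociative":
        clean = dissociative_excess_cp(
            n, p["delta_h_vh"], p["delta_h_cal"], tm, total_subunit_conc, t
        )
    else:
        raise ValueError(f"unknown model {model!r}")

    rng = np.random.default_rng(config.seed)
    sigma = config.dsc_sigma_fraction * float(np.max(clean.excess_cp))
    noisy = clean.excess_cp + rng.normal(0.0, sigma, size=t.size)
    if linear_baseline is not None:
        intercept, slope = linear_baseline
        noisy = noisy + intercept + slope * (t - t[0])
    trace = Thermogram(
        temperature=t,
        excess_cp=noisy,
        total_subunit_conc=total_subunit_conc,
        scan_rate=60.0,
        baseline_method=None if linear_baseline is not None else "model+noise",
    )
    truth = {
        "scenario": config.scenario,
        "model": model,
        "n": n,
        "tm_celsius": p["tm_celsius"],
        "delta_h_cal": p["delta_h_cal"],
        "delta_h_vh": p["delta_h_vh"],
        "total_subunit_conc": total_subunit_conc,
        "noise_sigma": sigma,
        "seed": config.seed,
    }
    return trace, truth


def default_dilution_protocol(
    system: OligomerSystem,
    n_injections: int = 18,
    injection_volume: float = 5.0e-6,
    cell_volume: float = 1.0e-3,
) -> DilutionProtocol:
    """Protocol whose cell trajectory crosses the CTC mid-series.

    The syringe concentration is computed (not hard-coded) so that after
    half the injections the cell concentration reaches the system's
    critical transition concentration, which places the sigmoid's
    inflection in the middle of the series where it is most informative.
    """
    ctc = critical_transition_concentration(system)
    d = injection_volume / cell_volume
    reach = 1.0 - (1.0 - d) ** (n_injections // 2)
    return DilutionProtocol(
        syringe_total_subunit_conc=ctc / reach,
        cell_volume=cell_volume,
        injection_volumes=(injection_volume,) * n_injections,
        temperature=system.temperature,
    )


def make_dilution_dataset(
    config: GeneratorConfig,
    n: int = 16,
    protocol: Optional[DilutionProtocol] = None,
) -> tuple[InjectionSeries, DilutionProtocol, dict]:
    """Synthetic 18-injection dilution series with ground truth."""
    p = dict(_check_scenario(config.scenario, DILUTION_SCENARIOS))
    p.update(config.overrides)
    system = OligomerSystem(kd=p["kd"], n=n, delta_h_d=p["delta_h_d"])
    if protocol is None:
        protocol = default_dilution_protocol(system)
    clean = simulate_dilution(system, protocol)
    rng = np.random.default_rng(config.seed)
    sigma = (
        config.itc_sigma_fraction * float(np.max(np.abs(clean.heats_ucal)))
        + config.itc_sigma_floor_ucal
    )
    noisy_heats = clean.heats_ucal + rng.normal(0.0, sigma, size=len(clean))
    series = InjectionSeries(
        heats_ucal=noisy_heats,
        injection_volumes=clean.injection_volumes,
        moles_injected=clean.moles_injected,
        normalized_heat=noisy_heats * 1e-9 / clean.moles_injected,
        cell_conc_after=clean.cell_conc_after,
        kind="dilution",
        meta=dict(clean.meta),
    )
    truth = {
        "scenario": config.scenario,
        "n": n,
        "kd": p["kd"],
        "delta_h_d": p["delta_h_d"],
        "noise_sigma_ucal": sigma,
        "seed": config.seed,
        "syringe_total_subunit_conc": protocol.syringe_total_subunit_conc,
    }
    return series, protocol, truth


def default_titration_protocol(
    system: BindingSystem,
    cell_subunit_conc: float = 5.0e-6,
    n_injections: int = 20,
    injection_volume: float = 5.0e-6,
    cell_volume: float = 1.0e-3,
    final_molar_ratio: float = 2.2,
) -> TitrationProtocol:
    """Ligand-into-protein protocol reaching a target final molar ratio.

    Ratios are ligand per subunit (1 ⇔ 16 per hexadecamer).  The syringe
    concentration is computed so the cumulative ratio at the last
    injection equals ``final_molar_ratio``, comfortably past saturation
    for c-values in the tens.
    """
    d = injection_volume / cell_volume
    shrink = (1.0 - d) ** n_injections
    ligand_reach = 1.0 - shrink  # cell ligand conc = C_syr * ligand_reach
    c_syr = final_molar_ratio * cell_subunit_conc * shrink / ligand_reach
    return TitrationProtocol(
        cell_subunit_conc=cell_subunit_conc,
        syringe_ligand_conc=c_syr,
        cell_volume=cell_volume,
        injection_volumes=(injection_volume,) * n_injections,
        temperature=system.temperature,
    )


def make_binding_dataset(
    config: GeneratorConfig,
    protocol: Optional[TitrationProtocol] = None,
) -> tuple[InjectionSeries, TitrationProtocol, dict]:
    """Synthetic ATP-titration series spanning molar ratio 0 → ~2/subunit."""
    p = dict(_check_scenario(config.scenario, BINDING_SCENARIOS))
    p.update(config.overrides)
    system = BindingSystem(kd=p["kd"], delta_h=p["delta_h"], n_sites=p["n_sites"])
    if protocol is None:
        protocol = default_titration_protocol(system)
    clean = simulate_titration(system, protocol)
    rng = np.random.default_rng(config.seed)
    sigma = (
        config.itc_sigma_fraction * float(np.max(np.abs(clean.heats_ucal)))
        + config.itc_sigma_floor_ucal
    )
    noisy_heats = clean.heats_ucal + rng.normal(0.0, sigma, size=len(clean))
    series = InjectionSeries(
        heats_ucal=noisy_heats,
        injection_volumes=clean.injection_volumes,
        moles_injected=clean.moles_injected,
        normalized_heat=noisy_heats * 1e-9 / clean.moles_injected,
        cell_conc_after=clean.cell_conc_after,
        kind="binding",
        molar_ratio=clean.molar_ratio,
        meta=dict(clean.meta),
    )
    truth = {
        "scenario": config.scenario,
        "n_sites": p["n_sites"],
        "kd": p["kd"],
        "delta_h": p["delta_h"],
        "noise_sigma_ucal": sigma,
        "seed": config.seed,
        "cell_subunit_conc": protocol.cell_subunit_conc,
        "syringe_ligand_conc": protocol.syringe_ligand_conc,
    }
    return series, protocol, truth
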