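"""Binding ITC with the "one set of sites" model.

The chaperonin hexadecamer carries 16 identical, independent nucleotide
sites — one per subunit — so the isotherm is bookkept per subunit: the
site concentration is n_sites × (subunit concentration) and a cumulative
molar ratio of 1 means one ATP per subunit (16 per complex).  Free,
bound and total ligand are related by the single-site quadratic

    L_bound = [ (L_t + S_t + K_d) − sqrt((L_t + S_t + K_d)² − 4·L_t·S_t) ] / 2

evaluated in the cancellation-free form 2·L_t·S_t / (b + sqrt(b² − 4·L_t·S_t)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit

from .result import FitResult
from .series import InjectionSeries
from .thermo import T_REF, entropy_from_enthalpy_gibbs, gibbs_from_kd

__all__ = [
    "BindingSystem",
    "TitrationProtocol",
    "bound_ligand",
    "simulate_titration",
    "fit_one_set_of_sites",
]


@dataclass(frozen=True)
class BindingSystem:
    """Identical-independent-sites ligand binding, normalized per subunit.

    ``n_sites`` is sites per subunit (≈ 1 for one ATP per subunit),
    ``kd`` the per-site dissociation constant (mol/L), ``delta_h`` the
    binding enthalpy in kcal per mol of ligand bound.
    """

    kd: float
    delta_h: float
    n_sites: float = 1.0
    temperature: float = T_REF

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")


@dataclass(frozen=True)
class TitrationProtocol:
    """Ligand-into-protein titration schedule."""

    cell_subunit_conc: float  # mol/L
    syringe_ligand_conc: float  # mol/L
    cell_volume: float = 1.0e-3  # liters
    injection_volumes: tuple[float, ...] = (5.0e-6,) * 20
    temperature: float = T_REF

    def __post_init__(self) -> None:
        if self.cell_subunit_conc <= 0 or self.syringe_ligand_conc <= 0:
            raise ValueError("concentrations must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("all injection volumes must be positive")


def bound_ligand(
    system: BindingSystem, total_ligand: float, total_subunit: float
) -> float:
    """Bound-ligand concentration from the site-conservation quadratic.

    ``total_subunit`` is subunit concentration; the site concentration is
    n_sites × total_subunit.  The stable quadratic form avoids
    cancellation when binding is nearly stoichiometric.
    """
    if total_ligand < 0 or total_subunit < 0:
        raise ValueError("concentrations must be ≥ 0")
    lt = total_ligand
    st = system.n_sites * total_subunit
    if lt == 0.0 or st == 0.0:
        return 0.0
    b = lt + st + system.kd
    disc = b * b - 4.0 * lt * st
    assert disc >= 0.0, "negative discriminant: implementation bug"
    return 2.0 * lt * st / (b + math.sqrt(disc))


def simulate_titration(
    system: BindingSystem,
    protocol: TitrationProtocol,
    displacement: bool = True,
) -> InjectionSeries:
    """Per-injection binding heats q_i = ΔH·V0·Δ[L]_bound.

    Perfusion displacement as in the dilution cell: each injection dilutes
    pre-existing contents (protein and accumulated ligand) by (1 − v/V0)
    before the fresh ligand aliquot mixes in and rebinds.
    """
    v0 = protocol.cell_volume
    s_cell = protocol.cell_subunit_conc
    l_cell = 0.0
    b_cell = 0.0  # bound ligand, mol/L
    vol = v0

    heats, moles_inj, ratios, l_after = [], [], [], []
    for v in protocol.injection_volumes:
        if displacement:
            d = v / v0
            s_new = s_cell * (1.0 - d)
            l_new = l_cell * (1.0 - d) + protocol.syringe_ligand_conc * d
            b_mix = b_cell * (1.0 - d)
            active_vol = v0
        else:
            new_vol = vol + v
            s_new = s_cell * vol / new_vol
            l_new = (l_cell * vol + protocol.syringe_ligand_conc * v) / new_vol
            b_mix = b_cell * vol / new_vol
            vol = new_vol
            active_vol = new_vol
        b_new = bound_ligand(system, l_new, s_new)
        q_ucal = system.delta_h * active_vol * (b_new - b_mix) * 1e9
        heats.append(q_ucal)
        moles_inj.append(protocol.syringe_ligand_conc * v)
        ratios.append(l_new / s_new)
        l_after.append(l_new)
        s_cell, l_cell, b_cell = s_new, l_new, b_new

    heats = np.asarray(heats)
    moles_inj = np.asarray(moles_inj)
    return InjectionSeries(
        heats_ucal=heats,
        injection_volumes=np.asarray(protocol.injection_volumes),
        moles_injected=moles_inj,
        normalized_heat=heats * 1e-9 / moles_inj,
        cell_conc_after=np.asarray(l_after),
        kind="binding",
        molar_ratio=np.asarray(ratios),
        meta={"displacement": displacement},
    )


def fit_one_set_of_sites(
    series: InjectionSeries,
    protocol: TitrationProtocol,
    initial_guess: tuple[float, float, float] | None = None,
    displacement: bool = True,
) -> FitResult:
    """Least-squares fit of (n_sites, kd, ΔH) to a titration series.

    ΔS is derived as (ΔH − RT·ln kd)/T and reported in cal/(mol·K), the
    unit convention of binding tables.  A Wiseman c-value
    (n_sites·[subunit]/kd) far outside [0.01, 1000] attaches an
    identifiability warning.
    """
    if len(series) < 5:
        raise ValueError("need at least 5 injections spanning the transition")
    obs = np.asarray(series.heats_ucal, dtype=float)

    if initial_guess is not None:
        n0, kd0, dh0 = initial_guess
    else:
        # total heat / total sites for ΔH; midpoint ratio for n; kd from slope scale
        n0 = 1.0
        dh0 = float(np.sum(obs)) * 1e-9 / (
            protocol.cell_subunit_conc * protocol.cell_volume
        )
        if dh0 == 0:
            dh0 = 1.0
        kd0 = max(protocol.cell_subunit_conc / 50.0, 1e-9)

    params = lmfit.Parameters()
    params.add("n_sites", value=n0, min=1e-3)
    params.add("log10_kd", value=math.log10(kd0), min=-12.0, max=0.0)
    params.add("delta_h", value=dh0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        system = BindingSystem(
            kd=10.0 ** p["log10_kd"].value,
            delta_h=p["delta_h"].value,
            n_sites=p["n_sites"].value,
            temperature=protocol.temperature,
        )
        sim = simulate_titration(system, protocol, displacement=displacement)
        return sim.heats_ucal - obs

    out = lmfit.minimize(residual, params, method="leastsq")

    kd = 10.0 ** out.params["log10_kd"].value
    dh = out.params["delta_h"].value
    n_sites = out.params["n_sites"].value
    lg_err = out.params["log10_kd"].stderr
    kd_err = kd * math.log(10.0) * lg_err if lg_err is not None else None

    dg = gibbs_from_kd(kd, protocol.temperature)
    ds_kcal = entropy_from_enthalpy_gibbs(dh, dg, protocol.temperature)

    warnings: list[str] = []
    c_value = n_sites * protocol.cell_subunit_conc / kd
    if not (0.01 <= c_value <= 1000.0):
        warnings.append(
            f"Wiseman c-value {c_value:.3g} outside [0.01, 1000]: "
            "binding parameters are weakly identifiable at this cell concentration"
        )
    if not out.success:
        warnings.append(f"optimizer did not converge: {out.message}")

    return FitResult(
        model="one_set_of_sites",
        params={"n_sites": n_sites, "kd": kd, "delta_h": dh},
        stderr={
            "n_sites": out.params["n_sites"].stderr,
            "kd": kd_err,
            "delta_h": out.params["delta_h"].stderr,
        },
        residuals=np.asarray(out.residual),
        converged=bool(out.success),
        n_eval=int(out.nfev),
        derived={
            "delta_g": dg,
            "delta_s_cal_per_mol_K": ds_kcal * 1000.0,
            "c_value": c_value,
        },
        warnings=warnings,
    )
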