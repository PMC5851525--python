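"""Dilution ITC: forward model and fitter for oligomer-dissociation heats.

A concentrated, mostly assembled protein solution is injected stepwise
into buffer.  On each injection the cell contents re-equilibrate at the
new (lower-saturation) total concentration; the net moles of subunit that
dissociate release ΔH_d per mole, producing the measured heat.  Early
injections into near-empty cells dissociate almost completely; as the
cell concentration climbs past the critical transition concentration the
signal decays toward zero, yielding the characteristic sigmoid in the
normalized molar heat.

The cell is modelled as a fixed-volume perfusion cell: injecting v into
volume V0 expels v of pre-injection-composition liquid, i.e. dilutes
existing contents by (1 − v/V0) before mixing in the aliquot.  A
no-displacement (growing volume) variant is available via a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .oligomer import OligomerSystem, monomer_concentration
from .result import FitResult
from .series import InjectionSeries
from .thermo import T_REF, entropy_from_enthalpy_gibbs, gibbs_from_kd

__all__ = ["DilutionProtocol", "simulate_dilution", "fit_dilution"]


@dataclass(frozen=True)
class DilutionProtocol:
    """Injection schedule for a protein-into-buffer dilution experiment."""

    syringe_total_subunit_conc: float  # mol/L
    cell_volume: float = 1.0e-3  # liters
    injection_volumes: tuple[float, ...] = field(
        default_factory=lambda: (5.0e-6,) * 18
    )
    temperature: float = T_REF

    def __post_init__(self) -> None:
        if self.syringe_total_subunit_conc <= 0:
            raise ValueError("syringe concentration must be positive")
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be positive")
        if len(self.injection_volumes) < 1:
            raise ValueError("at least one injection required")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("all injection volumes must be positive")


def simulate_dilution(
    system: OligomerSystem,
    protocol: DilutionProtocol,
    displacement: bool = True,
) -> InjectionSeries:
    """Simulate per-injection heats for oligomer dissociation on dilution.

    For each injection: dilute the cell (perfusion displacement), mix in
    the syringe aliquot at syringe-equilibrium composition, re-equilibrate
    at the new total concentration, and convert the net change in free
    monomer to heat at ΔH_d per mol subunit:

        q_i = ΔH_d · V0 · ([monomer]_equilibrated − [monomer]_mixed).

    With ΔH_d < 0 (exothermic dissociation) every heat is ≤ 0 and the
    magnitudes shrink as assembly saturates.
    """
    v0 = protocol.cell_volume
    c_syr = protocol.syringe_total_subunit_conc
    a_syr = monomer_concentration(system, c_syr)

    c_cell = 0.0  # total subunit, mol/L
    a_cell = 0.0  # free monomer, mol/L
    vol = v0  # only grows in the no-displacement variant

    heats = []
    moles_inj = []
    conc_after = []
    for i, v in enumerate(protocol.injection_volumes):
        if displacement:
            d = v / v0
            c_mix = c_cell * (1.0 - d) + c_syr * d
            a_mix = a_cell * (1.0 - d) + a_syr * d
            active_vol = v0
        else:
            new_vol = vol + v
            c_mix = (c_cell * vol + c_syr * v) / new_vol
            a_mix = (a_cell * vol + a_syr * v) / new_vol
            vol = new_vol
            active_vol = new_vol
        try:
            a_eq = monomer_concentration(system, c_mix)
        except RuntimeError as exc:
            raise RuntimeError(f"speciation failed at injection {i}: {exc}") from exc
        # kcal/mol · L · mol/L = kcal → microcal
        q_ucal = system.delta_h_d * active_vol * (a_eq - a_mix) * 1e9
        heats.append(q_ucal)
        moles_inj.append(c_syr * v)
        conc_after.append(c_mix)
        c_cell, a_cell = c_mix, a_eq

    heats = np.asarray(heats)
    moles_inj = np.asarray(moles_inj)
    return InjectionSeries(
        heats_ucal=heats,
        injection_volumes=np.asarray(protocol.injection_volumes),
        moles_injected=moles_inj,
        normalized_heat=heats * 1e-9 / moles_inj,  # kcal per mol injected
        cell_conc_after=np.asarray(conc_after),
        kind="dilution",
        meta={"displacement": displacement},
    )


def _cell_concentrations(protocol: DilutionProtocol) -> np.ndarray:
    """Total-subunit concentration in the cell after each injection."""
    c = 0.0
    out = []
    for v in protocol.injection_volumes:
        d = v / protocol.cell_volume
        c = c * (1.0 - d) + protocol.syringe_total_subunit_conc * d
        out.append(c)
    return np.asarray(out)


def _initial_guess(series: InjectionSeries, protocol: DilutionProtocol, n: int):
    """Heuristic starting point: first-injection complete-dissociation limit
    for ΔH_d; the concentration at the half-signal point (≈ CTC) for kd.

    Uses only heats and the protocol, so it works on series read from
    file (where speciation bookkeeping is unavailable).
    """
    moles_first = protocol.syringe_total_subunit_conc * protocol.injection_volumes[0]
    dh0 = float(series.heats_ucal[0]) * 1e-9 / moles_first
    conc = _cell_concentrations(protocol)
    norm = np.abs(
        np.asarray(series.heats_ucal)
        / (protocol.syringe_total_subunit_conc
           * np.asarray(protocol.injection_volumes))
    )
    below = np.nonzero(norm <= 0.5 * norm[0])[0]
    ctc_est = float(conc[below[0]]) if below.size else float(conc[-1])
    kd0 = max(ctc_est * n ** (1.0 / (n - 1)) / 2.0, 1e-12)
    return kd0, dh0 if dh0 != 0 else -1.0


def fit_dilution(
    series: InjectionSeries,
    protocol: DilutionProtocol,
    n: int = 16,
    initial_guess: tuple[float, float] | None = None,
    fit_offset: bool = False,
    displacement: bool = True,
) -> FitResult:
    """Weighted nonlinear least squares for (kd, ΔH_d) at fixed stoichiometry.

    Parameters are fitted on the per-injection heats (μcal).  kd is
    optimized as log10(kd) for conditioning but reported in mol/L.
    Derived ΔG_d and ΔS_d (per subunit, at the protocol temperature) are
    attached.  Non-convergence and flat-signal inputs are flagged in
    ``warnings``/``converged``, never silent.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 injections to fit (kd, ΔH_d)")

    obs = np.asarray(series.heats_ucal, dtype=float)
    warnings: list[str] = []
    if np.max(np.abs(obs)) < 1.0:
        warnings.append(
            "flat signal: all |q| < 1 μcal — kd and ΔH_d are weakly identifiable"
        )

    kd0, dh0 = initial_guess if initial_guess is not None else _initial_guess(
        series, protocol, n
    )

    params = lmfit.Parameters()
    params.add("log10_kd", value=math.log10(kd0), min=-12.0, max=0.0)
    params.add("delta_h_d", value=dh0)
    params.add("offset_ucal", value=0.0, vary=fit_offset)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        system = OligomerSystem(
            kd=10.0 ** p["log10_kd"].value,
            n=n,
            delta_h_d=p["delta_h_d"].value,
            temperature=protocol.temperature,
        )
        sim = simulate_dilution(system, protocol, displacement=displacement)
        return sim.heats_ucal + p["offset_ucal"].value - obs

    out = lmfit.minimize(residual, params, method="leastsq")

    kd = 10.0 ** out.params["log10_kd"].value
    dh = out.params["delta_h_d"].value
    # delta-method stderr for kd from the log10 parameter
    lg_err = out.params["log10_kd"].stderr
    kd_err = kd * math.log(10.0) * lg_err if lg_err is not None else None
    dg = gibbs_from_kd(kd, protocol.temperature)
    ds = entropy_from_enthalpy_gibbs(dh, dg, protocol.temperature)

    fitted = {"kd": kd, "delta_h_d": dh}
    stderr: dict[str, float | None] = {
        "kd": kd_err,
        "delta_h_d": out.params["delta_h_d"].stderr,
    }
    if fit_offset:
        fitted["offset_ucal"] = out.params["offset_ucal"].value
        stderr["offset_ucal"] = out.params["offset_ucal"].stderr

    if not out.success:
        warnings.append(f"optimizer did not converge: {out.message}")
    return FitResult(
        model=f"dilution_n{n}",
        params=fitted,
        stderr=stderr,
        residuals=np.asarray(out.residual),
        converged=bool(out.success),
        n_eval=int(out.nfev),
        derived={"delta_g_d": dg, "delta_s_d": ds, "n": float(n)},
        warnings=warnings,
    )
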