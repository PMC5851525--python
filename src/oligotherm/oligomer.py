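"""Mass-action equilibrium between an n-mer and its monomers.

The assembly A_n ⇌ n·A is parameterized by a *per-subunit* dissociation
constant ``kd`` (mol/L) with the convention

    [A]^n / [A_n] = kd^(n−1),

which reduces to the standard dimer convention at n = 2 and makes the
per-subunit Gibbs energy of dissociation ΔG_d = RT·ln(kd / 1 M).  Mass
balance over total subunit concentration C then reads

    a + n·a^n / kd^(n−1) = C,

an n-th order polynomial in the free-monomer concentration ``a`` whose
left side is strictly increasing, so the physical root on [0, C] is
unique.  For the chaperonin hexadecamer n = 16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .thermo import T_REF

__all__ = [
    "OligomerSystem",
    "SpeciationResult",
    "monomer_fraction",
    "critical_transition_concentration",
    "assembled_fraction_vs_concentration",
]

_RTOL = 4 * np.finfo(float).eps


@dataclass(frozen=True)
class OligomerSystem:
    """Stoichiometry and per-subunit thermodynamics of an n-mer assembly.

    Parameters
    ----------
    kd : float
        Per-subunit dissociation constant, mol/L.
    n : int
        Subunits per complex (two stacked octameric rings → 16).
    delta_h_d : float
        Dissociation enthalpy, kcal per mol subunit (negative when
        disassembly is exothermic).
    temperature : float
        Kelvin.
    """

    kd: float
    n: int = 16
    delta_h_d: float = 0.0
    temperature: float = T_REF

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"stoichiometry n must be ≥ 2, got {self.n}")
        if self.kd <= 0:
            raise ValueError(f"kd must be positive, got {self.kd!r}")


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium species concentrations at one total subunit concentration."""

    total_subunit_conc: float
    monomer_conc: float
    oligomer_conc: float  # complex units, mol/L
    monomer_fraction: float


def _oligomer_subunit_conc(system: OligomerSystem, a: float) -> float:
    """Subunit concentration held in complexes: n·a^n/kd^(n−1), log-domain."""
    if a <= 0.0:
        return 0.0
    n = system.n
    return math.exp(math.log(n) + n * math.log(a) - (n - 1) * math.log(system.kd))


def monomer_concentration(system: OligomerSystem, total_subunit_conc: float) -> float:
    """Free-monomer concentration solving a + n·a^n/kd^(n−1) = C_tot.

    Bracketed root finding on [0, C_tot]; the left side is strictly
    increasing in ``a`` so the root is unique.
    """
    c = total_subunit_conc
    if c < 0:
        raise ValueError("total subunit concentration must be ≥ 0")
    if c == 0.0:
        return 0.0

    def residual(a: float) -> float:
        return a + _oligomer_subunit_conc(system, a) - c

    # residual(0) = −c < 0 and residual(c) ≥ 0, so [0, c] always brackets.
    try:
        root = brentq(residual, 0.0, c, xtol=1e-300, rtol=_RTOL, maxiter=200)
    except RuntimeError as exc:  # pragma: no cover - brentq converges here
        raise RuntimeError(
            f"speciation solver failed at C_tot={c:g} M for n={system.n}, "
            f"kd={system.kd:g} M: {exc}"
        ) from exc
    return float(root)


def monomer_fraction(
    system: OligomerSystem, total_subunit_conc: float
) -> SpeciationResult:
    """Full equilibrium speciation at a total subunit concentration.

    At C_tot = 0 the all-monomer infinite-dilution limit (fraction 1) is
    returned by continuity.
    """
    c = total_subunit_conc
    if c == 0.0:
        return SpeciationResult(0.0, 0.0, 0.0, 1.0)
    a = monomer_concentration(system, c)
    oligo_subunits = c - a
    return SpeciationResult(
        total_subunit_conc=c,
        monomer_conc=a,
        oligomer_conc=oligo_subunits / system.n,
        monomer_fraction=a / c,
    )


def critical_transition_concentration(system: OligomerSystem) -> float:
    """Total subunit concentration at which half the subunits are free.

    Below the CTC disassembly dominates; above it assembly does.  Setting
    a = C/2 in the mass balance gives the closed form
    CTC = 2·kd·n^(−1/(n−1)), used to bracket a bisection refinement on the
    monotone fraction-vs-concentration curve.
    """
    n, kd = system.n, system.kd
    closed = 2.0 * kd * n ** (-1.0 / (n - 1))

    def half_point(c: float) -> float:
        return monomer_fraction(system, c).monomer_fraction - 0.5

    lo, hi = 0.5 * closed, 2.0 * closed
    # fraction is decreasing in C, so half_point(lo) > 0 > half_point(hi)
    return float(brentq(half_point, lo, hi, xtol=1e-300, rtol=_RTOL))


def assembled_fraction_vs_concentration(
    system: OligomerSystem, conc_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Fraction of subunits held in complexes along a concentration grid."""
    out = []
    for c in conc_grid:
        spec = monomer_fraction(system, c)
        out.append((float(c), 1.0 - spec.monomer_fraction))
    return out
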