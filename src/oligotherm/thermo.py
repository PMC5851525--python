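"""Physical constants, unit conventions, and closed-form thermodynamic identities.

All thermodynamic quantities in this package are expressed *per mole of
subunit* (the convention used for oligomeric assemblies whose parameters
are normalized per monomer), energies in kcal/mol, temperatures in kelvin
internally.  Public tables and the CLI accept/emit degrees Celsius where
instrument software does.

The identities implemented here connect a dissociation constant, Gibbs
energy, enthalpy and entropy at a single temperature:

    ΔG = R·T·ln(K_d / c°)          (c° = 1 M standard state)
    ΔS = (ΔH − ΔG) / T
    R_cal/vH = ΔH_cal / ΔH_vH      (unity for a two-state transition)

and the van't Hoff temperature dependence of an equilibrium constant

    K(T) = K(T_m) · exp[ −(ΔH_vH/R) (1/T − 1/T_m) ].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "R_KCAL",
    "STANDARD_CONC_M",
    "CELSIUS_OFFSET",
    "T_REF",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "gibbs_from_kd",
    "kd_from_gibbs",
    "entropy_from_enthalpy_gibbs",
    "enthalpy_ratio",
    "vant_hoff_k",
    "round_half_away",
    "ThermoState",
]

#: Gas constant, kcal/(mol·K).
R_KCAL = 1.9872e-3

#: Standard-state concentration for ln(K_d) arguments, mol/L.
STANDARD_CONC_M = 1.0

#: Offset between Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15

#: Reference temperature for tabulated 25 °C parameters, kelvin.
T_REF = 298.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET


def gibbs_from_kd(kd: float, temperature: float = T_REF) -> float:
    """Per-subunit Gibbs energy of dissociation from the dissociation constant.

    Parameters
    ----------
    kd : float
        Per-subunit dissociation constant, mol/L. Must be positive.
    temperature : float
        Absolute temperature, K. Must be positive.

    Returns
    -------
    float
        ΔG = R·T·ln(kd / 1 M) in kcal per mol subunit; negative for
        sub-molar dissociation constants.
    """
    if kd <= 0:
        raise ValueError(f"dissociation constant must be positive, got {kd!r}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature!r}")
    return R_KCAL * temperature * math.log(kd / STANDARD_CONC_M)


def kd_from_gibbs(delta_g: float, temperature: float = T_REF) -> float:
    """Inverse of :func:`gibbs_from_kd`: K_d = exp(ΔG / RT) · 1 M."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature!r}")
    return STANDARD_CONC_M * math.exp(delta_g / (R_KCAL * temperature))


def entropy_from_enthalpy_gibbs(
    delta_h: float, delta_g: float, temperature: float = T_REF
) -> float:
    """ΔS = (ΔH − ΔG)/T, in kcal/(mol subunit·K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature!r}")
    return (delta_h - delta_g) / temperature


def enthalpy_ratio(delta_h_cal: float, delta_h_vh: float) -> float:
    """Calorimetric-to-van't Hoff enthalpy ratio.

    Unity characterizes a two-state monomolecular transition; values above
    one flag multistep or dissociation-coupled unfolding.
    """
    if delta_h_vh == 0:
        raise ValueError("van't Hoff enthalpy must be nonzero")
    return delta_h_cal / delta_h_vh


def vant_hoff_k(
    temperature: float, tm: float, delta_h_vh: float, k_at_tm: float = 1.0
) -> float:
    """Equilibrium constant at ``temperature`` via the van't Hoff relation.

    K(T) = K(Tm)·exp[−(ΔH_vH/R)(1/T − 1/Tm)].  ``k_at_tm`` carries the
    model-dependent midpoint convention: 1 for a two-state transition, the
    half-dissociation value for a dissociative one.
    """
    if tm <= 0 or temperature <= 0:
        raise ValueError("temperatures must be positive")
    return k_at_tm * math.exp(-(delta_h_vh / R_KCAL) * (1.0 / temperature - 1.0 / tm))


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables).

    Python's builtin ``round`` is banker's rounding; report tables
    conventionally round 0.5 up in magnitude.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class ThermoState:
    """A self-consistent thermodynamic state at one temperature.

    Any subset of fields may be populated; on construction every identity
    whose inputs are present is checked against ``tolerance`` (kcal/mol).
    """

    temperature: float
    delta_g: Optional[float] = None
    delta_h: Optional[float] = None
    delta_s: Optional[float] = None
    kd: Optional[float] = None
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if None not in (self.delta_g, self.delta_h, self.delta_s):
            resid = self.delta_g - (self.delta_h - self.temperature * self.delta_s)
            if abs(resid) > self.tolerance:
                raise ValueError(
                    f"ΔG = ΔH − TΔS violated by {resid:.3g} kcal/mol "
                    f"(tolerance {self.tolerance:g})"
                )
        if self.delta_g is not None and self.kd is not None:
            resid = self.delta_g - gibbs_from_kd(self.kd, self.temperature)
            if abs(resid) > self.tolerance:
                raise ValueError(
                    f"ΔG = RT·ln(K_d/1 M) violated by {resid:.3g} kcal/mol "
                    f"(tolerance {self.tolerance:g})"
                )
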