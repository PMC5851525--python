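"""Injection-series container shared by dilution and binding ITC."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["InjectionSeries"]


@dataclass
class InjectionSeries:
    """Ordered per-injection heats with the bookkeeping needed to fit them.

    Attributes
    ----------
    heats_ucal : ndarray
        Measured (or simulated) heat per injection, microcalories.
    injection_volumes : ndarray
        Injected volume per injection, liters.
    moles_injected : ndarray
        Moles of titrant (subunit for dilution, ligand for binding)
        delivered per injection.
    normalized_heat : ndarray
        Heat per mole of injected titrant, kcal/mol.
    cell_conc_after : ndarray
        Total titrant concentration in the cell after each injection
        (subunit for dilution runs), mol/L.
    molar_ratio : ndarray, optional
        Cumulative ligand:subunit molar ratio (binding runs only).
    kind : str
        ``"dilution"`` or ``"binding"``.
    """

    heats_ucal: np.ndarray
    injection_volumes: np.ndarray
    moles_injected: np.ndarray
    normalized_heat: np.ndarray
    cell_conc_after: np.ndarray
    kind: str = "dilution"
    molar_ratio: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.heats_ucal)
        for name in ("injection_volumes", "moles_injected", "normalized_heat",
                     "cell_conc_after"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match heats ({n})")

    def __len__(self) -> int:
        return len(self.heats_ucal)

    @property
    def cumulative_moles_injected(self) -> np.ndarray:
        return np.cumsum(self.moles_injected)
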