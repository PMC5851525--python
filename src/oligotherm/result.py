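"""Uniform container for nonlinear least-squares fit outcomes."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["FitResult"]


@dataclass
class FitResult:
    """Fitted parameters with uncertainties and convergence diagnostics.

    ``params`` maps parameter names to point estimates; ``stderr`` holds
    the asymptotic standard errors (None when the covariance could not be
    estimated).  ``derived`` carries quantities computed from the fit
    (ΔG, ΔS, ...) that were not free parameters.  ``warnings`` collects
    identifiability or convergence caveats — a fit is never silently bad.
    """

    model: str
    params: dict[str, float]
    stderr: dict[str, Optional[float]]
    residuals: np.ndarray
    converged: bool
    n_eval: int = 0
    derived: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def rss(self) -> float:
        """Residual sum of squares."""
        return float(np.sum(np.asarray(self.residuals) ** 2))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "stderr": {
                k: (None if v is None else float(v)) for k, v in self.stderr.items()
            },
            "residuals": [float(r) for r in np.asarray(self.residuals).ravel()],
            "rss": self.rss,
            "converged": bool(self.converged),
            "n_eval": int(self.n_eval),
            "derived": {k: float(v) for k, v in self.derived.items()},
            "warnings": list(self.warnings),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            model=d["model"],
            params=dict(d["params"]),
            stderr=dict(d["stderr"]),
            residuals=np.asarray(d["residuals"], dtype=float),
            converged=bool(d["converged"]),
            n_eval=int(d.get("n_eval", 0)),
            derived=dict(d.get("derived", {})),
            warnings=list(d.get("warnings", [])),
        )

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "FitResult":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        return cls.from_dict(json.loads(text))
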