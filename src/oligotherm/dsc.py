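"""DSC thermogram models and analysis.

Two excess-heat-capacity models are provided:

* **two-state** (N ⇌ U, monomolecular): the classic symmetric-ish peak

      Cp_ex(T) = ΔH_cal·ΔH_vH/(R·T²) · K/(1+K)²,
      K(T) = exp[−(ΔH_vH/R)(1/T − 1/Tm)],

  with maximum ΔH_cal·ΔH_vH/(4·R·Tm²) at Tm and unit-normalized area
  ΔH_cal.

* **dissociative** (A_n ⇌ n·U): unfolding coupled to oligomer
  dissociation.  With α the unfolded-subunit fraction at total subunit
  concentration C,

      K(T) = n·α^n·C^(n−1)/(1−α),

  K following van't Hoff in temperature with midpoint α = 0.5 at the
  stated Tm.  The mass-action term skews the peak toward temperatures
  below the midpoint and makes the apparent Tm concentration-dependent —
  the two experimental signatures of dissociation-coupled unfolding.
  At n = 1 the model reduces exactly to the two-state form.

ΔH_cal is always measured model-free by integrating the baselined trace;
ΔH_vH comes from a model fit or from the peak-shape formula
ΔH_vH = 4·R·Tm²·Cp_max/ΔH_cal.  Their ratio R = ΔH_cal/ΔH_vH is unity
for a genuine two-state transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import lmfit

from .oligomer import OligomerSystem, assembled_fraction_vs_concentration
from .thermo import R_KCAL, celsius_to_kelvin, enthalpy_ratio, kelvin_to_celsius

__all__ = [
    "Thermogram",
    "DscFit",
    "subtract_baseline",
    "calorimetric_enthalpy",
    "two_state_excess_cp",
    "dissociative_excess_cp",
    "vant_hoff_from_peak",
    "fit_thermogram",
    "enthalpy_vs_concentration",
]


@dataclass(frozen=True)
class Thermogram:
    """Excess heat capacity vs temperature for one scan.

    ``temperature`` is a strictly increasing kelvin grid; ``excess_cp``
    is in kcal/(mol subunit·K).  Concentration and scan rate are carried
    as metadata (a single scan rate means equilibrium analysis applies).
    """

    temperature: np.ndarray
    excess_cp: np.ndarray
    total_subunit_conc: Optional[float] = None  # mol/L
    scan_rate: Optional[float] = None  # K/hour, metadata only
    baseline_method: Optional[str] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        cp = np.asarray(self.excess_cp, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "excess_cp", cp)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("temperature grid must be a 1-D array of ≥ 2 points")
        if cp.shape != t.shape:
            raise ValueError("excess_cp shape must match temperature grid")
        diffs = np.diff(t)
        if np.any(diffs <= 0):
            bad = int(np.nonzero(diffs <= 0)[0][0]) + 1
            raise ValueError(
                f"temperature grid must be strictly increasing (violated at row {bad})"
            )

    def __len__(self) -> int:
        return self.temperature.size


@dataclass(frozen=True)
class DscFit:
    """Thermogram analysis summary: midpoint, enthalpies and their ratio."""

    tm_celsius: float
    delta_h_cal: float
    delta_h_vh: float
    model: str  # "two_state" | "dissociative"
    tm_peak_celsius: Optional[float] = None  # peak-maximum temperature
    converged: bool = True
    rss: float = 0.0
    warnings: tuple[str, ...] = ()

    @property
    def ratio(self) -> float:
        return enthalpy_ratio(self.delta_h_cal, self.delta_h_vh)

    @property
    def tm_kelvin(self) -> float:
        return celsius_to_kelvin(self.tm_celsius)


# ---------------------------------------------------------------------------
# baseline handling


def _default_windows(n: int, frac: float = 0.12) -> tuple[slice, slice]:
    w = max(10, int(round(n * frac)))
    return slice(0, w), slice(n - w, n)


def _window_is_flat(t: np.ndarray, y: np.ndarray, peak_scale: float) -> bool:
    # flat = the window neither rides the transition (net rise across the
    # window well below the peak) nor scatters beyond noise about a line
    coef = np.polyfit(t, y, 1)
    resid = y - np.polyval(coef, t)
    net_rise = abs(coef[0]) * (t[-1] - t[0])
    return net_rise < 0.05 * peak_scale and float(np.std(resid)) < 0.05 * peak_scale


def subtract_baseline(
    raw: Thermogram,
    method: str = "linear",
    pre_window: slice | None = None,
    post_window: slice | None = None,
) -> Thermogram:
    """Remove the instrumental baseline from a raw scan.

    ``linear`` draws a straight line through the pre- and post-transition
    windows.  ``progress`` interpolates between separate pre- and post-
    transition lines weighted by the transition progress (the running
    normalized integral), iterated to self-consistency — the standard
    sigmoidal chemical baseline.

    Windows default to the outer 12% of the grid (≥ 10 points each) and
    must be flat relative to the peak; otherwise the candidates are
    reported in the error.
    """
    if method not in ("linear", "progress"):
        raise ValueError(f"unknown baseline method {method!r}")
    t = raw.temperature
    y = raw.excess_cp
    n = t.size
    pre, post = _default_windows(n)
    if pre_window is not None:
        pre = pre_window
    if post_window is not None:
        post = post_window
    if (pre.stop - (pre.start or 0)) < 10 or (post.stop - post.start) < 10:
        raise ValueError("baseline windows need ≥ 10 points each")

    peak_scale = float(np.max(y) - np.min(y))
    if peak_scale == 0.0:
        return replace(raw, baseline_method=method)
    for name, w in (("pre", pre), ("post", post)):
        if not _window_is_flat(t[w], y[w], peak_scale):
            raise ValueError(
                f"no flat {name}-transition window found; candidate rows "
                f"{w.start}–{w.stop} are not flat relative to the peak — "
                "pass pre_window/post_window explicitly"
            )

    pre_coef = np.polyfit(t[pre], y[pre], 1)
    post_coef = np.polyfit(t[post], y[post], 1)

    if method == "linear":
        both_t = np.concatenate([t[pre], t[post]])
        both_y = np.concatenate([y[pre], y[post]])
        base = np.polyval(np.polyfit(both_t, both_y, 1), t)
        corrected = y - base
    else:
        pre_line = np.polyval(pre_coef, t)
        post_line = np.polyval(post_coef, t)
        corrected = y - pre_line  # initial guess for progress weighting
        for _ in range(8):
            cum = np.concatenate(
                [[0.0], np.cumsum(0.5 * (corrected[1:] + corrected[:-1]) * np.diff(t))]
            )
            total = cum[-1]
            alpha = cum / total if total != 0 else np.zeros_like(cum)
            alpha = np.clip(alpha, 0.0, 1.0)
            base = (1.0 - alpha) * pre_line + alpha * post_line
            corrected = y - base
    return replace(raw, excess_cp=corrected, baseline_method=method)


def calorimetric_enthalpy(trace: Thermogram) -> float:
    """Model-free ΔH_cal: trapezoidal area under the baselined trace."""
    return float(np.trapezoid(trace.excess_cp, trace.temperature))


# ---------------------------------------------------------------------------
# forward models


def two_state_excess_cp(
    tm: float,
    delta_h_vh: float,
    delta_h_cal: float,
    grid: Sequence[float],
) -> Thermogram:
    """Two-state excess heat capacity on a kelvin grid (Tm in kelvin)."""
    t = np.asarray(grid, dtype=float)
    if not (t[0] <= tm <= t[-1]):
        raise ValueError("tm must lie within the temperature grid")
    k = np.exp(-(delta_h_vh / R_KCAL) * (1.0 / t - 1.0 / tm))
    cp = (delta_h_cal * delta_h_vh / (R_KCAL * t**2)) * k / (1.0 + k) ** 2
    return Thermogram(temperature=t, excess_cp=cp, baseline_method="model")


def _solve_alpha_grid(n: int, rhs: np.ndarray) -> np.ndarray:
    """Solve n·ln α − ln(1−α) = rhs for α ∈ (0, 1) at every grid point.

    The left side is strictly increasing in α, so a vectorized bisection
    converges unconditionally.  Tails beyond floating-point brackets use
    the asymptotic closed forms α ≈ exp(rhs/n) (unfolded fraction → 0)
    and 1 − α ≈ exp(−rhs) (→ 1), whose neglected terms are below 1e-13.
    """
    rhs = np.asarray(rhs, dtype=float)
    alpha = np.empty_like(rhs)
    lo_val, hi_val = 1e-14, 1.0 - 1e-14
    g_lo = n * math.log(lo_val) - math.log1p(-lo_val) - rhs
    g_hi = n * math.log(hi_val) - math.log1p(-hi_val) - rhs
    low_tail = g_lo >= 0.0
    high_tail = g_hi <= 0.0
    mid = ~(low_tail | high_tail)
    with np.errstate(under="ignore"):
        alpha[low_tail] = np.exp(rhs[low_tail] / n)
        alpha[high_tail] = 1.0 - np.exp(-rhs[high_tail])
    if np.any(mid):
        lo = np.full(rhs.shape, lo_val)
        hi = np.full(rhs.shape, hi_val)
        for _ in range(110):
            m = 0.5 * (lo + hi)
            g_m = n * np.log(m) - np.log1p(-m) - rhs
            go_down = g_m > 0.0
            hi = np.where(go_down & mid, m, hi)
            lo = np.where(~go_down & mid, m, lo)
        alpha[mid] = (0.5 * (lo + hi))[mid]
    return alpha


def dissociative_excess_cp(
    system: OligomerSystem | int,
    delta_h_vh: float,
    delta_h_cal: float,
    tm_at_conc: float,
    total_subunit_conc: float,
    grid: Sequence[float],
    tm_ref_conc: float | None = None,
) -> Thermogram:
    """Dissociation-coupled excess heat capacity A_n ⇌ n·U.

    ``tm_at_conc`` (kelvin) is the temperature of half-conversion
    (α = 0.5) at the reference concentration (``tm_ref_conc``, defaulting
    to ``total_subunit_conc`` itself); K(T) follows van't Hoff with
    enthalpy ``delta_h_vh``.  α(T) solves the mass-action relation
    K(T) = n·α^n·C^(n−1)/(1−α) per grid point by vectorized bracketed
    bisection; Cp_ex = ΔH_cal·dα/dT uses the exact implicit derivative

        dα/dT = (ΔH_vH/(R·T²)) / (n/α + 1/(1−α)),

    which reduces to the analytic two-state expression at n = 1 (pass an
    integer for ``system`` when no assembly system applies).

    The mass-action term skews the peak below the midpoint for n > 1 and
    shifts the apparent midpoint up with concentration: passing
    ``tm_ref_conc`` ≠ ``total_subunit_conc`` evaluates the trace at a new
    load concentration with the equilibrium-constant anchor held fixed.
    """
    n = system.n if isinstance(system, OligomerSystem) else int(system)
    if n < 1:
        raise ValueError("stoichiometry must be ≥ 1")
    t = np.asarray(grid, dtype=float)
    if not (t[0] <= tm_at_conc <= t[-1]):
        raise ValueError("tm_at_conc must lie within the temperature grid")
    c_ref = tm_ref_conc if tm_ref_conc is not None else total_subunit_conc
    # midpoint anchor: ln K(Tm, C_ref) − ln n − (n−1)·ln C = (n−1)·ln(0.5·C_ref/C)
    rhs_tm = (n - 1) * math.log(0.5)
    if c_ref is not None and total_subunit_conc is not None and n > 1:
        rhs_tm += (n - 1) * math.log(c_ref / total_subunit_conc)
    rhs = rhs_tm - (delta_h_vh / R_KCAL) * (1.0 / t - 1.0 / tm_at_conc)
    alpha = _solve_alpha_grid(n, rhs)
    with np.errstate(divide="ignore"):
        denom = n / alpha + 1.0 / (1.0 - alpha)
        cp = delta_h_cal * (delta_h_vh / (R_KCAL * t**2)) / denom
    cp = np.where(np.isfinite(cp), cp, 0.0)
    return Thermogram(
        temperature=t,
        excess_cp=cp,
        total_subunit_conc=total_subunit_conc,
        baseline_method="model",
    )


def vant_hoff_from_peak(cp_max: float, tm: float, delta_h_cal: float) -> float:
    """Peak-shape van't Hoff enthalpy: ΔH_vH = 4·R·Tm²·Cp_max/ΔH_cal (Tm in K)."""
    if delta_h_cal == 0:
        raise ValueError("ΔH_cal must be nonzero")
    return 4.0 * R_KCAL * tm**2 * cp_max / delta_h_cal


def _midpoint_temperature(t: np.ndarray, cp: np.ndarray) -> float:
    """Temperature of half-area (α = 0.5) by interpolating the running integral."""
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (cp[1:] + cp[:-1]) * np.diff(t))])
    return float(np.interp(0.5 * cum[-1], cum, t))


# ---------------------------------------------------------------------------
# fitting


def fit_thermogram(
    trace: Thermogram,
    model: str = "two_state",
    n: int = 16,
    total_subunit_conc: float | None = None,
) -> DscFit:
    """Extract (Tm, ΔH_cal, ΔH_vH) from a baselined thermogram.

    ΔH_cal comes model-free from integration; Tm and ΔH_vH from a
    least-squares fit of the chosen excess-Cp model with ΔH_cal held at
    its measured value.  For the dissociative model Tm is the α = 0.5
    midpoint (the peak-maximum temperature is reported alongside); for
    the two-state model the two coincide.
    """
    if model not in ("two_state", "dissociative"):
        raise ValueError(f"unknown model {model!r}")
    t = trace.temperature
    cp = trace.excess_cp
    ipeak = int(np.argmax(cp))
    if ipeak in (0, t.size - 1):
        raise ValueError(
            "peak lies at the grid boundary; the transition is not fully "
            "captured — refusing to fit"
        )
    dh_cal = calorimetric_enthalpy(trace)
    tm0 = float(t[ipeak])
    dh_vh0 = vant_hoff_from_peak(float(cp[ipeak]), tm0, dh_cal)
    conc = None
    if model == "dissociative":
        tm0 = _midpoint_temperature(t, cp)
        conc = (
            total_subunit_conc
            if total_subunit_conc is not None
            else trace.total_subunit_conc
        )
        if conc is None:
            raise ValueError("dissociative fit needs the total subunit concentration")

    params = lmfit.Parameters()
    params.add("tm", value=tm0, min=float(t[0]), max=float(t[-1]))
    params.add("dh_vh", value=max(dh_vh0, 1.0), min=1.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        if model == "two_state":
            m = two_state_excess_cp(p["tm"].value, p["dh_vh"].value, dh_cal, t)
        else:
            m = dissociative_excess_cp(
                n, p["dh_vh"].value, dh_cal, p["tm"].value, conc, t
            )
        return m.excess_cp - cp

    out = lmfit.minimize(residual, params, method="leastsq")
    tm_fit = out.params["tm"].value
    dh_vh = out.params["dh_vh"].value

    if model == "two_state":
        tm_peak = tm_fit
    else:
        fitted = dissociative_excess_cp(n, dh_vh, dh_cal, tm_fit, conc, t)
        tm_peak = float(t[int(np.argmax(fitted.excess_cp))])

    warnings = () if out.success else (f"optimizer did not converge: {out.message}",)
    return DscFit(
        tm_celsius=kelvin_to_celsius(tm_fit),
        delta_h_cal=dh_cal,
        delta_h_vh=dh_vh,
        model=model,
        tm_peak_celsius=kelvin_to_celsius(tm_peak),
        converged=bool(out.success),
        rss=float(np.sum(np.asarray(out.residual) ** 2)),
        warnings=warnings,
    )


def enthalpy_vs_concentration(
    system: OligomerSystem,
    full_delta_h: float,
    conc_list: Sequence[float],
) -> list[tuple[float, float]]:
    """Apparent calorimetric enthalpy vs load concentration.

    Only the assembled fraction contributes the dissociation-coupled
    enthalpy, so the observed ΔH(C) = fraction-assembled(C)·ΔH_full rises
    monotonically with concentration — the signature seen when scanning a
    dilution ladder.
    """
    if any(c <= 0 for c in conc_list):
        raise ValueError("concentrations must be positive")
    return [
        (c, f * full_delta_h)
        for c, f in assembled_fraction_vs_concentration(system, conc_list)
    ]
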