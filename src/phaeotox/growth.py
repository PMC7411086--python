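"""Specific growth rates, relative growth inhibition, and IC50 estimation.

Growth of a batch microalgal culture is summarised by the mean specific
growth rate ``mu = (ln N_final - ln N_initial) / dt`` (per day).  Toxicant
effect at a dose is expressed as the relative cell-density reduction
toward the control at the exposure endpoint, and the dose-response curve
is summarised by the IC50 -- the concentration inhibiting half the
maximum growth.  Two estimators are provided: a two-parameter
log-logistic least-squares fit (default) and log-linear interpolation
between the doses bracketing 50% inhibition (fallback and cross-check).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GrowthSeries",
    "DoseResponseFit",
    "specific_growth_rate",
    "relative_inhibition",
    "fit_ic50",
    "log_logistic_inhibition",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class GrowthSeries:
    """Cell-density time series for one replicate culture.

    Parameters
    ----------
    times : array-like
        Hours since inoculation, strictly increasing.
    densities : array-like
        Cell densities (cells per mL), strictly positive.
    treatment : float
        Toxicant concentration (ug/L) this replicate was exposed to.
    replicate_id : str
        Replicate label.
    """

    times: np.ndarray
    densities: np.ndarray
    treatment: float = 0.0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        densities = np.asarray(self.densities, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("growth series needs at least two time points")
        if densities.shape != times.shape:
            raise ValueError("times and densities must have equal length")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(densities > 0):
            raise ValueError("densities must be strictly positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "densities", densities)

    def density_at(self, time_h: float) -> float:
        """Density at a sampled time point (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.times, time_h))
        if idx.size == 0:
            raise ValueError(f"time {time_h} h not sampled in this series")
        return float(self.densities[idx[0]])


@dataclass
class DoseResponseFit:
    """Result of an IC50 estimation.

    ``method`` records which estimator produced ``ic50``:
    ``"log-logistic fit"`` or ``"log-linear interpolation"``.  When the
    data never reach 50% inhibition and the fit does not converge,
    ``reached`` is False and ``ic50`` is NaN (never an extrapolation).
    """

    ic50: float
    hill_slope: float
    method: str
    doses: np.ndarray
    inhibitions: np.ndarray
    residuals: np.ndarray
    reached: bool = True
    stimulation_flag: bool = False
    notes: str = ""
    per_dose: dict = field(default_factory=dict)


def specific_growth_rate(series: GrowthSeries, window: tuple[float, float]) -> float:
    """Mean specific growth rate (per day) over a time window.

    mu = (ln N_final - ln N_initial) / dt  with dt in days; the window
    endpoints must be sampled times of the series.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    n0 = series.density_at(t0)
    n1 = series.density_at(t1)
    dt_days = (t1 - t0) / HOURS_PER_DAY
    return float((np.log(n1) - np.log(n0)) / dt_days)


def relative_inhibition(treated: float, control: float) -> float:
    """Relative cell-density reduction toward the control, in percent.

    ``(1 - N_treated / N_control) * 100``; negative values indicate
    growth stimulation and are retained, not clipped.
    """
    if control <= 0:
        raise ValueError("control density must be positive")
    if treated < 0:
        raise ValueError("treated density cannot be negative")
    return float((1.0 - treated / control) * 100.0)


def log_logistic_inhibition(dose, ic50: float, hill_slope: float):
    """Two-parameter log-logistic inhibition curve, percent.

    I(d) = 100 / (1 + (ic50/d)**hill_slope), with I(0) = 0 by continuity.
    """
    dose = np.asarray(dose, dtype=float)
    out = np.zeros_like(dose)
    pos = dose > 0
    out[pos] = 100.0 / (1.0 + (ic50 / dose[pos]) ** hill_slope)
    return out if out.ndim else float(out)


def _interpolate_ic50(doses: np.ndarray, inhibitions: np.ndarray) -> float | None:
    """Log-linear interpolation of inhibition between doses bracketing 50%."""
    pos = doses > 0
    d, y = doses[pos], inhibitions[pos]
    order = np.argsort(d)
    d, y = d[order], y[order]
    exact = np.flatnonzero(np.isclose(y, 50.0))
    if exact.size:
        return float(d[exact[0]])
    for i in range(len(d) - 1):
        if y[i] < 50.0 <= y[i + 1]:
            lo, hi = np.log10(d[i]), np.log10(d[i + 1])
            frac = (50.0 - y[i]) / (y[i + 1] - y[i])
            return float(10.0 ** (lo + frac * (hi - lo)))
    return None


def fit_ic50(
    doses,
    inhibitions,
    method: str = "log-logistic",
) -> DoseResponseFit:
    """Estimate the IC50 from per-dose inhibition percentages.

    Parameters
    ----------
    doses : array-like
        Concentrations (ug/L); a zero dose anchors the 0% asymptote but
        cannot enter log-dose space.
    inhibitions : array-like
        Relative inhibition per dose, percent (may be negative for
        stimulation; values are used as given).
    method : {"log-logistic", "interpolation"}
        Primary estimator.  The log-logistic fit minimises squared
        residuals of ``100/(1+(ic50/d)^h)``; on non-convergence it falls
        back to log-linear interpolation between the doses bracketing
        50%.  If neither applies, the result is flagged "IC50 not
        reached" with ``ic50 = NaN``.
    """
    doses = np.asarray(doses, dtype=float)
    inhibitions = np.asarray(inhibitions, dtype=float)
    if doses.shape != inhibitions.shape or doses.ndim != 1:
        raise ValueError("doses and inhibitions must be 1-D and matched")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    stim = bool(np.any(inhibitions < 0))
    per_dose = {float(d): float(i) for d, i in zip(doses, inhibitions)}

    def _result(ic50, hill, meth, reached=True, notes=""):
        pred = log_logistic_inhibition(doses, ic50, hill) if reached else np.full_like(doses, np.nan)
        return DoseResponseFit(
            ic50=ic50,
            hill_slope=hill,
            method=meth,
            doses=doses,
            inhibitions=inhibitions,
            residuals=inhibitions - pred,
            reached=reached,
            stimulation_flag=stim,
            notes=notes,
            per_dose=per_dose,
        )

    if method not in ("log-logistic", "interpolation"):
        raise ValueError(f"unknown method {method!r}")

    interp = _interpolate_ic50(doses, inhibitions)

    if method == "interpolation":
        if interp is None:
            return _result(float("nan"), float("nan"), "log-linear interpolation",
                           reached=False, notes="IC50 not reached")
        return _result(interp, float("nan"), "log-linear interpolation")

    # log-logistic least squares; dose 0 contributes (0, I0) with model value 0
    x0 = interp if interp is not None else (np.median(doses[doses > 0]) or 1.0)
    try:
        popt, _ = curve_fit(
            log_logistic_inhibition,
            doses,
            inhibitions,
            p0=[x0, 2.0],
            bounds=([1e-12, 1e-3], [np.inf, 50.0]),
            maxfev=10000,
        )
        ic50_fit, hill = float(popt[0]), float(popt[1])
    except RuntimeError:
        ic50_fit = None
        hill = float("nan")

    if ic50_fit is not None:
        notes = "" if np.any(inhibitions >= 50.0) else \
            "50% inhibition not observed; IC50 from fitted curve beyond data range"
        return _result(ic50_fit, hill, "log-logistic fit", notes=notes)
    if interp is not None:
        return _result(interp, float("nan"), "log-linear interpolation",
                       notes="log-logistic fit did not converge")
    return _result(float("nan"), float("nan"), "log-logistic fit",
                   reached=False, notes="IC50 not reached")
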