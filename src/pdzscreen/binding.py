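"""Quantitative binding and dose-response pharmacology.

Four pieces, matching the wet-lab validation of a PDZ protein-protein
interaction inhibitor:

* hyperbolic saturation binding, ``F(c) = F0 + Fmax * c / (Kd + c)`` — the
  model fitted to normalised FRET titrations of a dansylated peptide with
  increasing PDZ-domain concentration;
* the competitive-binding relation, ``Kd_app = Kd * (1 + [I]/Ki)``, and its
  inverse, used to turn a measured rightward Kd shift into an inhibition
  constant;
* the four-parameter logistic (4PL) dose-response curve,
  ``r(d) = bottom + (top − bottom) / (1 + (d/EC50)^hill)``, for EC50
  estimation by nonlinear regression;
* the cell-growth inhibition-rate transform,
  ``100 * (control − sample) / control``.

All concentrations are in μM.  Parameter standard errors come from the local
curvature (covariance) of the least-squares objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BindingCurve",
    "HyperbolicFit",
    "DoseResponse",
    "LogisticFit",
    "FitError",
    "fit_hyperbolic",
    "apparent_kd",
    "ki_from_shift",
    "fit_logistic",
    "inhibition_rate",
    "hyperbolic",
    "logistic4",
    "read_binding_csv",
    "read_dose_response_csv",
]


class FitError(RuntimeError):
    """Raised when a curve fit cannot be performed or does not converge."""


def hyperbolic(c: np.ndarray, kd: float, fmax: float, f0: float) -> np.ndarray:
    """Saturation binding curve F(c) = F0 + Fmax·c/(Kd + c)."""
    c = np.asarray(c, dtype=float)
    return f0 + fmax * c / (kd + c)


def logistic4(
    d: np.ndarray, ec50: float, hill: float, top: float, bottom: float
) -> np.ndarray:
    """Four-parameter logistic r(d) = bottom + (top−bottom)/(1 + (d/EC50)^hill)."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / ec50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass(frozen=True)
class BindingCurve:
    """One saturation titration: titrant concentrations (μM) vs signal.

    ``inhibitor_conc`` records the constant competitor concentration (μM),
    0 when absent.
    """

    concentrations: np.ndarray
    signal: np.ndarray
    inhibitor_conc: float = 0.0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if conc.ndim != 1 or conc.shape != sig.shape:
            raise ValueError("concentrations and signal must be equal-length 1-D")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")
        if len(np.unique(conc)) < 4:
            raise ValueError("need at least 4 distinct concentrations to fit")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "signal", sig)


@dataclass(frozen=True)
class HyperbolicFit:
    """Fitted saturation parameters (μM / signal units) and standard errors."""

    kd: float
    fmax: float
    f0: float
    kd_se: float
    fmax_se: float
    f0_se: float


@dataclass(frozen=True)
class DoseResponse:
    """One dose-response series: doses (μM) vs response, with replicate tag."""

    doses: np.ndarray
    response: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        if doses.ndim != 1 or doses.shape != resp.shape:
            raise ValueError("doses and response must be equal-length 1-D")
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        if len(np.unique(doses)) < 5:
            raise ValueError("need at least 5 distinct doses for a 4PL fit")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "response", resp)


@dataclass(frozen=True)
class LogisticFit:
    """Fitted 4PL parameters and standard errors."""

    ec50: float
    hill: float
    top: float
    bottom: float
    ec50_se: float
    hill_se: float
    top_se: float
    bottom_se: float


def fit_hyperbolic(curve: BindingCurve) -> HyperbolicFit:
    """Least-squares fit of the hyperbolic saturation model.

    Raises
    ------
    FitError
        When the signal is constant (no saturation information) or the
        optimiser fails to converge.
    """
    c, y = curve.concentrations, curve.signal
    if np.ptp(y) <= 1e-12 * max(1.0, abs(float(np.mean(y)))):
        raise FitError("constant signal: no saturation information to fit")
    f0_guess = float(y[np.argmin(c)])
    fmax_guess = float(y[np.argmax(c)] - f0_guess) or 1.0
    kd_guess = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
    try:
        popt, pcov = curve_fit(
            hyperbolic, c, y,
            p0=[kd_guess, fmax_guess, f0_guess],
            bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"hyperbolic fit failed: {exc}") from exc
    se = np.sqrt(np.abs(np.diag(pcov)))
    return HyperbolicFit(
        kd=float(popt[0]), fmax=float(popt[1]), f0=float(popt[2]),
        kd_se=float(se[0]), fmax_se=float(se[1]), f0_se=float(se[2]),
    )


def apparent_kd(kd: float, ki: float, inhibitor_conc: float) -> float:
    """Apparent Kd under competitive binding: ``Kd * (1 + [I]/Ki)`` (μM).

    Strictly increasing in the inhibitor concentration and decreasing in Ki;
    reduces to Kd when no inhibitor is present.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if ki <= 0:
        raise ValueError("Ki must be positive")
    if inhibitor_conc < 0:
        raise ValueError("inhibitor concentration must be non-negative")
    return kd * (1.0 + inhibitor_conc / ki)


def ki_from_shift(kd: float, kd_apparent: float, inhibitor_conc: float) -> float:
    """Inhibition constant from a competitive Kd shift (μM).

    Inverts ``Kd_app = Kd * (1 + [I]/Ki)``:
    ``Ki = [I] / (Kd_app/Kd − 1)``.  When the apparent Kd does not exceed
    the uninhibited Kd there is no measurable inhibition and ``math.inf`` is
    returned (a distinct condition, not an error).
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if inhibitor_conc <= 0:
        raise ValueError("inhibitor concentration must be positive")
    if kd_apparent <= kd:
        return math.inf  # no measurable inhibition
    return inhibitor_conc / (kd_apparent / kd - 1.0)


def fit_logistic(dr: DoseResponse) -> LogisticFit:
    """Least-squares 4PL fit of a dose-response series.

    Initialisation: top/bottom from the responses at the dose extremes, Hill
    slope 1, EC50 from the dose pair bracketing the half-range (geometric
    mean).  Bounds: EC50 > 0, Hill in [0.1, 10].

    Raises
    ------
    FitError
        On flat data (no dose dependence) or optimiser failure.
    """
    d, y = dr.doses, dr.response
    if np.ptp(y) <= 1e-12 * max(1.0, abs(float(np.mean(y)))):
        raise FitError("flat dose-response: no dose dependence to fit")
    order = np.argsort(d)
    d_sorted, y_sorted = d[order], y[order]
    top0 = float(y_sorted[0])      # 4PL form: response -> top as d -> 0
    bottom0 = float(y_sorted[-1])
    half = 0.5 * (top0 + bottom0)
    ec50_0 = _bracketing_dose(d_sorted, y_sorted, half)
    try:
        popt, pcov = curve_fit(
            logistic4, d, y,
            p0=[ec50_0, 1.0, top0, bottom0],
            bounds=([1e-12, 0.1, -np.inf, -np.inf], [np.inf, 10.0, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"4PL fit failed: {exc}") from exc
    se = np.sqrt(np.abs(np.diag(pcov)))
    return LogisticFit(
        ec50=float(popt[0]), hill=float(popt[1]),
        top=float(popt[2]), bottom=float(popt[3]),
        ec50_se=float(se[0]), hill_se=float(se[1]),
        top_se=float(se[2]), bottom_se=float(se[3]),
    )


def _bracketing_dose(d_sorted: np.ndarray, y_sorted: np.ndarray, half: float) -> float:
    """Geometric mean of the positive doses bracketing the half-response."""
    positive = d_sorted[d_sorted > 0]
    if positive.size == 0:
        return 1.0
    sign = np.sign(y_sorted - half)
    for k in range(len(d_sorted) - 1):
        if sign[k] != sign[k + 1]:
            lo = d_sorted[k] if d_sorted[k] > 0 else positive[0]
            return float(np.sqrt(lo * d_sorted[k + 1]))
    return float(np.sqrt(positive[0] * positive[-1]))


def inhibition_rate(control_od: float, sample_od: float) -> float:
    """Cell-growth inhibition in percent: ``100 * (control − sample)/control``.

    Negative values indicate growth stimulation; no clamping is applied.

    Raises
    ------
    ValueError
        When the control absorbance is not positive.
    """
    if control_od <= 0:
        raise ValueError("control OD must be positive")
    if sample_od < 0:
        raise ValueError("sample OD must be non-negative")
    return 100.0 * (control_od - sample_od) / control_od


# --------------------------------------------------------------------------
# CSV input
# --------------------------------------------------------------------------


def read_binding_csv(path: str | Path) -> BindingCurve:
    """Read a titration CSV with columns concentration_uM, signal
    [, inhibitor_uM] into a :class:`BindingCurve`."""
    df = pd.read_csv(path)
    required = {"concentration_uM", "signal"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    inhibitor = float(df["inhibitor_uM"].iloc[0]) if "inhibitor_uM" in df else 0.0
    return BindingCurve(
        concentrations=df["concentration_uM"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        inhibitor_conc=inhibitor,
    )


def read_dose_response_csv(path: str | Path) -> list[DoseResponse]:
    """Read a dose-response CSV (dose_uM, response[, replicate]) into one
    series per replicate."""
    df = pd.read_csv(path)
    required = {"dose_uM", "response"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if "replicate" not in df:
        df = df.assign(replicate=0)
    series = []
    for rep, grp in df.groupby("replicate", sort=True):
        series.append(
            DoseResponse(
                doses=grp["dose_uM"].to_numpy(float),
                response=grp["response"].to_numpy(float),
                replicate=int(rep),
            )
        )
    return series
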