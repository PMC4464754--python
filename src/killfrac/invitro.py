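"""In-vitro dose-response handling: IC50 fitting and kill ratios.

Dose-response curves (viability vs drug concentration) are fitted with the
standard four-parameter logistic (Hill) model

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)**hill),

whose IC50 is the concentration at half-maximal inhibition between the fitted
top and bottom plateaus.  The module also computes the fold difference in
IC50 between a drug-resistant and a drug-sensitive line, and the in-vitro
kill ratio (sensitive over resistant dead fraction) used to put in-vivo kill
measurements from the two lines on a common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "IC50Result",
    "fit_hill_ic50",
    "fold_difference",
    "invitro_kill_ratio",
    "read_dose_response",
    "DEFAULT_KILL_RATIO",
]

logger = logging.getLogger(__name__)

#: Default sensitive/resistant in-vitro kill ratio used for rescaling when no
#: direct cytotoxicity measurements are supplied.
DEFAULT_KILL_RATIO = 3.5


@dataclass(frozen=True)
class DoseResponseCurve:
    """Viability fractions measured over an ascending concentration series."""

    concentrations_nM: np.ndarray
    viability: np.ndarray
    line: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_nM, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        if c.shape != v.shape:
            raise ValueError("concentration and viability lengths differ")
        if c.size < 4:
            raise ValueError("at least 4 points are required for fitting")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly ascending")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("viability values must lie in [0, 1]")
        object.__setattr__(self, "concentrations_nM", c)
        object.__setattr__(self, "viability", v)


@dataclass(frozen=True)
class IC50Result:
    ic50_nM: float
    hill_slope: float
    top: float
    bottom: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if not self.ic50_nM > 0:
                raise ValueError("fitted ic50 must be positive")
            if self.bottom > self.top:
                raise ValueError("bottom plateau must not exceed top")


def _four_pl(c, top, bottom, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + (c / 10.0**log_ic50) ** hill)


def fit_hill_ic50(curve: DoseResponseCurve) -> IC50Result:
    """Fit the four-parameter logistic and return the IC50.

    Non-convergence (including degenerate flat curves) is reported through
    ``converged=False`` with a diagnostic message, never silently.
    """
    c = curve.concentrations_nM
    v = curve.viability
    if np.ptp(v) < 1e-9:
        return IC50Result(
            np.nan, np.nan, np.nan, np.nan, False, "viability shows no decline"
        )
    # mid-point crossing as IC50 initial guess (log-spaced series)
    mid = (v.max() + v.min()) / 2.0
    idx = int(np.argmin(np.abs(v - mid)))
    p0 = [float(v.max()), float(v.min()), float(np.log10(c[idx])), 1.0]
    lo = [0.0, 0.0, np.log10(c[0]) - 3.0, 0.05]
    hi = [1.5, 1.0, np.log10(c[-1]) + 3.0, 10.0]
    try:
        popt, _ = curve_fit(
            _four_pl, c, v, p0=p0, bounds=(lo, hi), maxfev=20000,
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
    except (RuntimeError, ValueError) as exc:
        return IC50Result(np.nan, np.nan, np.nan, np.nan, False, str(exc))
    top, bottom, log_ic50, hill = popt
    if bottom > top:
        top, bottom = bottom, top
    return IC50Result(
        ic50_nM=float(10.0**log_ic50),
        hill_slope=float(hill),
        top=float(top),
        bottom=float(bottom),
        converged=True,
    )


def fold_difference(ic50_resistant_nM: float, ic50_sensitive_nM: float) -> float:
    """Fold difference in drug response between the two lines (always >= 1).

    By convention the resistant line carries the larger IC50; the ratio is
    taken larger over smaller so a swapped argument order cannot produce a
    fold change below 1.
    """
    if ic50_resistant_nM <= 0 or ic50_sensitive_nM <= 0:
        raise ValueError("IC50 values must be positive")
    hi, lo = ic50_resistant_nM, ic50_sensitive_nM
    if hi < lo:
        logger.warning("resistant IC50 below sensitive IC50; taking larger/smaller")
        hi, lo = lo, hi
    return hi / lo


def invitro_kill_ratio(
    dead_fraction_sensitive: float, dead_fraction_resistant: float
) -> float:
    """Ratio of drug-induced cell death, sensitive over resistant line."""
    if dead_fraction_resistant <= 0:
        raise ZeroDivisionError(
            "resistant dead fraction is zero; consider the configured default "
            f"ratio {DEFAULT_KILL_RATIO}"
        )
    if dead_fraction_sensitive < 0:
        raise ValueError("dead fractions must be non-negative")
    return dead_fraction_sensitive / dead_fraction_resistant


def read_dose_response(path) -> dict[str, DoseResponseCurve]:
    """Read doseresponse.csv (line, concentration_nM, viability_fraction[,
    replicate]) into one averaged curve per line."""
    frame = pd.read_csv(path)
    required = {"line", "concentration_nM", "viability_fraction"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"dose-response table missing columns: {sorted(missing)}")
    curves: dict[str, DoseResponseCurve] = {}
    for line, grp in frame.groupby("line"):
        avg = (
            grp.groupby("concentration_nM")["viability_fraction"]
            .mean()
            .sort_index()
        )
        curves[line] = DoseResponseCurve(
            concentrations_nM=avg.index.to_numpy(float),
            viability=np.clip(avg.to_numpy(float), 0.0, 1.0),
            line=str(line),
        )
    return curves
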