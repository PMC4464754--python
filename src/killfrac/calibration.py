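"""Calibration of the kill-fraction model to per-section histology data.

The observations are per-section (BVF, dead tissue fraction) points for a
drug-sensitive and a drug-resistant lymphoma line.  Because the model's
cell-intrinsic factor fkill_m is measured for the sensitive line, the
resistant points are first rescaled by the in-vitro kill ratio (sensitive
over resistant, default 3.5) so both lines share one fkill_m; the pooled
points are then fitted by bounded nonlinear least squares for the two free
parameters fkill_m and r_b/L, with multistart to guard against the flat
likelihood in r_b/L at small values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import kill_fraction_scaled

__all__ = [
    "KillPoint",
    "KillDataset",
    "CalibrationResult",
    "rescale_resistant",
    "fit_kill_model",
    "r_squared",
    "read_kill_data",
    "DEFAULT_BOUNDS",
]

logger = logging.getLogger(__name__)

#: (lower, upper) box for (fkill_m, rb_over_L)
DEFAULT_BOUNDS = ((0.0, 1e-3), (1.0, 2.0))


@dataclass(frozen=True)
class KillPoint:
    line: str
    section_index: int
    bvf: float
    dead_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.bvf < 1.0:
            raise ValueError(f"bvf must lie in (0, 1), got {self.bvf}")
        if self.dead_fraction < 0:
            raise ValueError("dead_fraction must be non-negative")


@dataclass(frozen=True)
class KillDataset:
    """Per-section (BVF, dead fraction) observations, optionally rescaled."""

    points: tuple[KillPoint, ...]
    rescaled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        for p in self.points:
            if not self.rescaled and p.dead_fraction > 1.0:
                raise ValueError(
                    "dead_fraction above 1 only permitted after rescaling"
                )

    @property
    def bvf(self) -> np.ndarray:
        return np.array([p.bvf for p in self.points])

    @property
    def dead_fraction(self) -> np.ndarray:
        return np.array([p.dead_fraction for p in self.points])

    def subset(self, line: str) -> "KillDataset":
        return KillDataset(
            tuple(p for p in self.points if p.line == line), self.rescaled
        )


@dataclass(frozen=True)
class CalibrationResult:
    fkill_m_hat: float
    rb_over_L_hat: float
    r_squared: float
    residuals: np.ndarray
    iterations: int
    converged: bool
    covariance: np.ndarray | None = None
    restart_costs: tuple[float, ...] = field(default_factory=tuple)

    def predicted(self, bvf) -> np.ndarray:
        return self.fkill_m_hat * kill_fraction_scaled(bvf, self.rb_over_L_hat)

    def to_dict(self) -> dict:
        return {
            "fkill_m_hat": self.fkill_m_hat,
            "rb_over_L_hat": self.rb_over_L_hat,
            "r_squared": self.r_squared,
            "residuals": list(map(float, self.residuals)),
            "iterations": self.iterations,
            "converged": self.converged,
            "covariance": None
            if self.covariance is None
            else [list(map(float, row)) for row in self.covariance],
            "restart_costs": list(map(float, self.restart_costs)),
        }


def rescale_resistant(data: KillDataset, factor: float) -> KillDataset:
    """Multiply drug-resistant dead fractions by the in-vitro kill ratio.

    Sensitive points are untouched.  Rescaled values above 1 are kept (they
    are on the sensitive-equivalent scale) but logged.
    """
    if factor <= 0:
        raise ValueError("rescale factor must be positive")
    if data.rescaled:
        raise ValueError("dataset is already rescaled")
    points = []
    for p in data.points:
        if p.line == "resistant":
            new = p.dead_fraction * factor
            if new > 1.0:
                logger.warning(
                    "rescaled dead_fraction %.3f exceeds 1 for section %d",
                    new,
                    p.section_index,
                )
            p = dataclasses.replace(p, dead_fraction=new)
        points.append(p)
    return KillDataset(tuple(points), rescaled=True)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must share length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_kill_model(
    data: KillDataset,
    init: tuple[float, float] | None = None,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    multistart: int = 10,
    seed: int = 0,
    weights=None,
) -> CalibrationResult:
    """Bounded least-squares fit of (fkill_m, rb_over_L) to kill data.

    Minimizes ``sum((dead_fraction - fkill_m * g(bvf; rb_over_L))**2)`` where
    ``g`` is the annulus-averaged concentration.  ``multistart`` restarts are
    drawn with fkill_m uniform on its box and rb_over_L log-uniform on its
    box; the lowest-cost solution wins.  Deterministic for a given seed.
    """
    bvf = data.bvf
    dead = data.dead_fraction
    if bvf.size < 3:
        raise ValueError("at least 3 points are required")
    if np.ptp(bvf) == 0:
        raise ValueError(
            "all BVF values identical: fkill_m and rb_over_L are not "
            "jointly identifiable"
        )
    w = np.ones_like(dead) if weights is None else np.asarray(weights, float)
    (lo_f, lo_r), (hi_f, hi_r) = bounds

    def residual(theta):
        fm, rb = theta
        return w * (dead - fm * kill_fraction_scaled(bvf, rb))

    rng = np.random.default_rng(seed)
    starts = [init if init is not None else (0.2, 0.1)]
    for _ in range(max(0, multistart - 1)):
        starts.append(
            (
                rng.uniform(lo_f, hi_f),
                float(np.exp(rng.uniform(np.log(lo_r), np.log(hi_r)))),
            )
        )

    best = None
    costs = []
    iterations = 0
    for x0 in starts:
        x0 = (min(max(x0[0], lo_f), hi_f), min(max(x0[1], lo_r), hi_r))
        try:
            sol = least_squares(
                residual,
                x0=x0,
                bounds=([lo_f, lo_r], [hi_f, hi_r]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception as exc:  # propagate as diagnostics, not silence
            costs.append(float("inf"))
            logger.warning("restart at %s failed: %s", x0, exc)
            continue
        costs.append(float(sol.cost))
        iterations += int(sol.nfev)
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    if best is None:
        return CalibrationResult(
            np.nan,
            np.nan,
            np.nan,
            np.full_like(dead, np.nan),
            iterations,
            converged=False,
            restart_costs=tuple(costs),
        )

    fm_hat, rb_hat = best.x
    pred = fm_hat * kill_fraction_scaled(bvf, rb_hat)
    resid = dead - pred
    # Gauss-Newton covariance: s^2 (J^T J)^-1, guarded for rank deficiency
    cov = None
    dof = bvf.size - 2
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (2 * best.cost / dof)
        except np.linalg.LinAlgError:
            cov = None
    return CalibrationResult(
        fkill_m_hat=float(fm_hat),
        rb_over_L_hat=float(rb_hat),
        r_squared=r_squared(dead, pred),
        residuals=resid,
        iterations=iterations,
        converged=True,
        covariance=cov,
        restart_costs=tuple(costs),
    )


def read_kill_data(path, convention: str = "fraction") -> KillDataset:
    """Read killdata.csv (line, section_index, bvf, dead_fraction).

    ``convention`` declares whether bvf/dead_fraction columns carry fractions
    in [0, 1] or percentages; percentages are divided by 100 on read.
    """
    if convention not in ("fraction", "percent"):
        raise ValueError("convention must be 'fraction' or 'percent'")
    frame = pd.read_csv(path)
    required = {"line", "section_index", "bvf", "dead_fraction"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"kill data table missing columns: {sorted(missing)}")
    scale = 0.01 if convention == "percent" else 1.0
    points = tuple(
        KillPoint(
            line=row.line,
            section_index=int(row.section_index),
            bvf=float(row.bvf) * scale,
            dead_fraction=float(row.dead_fraction) * scale,
        )
        for row in frame.itertuples()
    )
    return KillDataset(points)
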