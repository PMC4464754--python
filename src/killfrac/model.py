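"""Closed-form drug-kill model for a vascularized tumor.

The model treats each blood vessel as a straight cylinder of radius ``r_b``
feeding a surrounding Krogh-type tissue cylinder of radius
``r_t = r_b / sqrt(BVF)``, where BVF is the blood volume fraction.  After
extravasation the drug obeys a steady-state diffusion-uptake balance

    (1/r) d/dr (r dsigma/dr) = sigma / L**2,

with ``L = sqrt(D / lambda)`` the diffusion penetration distance (``D`` drug
diffusivity, ``lambda`` cellular uptake rate).  With the radial coordinate
scaled by ``L``, the concentration decaying away from the vessel is

    sigma(r) / sigma0 = K0(r) / K0(r_b),

where ``K0`` is the modified Bessel function of the second kind.  Averaging
the profile over the tissue annulus and multiplying by the in-vitro kill
fraction ``fkill_m`` gives the fraction of tumor volume killed in closed form:

    f_kill = fkill_m * BVF * [2*sqrt(BVF)*K1(rb) - 2*K1(rb/sqrt(BVF))]
             / [sqrt(BVF) * rb * K0(rb) * (1 - BVF)],      rb = r_b / L.

All lengths are carried internally in micrometres and all fractions in
``[0, 1]``; percentages appear only at I/O boundaries.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.special import k0e, k1e

__all__ = [
    "ModelParams",
    "ConcentrationProfile",
    "TissueGeometry",
    "NumericsError",
    "scaled_concentration",
    "concentration_profile",
    "kill_fraction",
    "kill_fraction_scaled",
    "kill_fraction_oracle",
    "predict_curve",
]

#: Above this blood volume fraction the annulus is numerically degenerate and
#: the analytic limit f_kill -> fkill_m is returned instead of evaluating 0/0.
BVF_LIMIT_GUARD = 1.0 - 1e-6


class NumericsError(RuntimeError):
    """Raised when a numerical routine (quadrature) fails to converge."""


@dataclass(frozen=True)
class ModelParams:
    """The four tumor-specific parameters driving the kill-fraction model.

    Parameters
    ----------
    bvf
        Blood volume fraction, dimensionless, in (0, 1).
    rb_um
        Mean blood vessel radius in micrometres.
    L_um
        Drug diffusion penetration distance ``sqrt(D/lambda)`` in micrometres.
    fkill_m
        Maximal kill fraction measured in monolayer culture at the matched
        drug concentration; the model is linear in this factor.
    D_um2_s, lambda_per_s
        Optional diffusivity (um^2/s) and uptake rate (1/s).  When both are
        given they must satisfy ``L_um = sqrt(D/lambda)`` to 1e-9 relative.
    """

    bvf: float
    rb_um: float
    L_um: float
    fkill_m: float
    D_um2_s: float | None = None
    lambda_per_s: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.bvf < 1.0:
            raise ValueError(f"bvf must lie in (0, 1), got {self.bvf}")
        if self.rb_um <= 0.0:
            raise ValueError(f"rb_um must be positive, got {self.rb_um}")
        if self.L_um <= 0.0:
            raise ValueError(f"L_um must be positive, got {self.L_um}")
        if not 0.0 <= self.fkill_m <= 1.0:
            raise ValueError(f"fkill_m must lie in [0, 1], got {self.fkill_m}")
        if self.D_um2_s is not None and self.lambda_per_s is not None:
            implied = math.sqrt(self.D_um2_s / self.lambda_per_s)
            if abs(implied - self.L_um) > 1e-9 * self.L_um:
                raise ValueError(
                    f"L_um={self.L_um} inconsistent with sqrt(D/lambda)={implied}"
                )

    @property
    def rb_over_L(self) -> float:
        """Vessel radius scaled by the penetration distance, ``r_b / L``."""
        return self.rb_um / self.L_um

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TissueGeometry:
    """Single-vessel Krogh geometry in units of the penetration distance L."""

    rb_scaled: float
    rt_scaled: float

    @classmethod
    def from_params(cls, params: ModelParams) -> "TissueGeometry":
        rb = params.rb_over_L
        return cls(rb_scaled=rb, rt_scaled=rb / math.sqrt(params.bvf))

    def __post_init__(self) -> None:
        if self.rt_scaled <= self.rb_scaled:
            raise ValueError("tissue radius must exceed vessel radius")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Normalized drug concentration sigma/sigma0 sampled on a radial grid."""

    scaled_radii: np.ndarray
    normalized_concentration: np.ndarray
    sigma0: float = 1.0

    def __post_init__(self) -> None:
        r = np.asarray(self.scaled_radii, dtype=float)
        c = np.asarray(self.normalized_concentration, dtype=float)
        if r.shape != c.shape:
            raise ValueError("radii and concentration arrays must align")
        if np.any(np.diff(r) <= 0):
            raise ValueError("scaled_radii must be strictly increasing")
        if np.any(c <= 0) or np.any(c > 1 + 1e-12):
            raise ValueError("normalized concentration must lie in (0, 1]")
        object.__setattr__(self, "scaled_radii", r)
        object.__setattr__(self, "normalized_concentration", c)


def scaled_concentration(r_scaled, rb_over_L: float):
    """Normalized drug concentration ``sigma/sigma0 = K0(r)/K0(rb)``.

    ``r_scaled`` is the radial coordinate in units of L and may be a scalar or
    array; every value must be >= ``rb_over_L``.  The exponentially scaled
    Bessel forms are used so the ratio stays finite for large arguments.
    """
    if rb_over_L <= 0:
        raise ValueError(f"rb_over_L must be positive, got {rb_over_L}")
    r = np.asarray(r_scaled, dtype=float)
    if np.any(r < rb_over_L):
        raise ValueError(
            f"r_scaled must be >= rb_over_L={rb_over_L}, got min {r.min()}"
        )
    # K0(r)/K0(rb) = [k0e(r) e^-r] / [k0e(rb) e^-rb]
    out = k0e(r) / k0e(rb_over_L) * np.exp(-(r - rb_over_L))
    return out if out.ndim else float(out)


def concentration_profile(
    rb_over_L: float, r_max_scaled: float = 5.0, num: int = 200
) -> ConcentrationProfile:
    """Sample the normalized concentration on a grid from the vessel wall."""
    radii = np.linspace(rb_over_L, r_max_scaled, num)
    return ConcentrationProfile(radii, scaled_concentration(radii, rb_over_L))


def kill_fraction_scaled(bvf, rb_over_L):
    """Annulus-averaged normalized concentration, i.e. ``f_kill / fkill_m``.

    Vectorized over ``bvf`` and ``rb_over_L``.  Uses exponentially scaled
    Bessel functions throughout, so large ``rb_over_L`` underflows gracefully
    to 0 rather than producing NaN.
    """
    bvf = np.asarray(bvf, dtype=float)
    rb = np.asarray(rb_over_L, dtype=float)
    if np.any(bvf <= 0) or np.any(bvf >= 1):
        raise ValueError("bvf must lie in (0, 1)")
    if np.any(rb <= 0):
        raise ValueError("rb_over_L must be positive")
    bvf, rb = np.broadcast_arrays(bvf, rb)
    s = np.sqrt(bvf)
    rt = rb / s
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        num = 2.0 * s * k1e(rb) - 2.0 * k1e(rt) * np.exp(-(rt - rb))
        den = s * rb * k0e(rb) * (1.0 - bvf)
        direct = bvf * num / den
        # Small rb/L: the two K1 terms cancel at leading order (both ~1/rb),
        # so evaluate the annulus average by the small-argument expansion
        # x*K1(x) = 1 + (x^2/2)[ln(x/2) + gamma - 1/2] + O(x^4 ln x), which
        # reduces to a ratio of logarithms.
        ell = np.log(rb / 2.0) + np.euler_gamma - 0.5
        series = (-(1.0 - bvf) * ell + 0.5 * np.log(bvf)) / (
            (1.0 - bvf) * k0e(rb) * np.exp(-rb)
        )
        out = np.where(rb < 1e-4, series, direct)
        out = np.where(bvf > BVF_LIMIT_GUARD, 1.0, out)
    if np.any(~np.isfinite(out)):
        raise NumericsError("Bessel evaluation produced non-finite kill fraction")
    return out if out.ndim else float(out)


def kill_fraction(params: ModelParams) -> float:
    """Fraction of tumor volume killed, closed form.

    For ``bvf`` above the degeneracy guard the analytic limit ``fkill_m`` is
    returned (the annulus vanishes and the average concentration tends to the
    vessel-wall value).
    """
    return params.fkill_m * float(kill_fraction_scaled(params.bvf, params.rb_over_L))


def kill_fraction_oracle(params: ModelParams, tol: float = 1e-10) -> float:
    """Kill fraction by direct adaptive quadrature of the concentration profile.

    Independent of the closed form: integrates ``x * K0(x) / K0(rb)`` over the
    annulus ``[rb, rt]`` and area-averages.  Serves as the verification oracle
    for :func:`kill_fraction`.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if params.bvf > BVF_LIMIT_GUARD:
        return params.fkill_m
    rb = params.rb_over_L
    rt = rb / math.sqrt(params.bvf)

    def integrand(x: float) -> float:
        # x * K0(x) with the e^-rb reference factored out for stability
        return x * k0e(x) * math.exp(-(x - rb))

    val, err = quad(integrand, rb, rt, epsabs=tol, epsrel=tol, limit=500)
    if not math.isfinite(val) or (val > 0 and err > 1e-6 * val + 1e-12):
        raise NumericsError(
            f"quadrature failed to converge: value={val}, abserr={err}"
        )
    avg = 2.0 * val / ((rt**2 - rb**2) * k0e(rb))
    return params.fkill_m * avg


def predict_curve(
    fkill_m: float, rb_over_L: float, bvf_grid: Sequence[float]
) -> np.ndarray:
    """Predicted kill fraction along a sorted grid of blood volume fractions."""
    grid = np.asarray(bvf_grid, dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValueError("bvf_grid must be strictly increasing")
    if not 0.0 <= fkill_m <= 1.0:
        raise ValueError(f"fkill_m must lie in [0, 1], got {fkill_m}")
    return fkill_m * kill_fraction_scaled(grid, rb_over_L)
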