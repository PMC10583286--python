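"""Hahn-echo rate analysis: decay fitting, field regression, ξ-space.

The pipeline for one methyl group is

1. :func:`fit_decay` — exponential fits of peak amplitudes vs relaxation
   delay, per coherence and field, yielding rates with standard errors;
2. :func:`regress_field` — weighted linear regression of rates vs B0²,
   R_2,obs = R_2,0 + (β_CSA + β_ex)·B0²;
3. :func:`subtract_csa` — removal of the CSA slope to isolate β_ex, which
   constrains (ξH, ξC) to the line pair ξC + n_H·ξH = ±√β_ex;
4. :func:`chi2_surface` — χ²(ξH, ξC) over all four coherences with the
   per-coherence intercepts R_2,0 profiled out in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.optimize import curve_fit

from .constants import Coherence, FieldSpec, MQ_COHERENCES
from .rates import MethylSystem, XiPair, csa_contribution

__all__ = [
    "DecayCurve", "RateMeasurement", "FieldRegression", "XiConstraint",
    "fit_decay", "regress_field", "subtract_csa", "chi2_surface",
    "Chi2Surface", "CONF_DELTA_CHI2",
]

#: Δχ² thresholds for joint 68 % / 95 % confidence regions of 2 parameters
CONF_DELTA_CHI2 = {0.68: 2.30, 0.95: 6.18}


@dataclass(frozen=True)
class DecayCurve:
    """Peak amplitude vs relaxation delay for one coherence at one field."""

    times: np.ndarray          # s, strictly increasing, >= 0
    amplitudes: np.ndarray     # arbitrary units
    sigma: float               # amplitude noise (same units)
    coherence: Coherence
    fieldspec: FieldSpec
    methyl_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)
        if t.size < 4:
            raise ValueError("need at least 4 delay points")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative, strictly increasing")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class RateMeasurement:
    """One fitted relaxation rate observation."""

    methyl_id: str
    coherence: Coherence
    fieldspec: FieldSpec
    rate: float        # s-1
    err: float         # s-1, standard error (> 0)
    converged: bool = True

    def __post_init__(self) -> None:
        if self.err <= 0:
            raise ValueError("err must be positive")


@dataclass(frozen=True)
class FieldRegression:
    """Weighted straight-line fit of R_2,obs vs B0²."""

    intercept: float   # R_2,0 plus any field-independent part, s-1
    slope: float       # β_CSA + β_ex, s-1 T-2
    cov: np.ndarray    # 2x2 covariance of (intercept, slope)

    @property
    def intercept_err(self) -> float:
        return math.sqrt(self.cov[0, 0])

    @property
    def slope_err(self) -> float:
        return math.sqrt(self.cov[1, 1])


@dataclass(frozen=True)
class XiConstraint:
    """The line pair ξC + n_H·ξH = ±√β_ex from one coherence."""

    n_h: int
    beta_ex: float          # s-1 T-2
    beta_ex_err: float
    exchange_flag: str = "ok"   # "ok" | "no_exchange_or_csa_overestimate"

    def lines(self) -> tuple[float, float] | None:
        """The two roots ±√β_ex, or None when β_ex < 0."""
        if self.beta_ex < 0:
            return None
        r = math.sqrt(self.beta_ex)
        return (r, -r)


def fit_decay(curve: DecayCurve) -> RateMeasurement:
    """Weighted least-squares fit of A·exp(−R·T) to one decay curve.

    The standard error of R comes from the fit covariance scaled by the
    supplied amplitude noise (absolute_sigma). Non-convergence is flagged
    on the result rather than raising or returning NaN.
    """
    t, a = curve.times, curve.amplitudes
    # log-linear start (guard against non-positive amplitudes)
    pos = a > 0
    if pos.sum() >= 2:
        b = np.polyfit(t[pos], np.log(a[pos]), 1)
        p0 = (math.exp(b[1]), max(-b[0], 0.0))
    else:
        p0 = (float(a[0]) if a[0] > 0 else 1.0, 1.0)
    try:
        popt, pcov = curve_fit(
            lambda x, amp, rate: amp * np.exp(-rate * x), t, a, p0=p0,
            sigma=np.full(t.size, curve.sigma), absolute_sigma=True,
            maxfev=10000)
        err = math.sqrt(pcov[1, 1])
        ok = np.isfinite(err) and err > 0
        if not ok:
            err = abs(popt[1]) if popt[1] != 0 else 1.0
        return RateMeasurement(curve.methyl_id, curve.coherence,
                               curve.fieldspec, float(popt[1]), float(err),
                               converged=bool(ok))
    except RuntimeError:
        return RateMeasurement(curve.methyl_id, curve.coherence,
                               curve.fieldspec, float("nan"), 1.0,
                               converged=False)


def regress_field(measurements: list[RateMeasurement]) -> FieldRegression:
    """Inverse-variance-weighted linear regression of rate vs B0²."""
    fields = {m.fieldspec.larmor_h for m in measurements}
    if len(fields) < 3:
        raise ValueError(
            f"need measurements at >= 3 distinct fields, got {len(fields)}")
    x = np.array([m.fieldspec.b0 ** 2 for m in measurements])
    y = np.array([m.rate for m in measurements])
    w = np.array([1.0 / m.err for m in measurements])
    coef, cov = np.polyfit(x, y, 1, w=w, cov="unscaled")
    # polyfit returns highest degree first
    return FieldRegression(intercept=float(coef[1]), slope=float(coef[0]),
                           cov=cov[::-1, ::-1].copy())


def _beta_csa(system: MethylSystem, coherence: Coherence) -> float:
    """CSA slope coefficient (per T²): csa_contribution / B0²."""
    unit = FieldSpec(600.0)
    return csa_contribution(coherence, system, unit) / unit.b0 ** 2


def subtract_csa(reg: FieldRegression, system: MethylSystem,
                 coherence: Coherence,
                 dsigma_c_err: float = 0.0, dsigma_h_err: float = 0.0,
                 s2tau_err: float = 0.0) -> XiConstraint:
    """Remove the CSA slope to isolate the pure exchange slope β_ex.

    β_ex = slope − (4/45)(γCΔσC + n_H·γHΔσH)²·S²τc (per-T² form). Errors
    in the CSA parameters and S²τc propagate to β_ex by first-order
    expansion alongside the regression slope error. A β_ex more than 2σ
    below zero is flagged (no detectable exchange / CSA overestimate).
    """
    beta_csa = _beta_csa(system, coherence)
    beta_ex = reg.slope - beta_csa
    # first-order sensitivities of the CSA term
    var = reg.slope_err ** 2
    if system.s2tau > 0:
        var += (beta_csa / system.s2tau * s2tau_err) ** 2
    h = 1e-6
    for name, delta_err in (("dsigma_c", dsigma_c_err),
                            ("dsigma_h", dsigma_h_err)):
        if delta_err:
            base = getattr(system, name)
            bumped = MethylSystem(
                s2tau=system.s2tau,
                dsigma_c=system.dsigma_c + (h if name == "dsigma_c" else 0.0),
                dsigma_h=system.dsigma_h + (h if name == "dsigma_h" else 0.0))
            grad = (_beta_csa(bumped, coherence) - beta_csa) / h
            var += (grad * delta_err) ** 2
    err = math.sqrt(var)
    flag = "ok"
    if beta_ex < -2.0 * err:
        flag = "no_exchange_or_csa_overestimate"
    return XiConstraint(n_h=coherence.n_h, beta_ex=beta_ex,
                        beta_ex_err=err, exchange_flag=flag)


@dataclass
class Chi2Surface:
    """χ²(ξH, ξC) surface with confidence levels and the ± minimum pair."""

    xi_h: np.ndarray           # grid axis (per T)
    xi_c: np.ndarray
    chi2: np.ndarray           # shape (len(xi_c), len(xi_h))
    min_chi2: float
    minima: tuple[tuple[float, float], tuple[float, float]]  # ±(ξH, ξC)

    def levels(self) -> dict[float, float]:
        """Absolute χ² thresholds of the 68 % and 95 % contours."""
        return {p: self.min_chi2 + d for p, d in CONF_DELTA_CHI2.items()}

    def confidence_mask(self, level: float = 0.95) -> np.ndarray:
        return self.chi2 <= self.levels()[level]

    def contains(self, xi: XiPair, level: float = 0.95) -> bool:
        """Whether a (ξH, ξC) point (either sign) lies inside a contour.

        The point is mapped to the nearest grid node; both sign images are
        checked since the surface is symmetric under global sign flip.
        """
        mask = self.confidence_mask(level)
        for sgn in (1.0, -1.0):
            ih = int(np.argmin(np.abs(self.xi_h - sgn * xi.xi_h)))
            ic = int(np.argmin(np.abs(self.xi_c - sgn * xi.xi_c)))
            if mask[ic, ih]:
                return True
        return False


def chi2_surface(measurements: dict[Coherence, list[RateMeasurement]],
                 system: MethylSystem,
                 xi_h: np.ndarray | None = None,
                 xi_c: np.ndarray | None = None,
                 coherences: tuple[Coherence, ...] = MQ_COHERENCES,
                 n_grid: int = 301) -> Chi2Surface:
    """χ² over an (ξH, ξC) grid with per-coherence R_2,0 profiled out.

    At each grid point the exchange slope of coherence n is fixed to
    β_ex = (ξC + n·ξH)²; added to the CSA slope it defines a straight line
    in B0² whose intercept (the exchange-free rate R_2,0) is profiled out
    by the weighted closed form. χ² sums over the requested coherences and
    all fields. Negative measured slopes need no special handling: the
    model slope is bounded below by β_CSA, which simply raises the χ²
    floor.
    """
    stats = {}
    beta_max = 0.0
    for coh in coherences:
        ms = measurements.get(coh)
        if not ms:
            raise ValueError(f"no measurements for {coh.name}")
        if len({m.fieldspec.larmor_h for m in ms}) < 3:
            raise ValueError(f"{coh.name}: need >= 3 distinct fields")
        x = np.array([m.fieldspec.b0 ** 2 for m in ms])
        y = np.array([m.rate for m in ms])
        w = np.array([1.0 / m.err ** 2 for m in ms])
        wsum = w.sum()
        xbar = (w * x).sum() / wsum
        ybar = (w * y).sum() / wsum
        dx, dy = x - xbar, y - ybar
        stats[coh] = (float((w * dy * dy).sum()), float((w * dx * dy).sum()),
                      float((w * dx * dx).sum()), _beta_csa(system, coh))
        slope = stats[coh][1] / stats[coh][2]
        beta_max = max(beta_max, abs(slope - stats[coh][3]))
    if xi_h is None or xi_c is None:
        span = 1.5 * math.sqrt(beta_max) if beta_max > 0 else 1.0
        xi_h = np.linspace(-span, span, n_grid) if xi_h is None else xi_h
        xi_c = np.linspace(-span, span, n_grid) if xi_c is None else xi_c
    xi_h = np.asarray(xi_h, dtype=float)
    xi_c = np.asarray(xi_c, dtype=float)
    if xi_h.size == 0 or xi_c.size == 0:
        raise ValueError("empty grid")

    xh = xi_h[None, :]
    xc = xi_c[:, None]
    chi2 = np.zeros((xi_c.size, xi_h.size))
    for coh in coherences:
        syy, sxy, sxx, bcsa = stats[coh]
        beta = bcsa + (xc + coh.n_h * xh) ** 2
        chi2 += syy - 2.0 * beta * sxy + beta * beta * sxx

    imin = np.unravel_index(np.argmin(chi2), chi2.shape)
    best = (float(xi_h[imin[1]]), float(xi_c[imin[0]]))
    minima = (best, (-best[0], -best[1]))
    return Chi2Surface(xi_h=xi_h, xi_c=xi_c, chi2=chi2,
                       min_chi2=float(chi2[imin]), minima=minima)
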