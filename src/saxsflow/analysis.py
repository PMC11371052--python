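"""Curve-level SAXS analysis.

Implements the classical small-angle toolbox on 1-D profiles: ROI intensity
summation, single-peak fitting (Gaussian + linear baseline), the Guinier
approximation ``I(q) = I0 exp(-q^2 Rg^2 / 3)`` at low q, the Porod tail
``I(q) = K / q^4 + B`` at high q, the integral invariant
``Q = \\int_0^inf q^2 I(q) dq`` assembled from a Guinier extrapolation below
the measured range, trapezoidal quadrature on the (background-corrected)
data, and the closed-form Porod tail ``K / q_max`` above it, and the
T parameter ``T = 4 Q / (pi K)`` — the mean chord length / volume-to-surface
measure of an ideal two-phase system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad

from .reduction import Curve

__all__ = [
    "GuinierResult",
    "PorodResult",
    "InvariantResult",
    "PeakFitResult",
    "MissingDependencyError",
    "roi_intensity",
    "fit_single_peak",
    "guinier_fit",
    "porod_fit",
    "integral_invariant",
    "t_parameter",
]


class MissingDependencyError(RuntimeError):
    """An analysis step requires the result of an upstream step that is absent."""


@dataclass(frozen=True)
class GuinierResult:
    rg: float                       # radius of gyration, A
    i0: float                       # forward-scattering intensity
    fit_range: tuple[float, float]  # (q_min, q_max) actually used
    qmax_rg: float                  # q_max * Rg
    r_squared: float
    n_points: int

    def as_dict(self) -> dict:
        return {"Rg": self.rg, "I0": self.i0, "q_min": self.fit_range[0],
                "q_max": self.fit_range[1], "qmaxRg": self.qmax_rg,
                "r_squared": self.r_squared}


@dataclass(frozen=True)
class PorodResult:
    k: float                        # Porod constant, I * q^4 units
    b: float                        # flat background intensity
    fit_range: tuple[float, float]

    def as_dict(self) -> dict:
        return {"K": self.k, "B": self.b,
                "q_min": self.fit_range[0], "q_max": self.fit_range[1]}


@dataclass(frozen=True)
class InvariantResult:
    q_inv: float                    # \int q^2 I dq, I * q^3 units
    parts: tuple[float, float, float]   # (low-q extrapolated, measured, tail)

    def as_dict(self) -> dict:
        low, mid, high = self.parts
        return {"Q_inv": self.q_inv, "Q_low": low, "Q_measured": mid,
                "Q_tail": high}


@dataclass(frozen=True)
class PeakFitResult:
    amplitude: float
    center: float
    sigma: float
    baseline_intercept: float
    baseline_slope: float
    area: float                     # amplitude * sigma * sqrt(2 pi)
    stderr: dict                    # per-parameter 1-sigma uncertainties
    r_squared: float
    converged: bool

    def as_dict(self) -> dict:
        return {"amplitude": self.amplitude, "center": self.center,
                "sigma": self.sigma, "area": self.area,
                "baseline_intercept": self.baseline_intercept,
                "baseline_slope": self.baseline_slope,
                "r_squared": self.r_squared}


# -- ROI intensity -----------------------------------------------------------

def roi_intensity(curve: Curve, lo: float, hi: float) -> tuple[float, int]:
    """Sum of intensities over points with ``lo <= x <= hi`` (closed interval).

    Returns ``(sum, n_points)``; an ROI containing no curve points is an
    error rather than a silent zero.
    """
    if lo >= hi:
        raise ValueError(f"ROI lower bound {lo} must be below upper bound {hi}")
    sel = (curve.x >= lo) & (curve.x <= hi)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(
            f"ROI [{lo}, {hi}] contains no curve points "
            f"(curve spans [{curve.x[0]:g}, {curve.x[-1]:g}])")
    return float(curve.y[sel].sum()), n


# -- single-peak fitting -----------------------------------------------------

def fit_single_peak(curve: Curve,
                    window: Optional[tuple[float, float]] = None,
                    init: Optional[dict] = None) -> PeakFitResult:
    """Fit a Gaussian + linear baseline to a profile by least squares.

    Uses lmfit's Gaussian and linear models.  ``window`` restricts the fit
    to an abscissa range; ``init`` may seed ``amplitude``, ``center``,
    ``sigma``, ``intercept``, ``slope``.  Non-convergence and
    statistically-zero amplitude are reported through the result's
    ``converged`` flag, never silently.
    """
    from lmfit.models import GaussianModel, LinearModel

    x, y = curve.x, curve.y
    if window is not None:
        sel = (x >= window[0]) & (x <= window[1])
        x, y = x[sel], y[sel]
    if x.size < 5:
        raise ValueError(f"peak fit needs at least 5 points, got {x.size}")

    peak = GaussianModel(prefix="g_")
    base = LinearModel(prefix="l_")
    model = peak + base
    params = peak.guess(y - np.median(y), x=x)
    params += base.make_params(l_intercept=float(np.median(y)), l_slope=0.0)
    params["g_sigma"].set(min=1e-12)
    for key, val in (init or {}).items():
        name = {"amplitude": "g_amplitude", "center": "g_center",
                "sigma": "g_sigma", "intercept": "l_intercept",
                "slope": "l_slope"}.get(key, key)
        params[name].set(value=val)
    try:
        out = model.fit(y, params, x=x)
    except Exception as exc:
        raise RuntimeError(f"peak fit failed: {exc}") from exc

    sigma = float(out.params["g_sigma"].value)
    # lmfit's GaussianModel amplitude is the area; convert to peak height
    area = float(out.params["g_amplitude"].value)
    height = area / (sigma * math.sqrt(2 * math.pi)) if sigma > 0 else 0.0
    ss_res = float(np.sum(out.residual ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    amp_err = out.params["g_amplitude"].stderr
    degenerate = (not out.success) or sigma <= 0 or (
        amp_err is not None and amp_err > 0 and abs(area) < 2 * amp_err)
    stderr = {p: (out.params[p].stderr if out.params[p].stderr is not None
                  else float("nan")) for p in out.params}
    return PeakFitResult(
        amplitude=height,
        center=float(out.params["g_center"].value),
        sigma=sigma,
        baseline_intercept=float(out.params["l_intercept"].value),
        baseline_slope=float(out.params["l_slope"].value),
        area=area,
        stderr=stderr,
        r_squared=r2,
        converged=not degenerate,
    )


# -- Guinier fit -------------------------------------------------------------

def _linfit(x, y, w=None):
    """Weighted least-squares line y = a + b x; returns (a, b, r2)."""
    w = np.ones_like(x) if w is None else w
    W = np.sum(w)
    xm, ym = np.sum(w * x) / W, np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx == 0:
        raise ValueError("degenerate abscissa in linear fit")
    b = np.sum(w * (x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    ss_tot = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - np.sum(w * resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return a, b, r2


def guinier_fit(curve: Curve,
                q_range: Optional[tuple[float, float]] = None,
                qmax_rg_limit: float = 1.3) -> GuinierResult:
    """Guinier analysis: regression of ``ln I`` on ``q^2`` at low q.

    The slope must be negative (``Rg = sqrt(-3 slope)``).  When ``q_range``
    is omitted, the range starts at the first point and its upper end is
    iterated until ``q_max * Rg <= qmax_rg_limit`` self-consistently (the
    standard validity heuristic; 1.3 for globular scatterers).  Intensities
    must be strictly positive over the fit range; when the curve carries
    uncertainties the regression is weighted by ``(y / yerr)^2`` (the
    variance of ``ln y``).
    """
    if curve.xkind != "q":
        raise ValueError(f"Guinier fit needs a q-abscissa curve, got {curve.xkind!r}")
    x, y = curve.x, curve.y

    def fit_on(sel: np.ndarray) -> GuinierResult:
        qs, ys = x[sel], y[sel]
        if qs.size < 3:
            raise ValueError("Guinier fit needs at least 3 points in range")
        if np.any(ys <= 0):
            raise ValueError("nonpositive intensities in the Guinier range")
        w = None
        if curve.yerr is not None:
            err = curve.yerr[sel]
            if np.all(err > 0):
                w = (ys / err) ** 2
        a, b, r2 = _linfit(qs ** 2, np.log(ys), w)
        if b >= 0:
            raise ValueError(
                "no Guinier decay: ln I does not decrease with q^2 "
                f"(slope {b:.3g} >= 0)")
        rg = math.sqrt(-3.0 * b)
        return GuinierResult(rg=rg, i0=math.exp(a),
                             fit_range=(float(qs[0]), float(qs[-1])),
                             qmax_rg=float(qs[-1]) * rg, r_squared=r2,
                             n_points=int(qs.size))

    if q_range is not None:
        return fit_on((x >= q_range[0]) & (x <= q_range[1]))

    # automatic range: shrink q_max until q_max * Rg <= limit, self-consistent
    hi = x.size
    result = None
    for _ in range(100):
        result = fit_on(np.arange(x.size) < hi)
        if result.qmax_rg <= qmax_rg_limit:
            return result
        new_hi = int(np.searchsorted(x, qmax_rg_limit / result.rg, side="right"))
        new_hi = min(new_hi, hi - 1)
        if new_hi < 3:
            raise ValueError(
                f"cannot satisfy q_max*Rg <= {qmax_rg_limit}: fewer than 3 "
                "points would remain")
        hi = new_hi
    return result


# -- Porod fit ---------------------------------------------------------------

def porod_fit(curve: Curve,
              q_range: Optional[tuple[float, float]] = None,
              strict: bool = True) -> PorodResult:
    """Porod tail analysis: regression of ``q^4 I`` on ``q^4``.

    Under ``I = K/q^4 + B`` the transform ``q^4 I = K + B q^4`` is linear
    with intercept K (Porod constant) and slope B (flat background).  The
    default range is the top third of the measured q span.  A negative K is
    unphysical for sharp interfaces and raises an error (``strict=False``
    downgrades it to the returned value).
    """
    if curve.xkind != "q":
        raise ValueError(f"Porod fit needs a q-abscissa curve, got {curve.xkind!r}")
    x, y = curve.x, curve.y
    if q_range is None:
        q_range = (x[0] + 2.0 * (x[-1] - x[0]) / 3.0, x[-1])
    sel = (x >= q_range[0]) & (x <= q_range[1])
    if sel.sum() < 4:
        raise ValueError(f"Porod fit needs at least 4 points in range, "
                         f"got {int(sel.sum())}")
    q4 = x[sel] ** 4
    k, b, _ = _linfit(q4, q4 * y[sel])
    if k <= 0 and strict:
        raise ValueError(f"unphysical Porod constant K = {k:.4g} <= 0 "
                         "(no q^-4 tail in the fit range)")
    return PorodResult(k=float(k), b=float(b),
                       fit_range=(float(x[sel][0]), float(x[sel][-1])))


# -- integral invariant and T parameter --------------------------------------

def integral_invariant(curve: Curve,
                       guinier: Optional[GuinierResult],
                       porod: Optional[PorodResult]) -> InvariantResult:
    """Three-part quadrature of ``Q = \\int_0^inf q^2 I(q) dq``.

    * below the measured range: numerical integral of the Guinier model
      ``I0 exp(-q^2 Rg^2/3)`` from 0 to q_min;
    * over the measured range: trapezoid rule on ``q^2 (I - B)`` with the
      Porod background B removed;
    * above: the closed-form Porod tail ``\\int_{qmax}^inf K/q^2 dq = K/q_max``.

    Both upstream results are hard requirements; a missing one raises
    :class:`MissingDependencyError` (the enforced workflow dependency).
    """
    missing = [name for name, obj in (("Guinier", guinier), ("Porod", porod))
               if obj is None]
    if missing:
        raise MissingDependencyError(
            "integral invariant requires upstream "
            + " and ".join(missing) + " result(s); missing: "
            + ", ".join(missing))
    if curve.xkind != "q":
        raise ValueError("integral invariant needs a q-abscissa curve")
    q, i = curve.x, curve.y
    low, _ = quad(lambda s: s * s * guinier.i0 * math.exp(-s * s * guinier.rg ** 2 / 3.0),
                  0.0, float(q[0]))
    measured = float(np.trapezoid(q * q * (i - porod.b), q))
    tail = porod.k / float(q[-1])
    if measured < 0:
        import warnings
        warnings.warn(f"measured part of the invariant is negative "
                      f"({measured:.3g}); background over-subtraction?",
                      stacklevel=2)
    return InvariantResult(q_inv=low + measured + tail,
                           parts=(low, measured, tail))


def t_parameter(invariant: InvariantResult, porod: PorodResult) -> float:
    """Mean chord-length T parameter, ``T = 4 Q / (pi K)``.

    For an ideal two-phase system with sharp interfaces, the ratio of the
    integral invariant to the Porod constant measures the volume-to-surface
    ratio; this is the standard stereological form used in bone SAXS.
    """
    if porod.k <= 0:
        raise ValueError(f"T parameter undefined for Porod constant K = {porod.k:.4g} <= 0")
    if invariant.q_inv <= 0:
        raise ValueError("T parameter requires a positive integral invariant")
    return 4.0 * invariant.q_inv / (math.pi * porod.k)
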