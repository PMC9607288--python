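"""Hill-model analysis of spectroscopic titrations.

A receptor R binding n ligand molecules in a single cooperative step,

    R + n L  <=>  R·L_n,      Kd = [L]^n [R] / [R·L_n],

produces a sigmoidal dependence of any analytical signal xi that is
linear in the bound fraction:

    xi(L) = xi0 + (xi_inf - xi0) * L^n / (L^n + K^n),

where K is the per-site midpoint concentration (M) and Kd = K^n (M^n).
Estimation follows the classic two-stage protocol: a nonlinear
least-squares fit of the four-parameter isotherm supplies the
asymptotes xi0 and xi_inf, after which the Hill linearization

    lg(theta / (1 - theta)) = n * lg[L] - lg Kd,
    theta = |(xi - xi0) / (xi_inf - xi0)|,

is fit by ordinary least squares; the reported stoichiometry n is the
slope and the reported -lg Kd is the intercept (at lg L = 0 the logit
equals -lg Kd).  Points whose bound fraction falls outside a clipping
band are excluded from the linearization because the logit diverges at
the ends; the band tightens adaptively with the fit's residual noise,
since points within a few noise SDs of an asymptote carry no
information about the transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

__all__ = [
    "TitrationSeries",
    "HillFitResult",
    "LinearizedPoints",
    "hill_curve",
    "binding_fraction",
    "hill_linearize",
    "fit_binding",
    "BindingFitError",
]


class BindingFitError(ValueError):
    """Raised when a titration cannot be fit (too few points, divergence)."""


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: ligand concentration (M) versus analytical signal."""

    ligand_conc: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        conc = np.asarray(self.ligand_conc, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if conc.ndim != 1 or sig.ndim != 1 or conc.size != sig.size:
            raise ValueError("ligand_conc and signal must be 1-D and equal length")
        if np.any(~np.isfinite(conc)) or np.any(~np.isfinite(sig)):
            raise ValueError("titration contains non-finite values")
        if np.any(conc <= 0):
            bad = int(np.flatnonzero(conc <= 0)[0])
            raise ValueError(
                f"ligand concentrations must be strictly positive (row {bad}: {conc[bad]!r})"
            )
        if np.any(np.diff(conc) <= 0):
            order = np.argsort(conc)
            conc, sig = conc[order], sig[order]
            if np.any(np.diff(conc) <= 0):
                raise ValueError("ligand concentrations contain duplicates")
        object.__setattr__(self, "ligand_conc", conc)
        object.__setattr__(self, "signal", sig)

    def __len__(self) -> int:
        return self.ligand_conc.size


@dataclass(frozen=True)
class LinearizedPoints:
    """Hill-plot coordinates with the exclusion report."""

    lg_conc: np.ndarray
    logit_theta: np.ndarray
    excluded_low: int
    excluded_high: int

    @property
    def n_used(self) -> int:
        return self.lg_conc.size


@dataclass(frozen=True)
class HillFitResult:
    """Two-stage Hill fit: isotherm parameters plus linearized estimates.

    ``n`` and ``neg_lg_Kd`` come from the linearization (slope and minus
    intercept); ``K`` is the stage-1 per-site midpoint, with the
    consistency identity lg Kd = n * lg K.  Kd carries units of M^n.
    """

    xi0: float
    xi_inf: float
    n: float
    K: float
    neg_lg_Kd: float
    stderr_n: float
    stderr_neg_lg_Kd: float
    r_squared: float
    points_used: int
    theta_range: tuple[float, float]
    transition_bracketed: bool

    @property
    def Kd(self) -> float:
        """Dissociation constant in M^n (mind the units for n != 1)."""
        return 10.0 ** (-self.neg_lg_Kd)


def hill_curve(L, xi0: float, xi_inf: float, K: float, n: float):
    """Four-parameter Hill isotherm xi(L); reduces to the three-parameter
    form (xi = xi_inf * L^n / (L^n + K^n)) when xi0 = 0."""
    if K <= 0 or n <= 0:
        raise ValueError("K and n must be positive")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be non-negative")
    # evaluate in log space to avoid overflow for large n
    with np.errstate(divide="ignore"):
        x = np.where(L > 0, (L / K) ** n, 0.0)
    return xi0 + (xi_inf - xi0) * x / (1.0 + x)


def binding_fraction(xi, xi0: float, xi_inf: float):
    """Bound fraction theta = |(xi - xi0) / (xi_inf - xi0)|.

    The absolute value makes the definition sign-agnostic: the analytical
    signal may decrease on binding (e.g. the amide I intensity does).
    """
    if xi_inf == xi0:
        raise ValueError("degenerate asymptotes: xi_inf == xi0")
    return np.abs((np.asarray(xi, dtype=float) - xi0) / (xi_inf - xi0))


def hill_linearize(
    series: TitrationSeries,
    xi0: float,
    xi_inf: float,
    clip: tuple[float, float] = (0.01, 0.99),
) -> LinearizedPoints:
    """Transform a titration to Hill-plot coordinates (lg L, logit theta).

    Points with theta <= clip[0] or >= clip[1] are excluded and counted in
    the report; fewer than 3 surviving points is an error.
    """
    lo, hi = clip
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("clip bounds must satisfy 0 <= lo < hi <= 1")
    theta = binding_fraction(series.signal, xi0, xi_inf)
    keep = (theta > lo) & (theta < hi)
    n_low = int(np.sum(theta <= lo))
    n_high = int(np.sum(theta >= hi))
    if int(keep.sum()) < 3:
        raise BindingFitError(
            f"only {int(keep.sum())} usable points after clipping theta to ({lo}, {hi}); "
            "need at least 3"
        )
    th = theta[keep]
    return LinearizedPoints(
        lg_conc=np.log10(series.ligand_conc[keep]),
        logit_theta=np.log10(th / (1.0 - th)),
        excluded_low=n_low,
        excluded_high=n_high,
    )


def _stage1_fit(conc: np.ndarray, sig: np.ndarray) -> tuple[float, float, float, float]:
    """Nonlinear least squares of the four-parameter isotherm.

    Parametrized in (xi0, xi_inf, lg K, n).  The default start follows the
    usual heuristics (asymptotes from the end points, K from the
    half-range concentration, n = 1) and is complemented by a small
    multistart over n and lg K: when the titration does not reach
    saturation the SSR surface has a long flat valley and a single start
    can stall far from the optimum.
    """
    lgL = np.log10(conc)
    ln10 = np.log(10.0)

    def resid(p):
        xi0, xi_inf, lgK, n = p
        with np.errstate(over="ignore"):
            x = 10.0 ** (n * (lgL - lgK))
        g = x / (1.0 + x)
        return xi0 + (xi_inf - xi0) * g - sig

    def jac(p):
        xi0, xi_inf, lgK, n = p
        with np.errstate(over="ignore"):
            x = 10.0 ** (n * (lgL - lgK))
        g = x / (1.0 + x)
        dg = x / (1.0 + x) ** 2  # x * d(g)/dx
        amp = xi_inf - xi0
        return np.column_stack(
            [1.0 - g, g, -amp * n * ln10 * dg, amp * ln10 * (lgL - lgK) * dg]
        )

    span = sig[-1] - sig[0]
    half = sig[0] + 0.5 * span
    # concentration whose signal is nearest the half-range point
    k0 = conc[int(np.argmin(np.abs(sig - half)))]
    starts = []
    for n0 in (0.7, 1.0, 1.5, 2.5):
        for shift in (0.0, 1.5):
            starts.append((sig[0], sig[-1], np.log10(k0) + shift, n0))

    lo = [-np.inf, -np.inf, np.log10(conc[0]) - 6.0, 0.05]
    hi = [np.inf, np.inf, np.log10(conc[-1]) + 6.0, 10.0]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            res = least_squares(
                resid, p0, jac=jac, bounds=(lo, hi), method="trf",
                xtol=3e-16, ftol=3e-16, gtol=3e-16, max_nfev=400,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise BindingFitError("nonlinear Hill fit diverged")
    xi0, xi_inf, lgK, n = best.x
    return float(xi0), float(xi_inf), float(10.0**lgK), float(n)


def fit_binding(
    series: TitrationSeries,
    clip: tuple[float, float] = (0.01, 0.99),
    min_theta_span: float = 0.3,
) -> HillFitResult:
    """Two-stage estimate of (n, -lg Kd) from a titration series.

    Stage 1 fits the four-parameter isotherm by nonlinear least squares;
    stage 2 performs ordinary least squares on the Hill linearization
    using the stage-1 asymptotes.  Reported n and -lg Kd are the stage-2
    slope and intercept, with their regression standard errors.

    The clipping band is tightened adaptively: points whose bound
    fraction lies within 3 residual SDs of either asymptote are
    excluded, because there the logit measures noise, not binding.  A
    titration whose observed bound-fraction span is below
    ``min_theta_span`` is flagged as not bracketing the transition
    (``transition_bracketed=False``) and a warning is emitted.
    """
    if len(series) < 5:
        raise BindingFitError(f"need at least 5 titration points, got {len(series)}")
    conc, sig = series.ligand_conc, series.signal

    xi0, xi_inf, K, n_nls = _stage1_fit(conc, sig)

    # residual noise estimate from stage 1 -> adaptive clipping floor
    resid = hill_curve(conc, xi0, xi_inf, K, n_nls) - sig
    dof = max(len(series) - 4, 1)
    sigma = float(np.sqrt(np.sum(resid**2) / dof))
    amp = abs(xi_inf - xi0)
    noise_floor = min(3.0 * sigma / amp, 0.3) if amp > 0 else 0.0
    lo_eff = max(clip[0], noise_floor)
    hi_eff = min(clip[1], 1.0 - noise_floor)

    theta = binding_fraction(sig, xi0, xi_inf)
    th_lo, th_hi = float(np.min(theta)), float(np.max(theta))
    bracketed = (th_hi - th_lo) >= min_theta_span
    if not bracketed:
        warnings.warn(
            f"titration spans only theta = [{th_lo:.3f}, {th_hi:.3f}]; "
            "the binding transition is not bracketed and estimates may be unstable",
            stacklevel=2,
        )

    pts = hill_linearize(series, xi0, xi_inf, clip=(lo_eff, hi_eff))
    reg = linregress(pts.lg_conc, pts.logit_theta)
    n_hat = float(reg.slope)
    neg_lg_kd = float(reg.intercept)
    if n_hat <= 0:
        raise BindingFitError("linearized Hill slope is non-positive; fit rejected")

    return HillFitResult(
        xi0=xi0,
        xi_inf=xi_inf,
        n=n_hat,
        K=K,
        neg_lg_Kd=neg_lg_kd,
        stderr_n=float(reg.stderr),
        stderr_neg_lg_Kd=float(reg.intercept_stderr),
        r_squared=float(reg.rvalue**2),
        points_used=pts.n_used,
        theta_range=(th_lo, th_hi),
        transition_bracketed=bracketed,
    )
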