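"""Spectral signal extraction for titration series.

Implements the standard FTIR processing chain used to read an
analytical signal from raw absorbance spectra: blank subtraction,
linear baseline correction, min–max normalization, Savitzky–Golay
smoothing (5-point, quadratic by default) and Savitzky–Golay second
differentiation (9-point window), followed by peak picking with
parabolic sub-grid refinement.  Second-derivative spectra sharpen
overlapping bands: an absorption maximum appears as a local minimum of
d²A/dν², which is why band *minima* of the derivative trace are the
usual analytical readout.

All operators are grid- and length-preserving.  Wavenumber grids may be
supplied ascending or descending; they are normalized to ascending
internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "PeakReading",
    "subtract_blank",
    "baseline_correct",
    "minmax_normalize",
    "savgol_smooth",
    "second_derivative",
    "pick_peak",
]


@dataclass(frozen=True)
class Spectrum:
    """A wavenumber grid (cm^-1) with absorbance values."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if nu.ndim != 1 or a.ndim != 1 or nu.size != a.size:
            raise ValueError("wavenumbers and absorbance must be 1-D, equal length")
        if nu.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        if np.any(~np.isfinite(nu)) or np.any(~np.isfinite(a)):
            raise ValueError("spectrum contains non-finite values")
        d = np.diff(nu)
        if np.all(d < 0):  # descending grid: normalize to ascending
            nu, a = nu[::-1], a[::-1]
        elif not np.all(d > 0):
            raise ValueError("wavenumber grid must be strictly monotonic")
        object.__setattr__(self, "wavenumbers", nu)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def step(self) -> float:
        """Grid step; raises if the grid is not uniform."""
        d = np.diff(self.wavenumbers)
        if not np.allclose(d, d[0], rtol=1e-6, atol=0.0):
            raise ValueError("wavenumber grid is not uniform")
        return float(d[0])

    def with_absorbance(self, a: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers, a)


@dataclass(frozen=True)
class PeakReading:
    """A picked extremum with parabolically refined position."""

    target_region: tuple[float, float]
    position: float
    intensity: float
    kind: str  # "maximum" | "minimum"
    on_boundary: bool = False


def _require_same_grid(a: Spectrum, b: Spectrum) -> None:
    if len(a) != len(b) or not np.array_equal(a.wavenumbers, b.wavenumbers):
        raise ValueError("spectra are on different wavenumber grids; resample explicitly")


def subtract_blank(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Pointwise sample - blank on identical grids (no implicit resampling)."""
    _require_same_grid(sample, blank)
    return sample.with_absorbance(sample.absorbance - blank.absorbance)


def baseline_correct(s: Spectrum, anchor_regions) -> Spectrum:
    """Subtract the least-squares line through anchor-region means.

    Each anchor region (lo, hi) contributes one point (mean wavenumber,
    mean absorbance); the line through those points, fit by least
    squares, is removed so that anchor regions map to ~0.
    """
    regions = list(anchor_regions)
    if len(regions) < 2:
        raise ValueError("need at least 2 anchor regions")
    nu, a = s.wavenumbers, s.absorbance
    xs, ys = [], []
    for lo, hi in regions:
        if lo > hi:
            lo, hi = hi, lo
        mask = (nu >= lo) & (nu <= hi)
        if not mask.any():
            raise ValueError(f"anchor region ({lo}, {hi}) contains no grid points")
        xs.append(nu[mask].mean())
        ys.append(a[mask].mean())
    slope, offset = np.polyfit(xs, ys, 1)
    return s.with_absorbance(a - (slope * nu + offset))


def minmax_normalize(s: Spectrum) -> Spectrum:
    """Linear rescale of absorbance to [0, 1]."""
    a = s.absorbance
    lo, hi = a.min(), a.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant spectrum")
    return s.with_absorbance((a - lo) / (hi - lo))


def savgol_smooth(s: Spectrum, window: int = 5, order: int = 2) -> Spectrum:
    """Savitzky–Golay smoothing; polynomials of degree <= order pass unchanged."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(s):
        raise ValueError("window exceeds spectrum length")
    if window <= order:
        raise ValueError("window must exceed polynomial order")
    return s.with_absorbance(
        savgol_filter(s.absorbance, window_length=window, polyorder=order,
                      mode="interp")
    )


def second_derivative(s: Spectrum, smoothing_points: int = 9) -> Spectrum:
    """Savitzky–Golay second derivative d²A/dν² (quadratic, 9-point window).

    Requires a uniform grid.  Any linear component of the spectrum is
    annihilated exactly, so the operator is insensitive to baseline
    offset and slope.
    """
    if smoothing_points % 2 == 0:
        raise ValueError("smoothing_points must be odd")
    if smoothing_points > len(s):
        raise ValueError("smoothing_points exceeds spectrum length")
    step = s.step  # raises on non-uniform grid
    d2 = savgol_filter(
        s.absorbance, window_length=smoothing_points, polyorder=2,
        deriv=2, delta=step, mode="interp",
    )
    return s.with_absorbance(d2)


def pick_peak(s: Spectrum, region: tuple[float, float], kind: str = "maximum") -> PeakReading:
    """Extremum of the requested kind within a wavenumber region.

    The position is refined by a parabola through the extremum and its two
    neighbours.  An extremum sitting on the region boundary is flagged
    (``on_boundary=True``) as possibly truncated, with a warning.
    """
    if kind not in ("maximum", "minimum"):
        raise ValueError("kind must be 'maximum' or 'minimum'")
    lo, hi = region
    if lo > hi:
        lo, hi = hi, lo
    nu, a = s.wavenumbers, s.absorbance
    mask = (nu >= lo) & (nu <= hi)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise ValueError("region must contain at least 3 grid points")
    seg = a[idx]
    k = int(np.argmax(seg) if kind == "maximum" else np.argmin(seg))
    i = idx[k]
    on_boundary = k == 0 or k == idx.size - 1
    if on_boundary:
        warnings.warn(
            f"{kind} at {nu[i]:.1f} cm^-1 lies on the region boundary "
            f"({lo:.1f}, {hi:.1f}); the band may be truncated",
            stacklevel=2,
        )
        return PeakReading((lo, hi), float(nu[i]), float(a[i]), kind, True)
    # 3-point parabolic refinement (minimal sub-grid estimator)
    y0, y1, y2 = a[i - 1], a[i], a[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        dx = 0.0
    else:
        dx = 0.5 * (y0 - y2) / denom
    x0, x1, x2 = nu[i - 1], nu[i], nu[i + 1]
    pos = x1 + dx * 0.5 * (x2 - x0)
    inten = y1 - 0.25 * (y0 - y2) * dx
    return PeakReading((lo, hi), float(pos), float(inten), kind, False)
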