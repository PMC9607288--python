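"""Synthetic titrations, band spectra, and uptake kinetics with known truth.

Every downstream stage of the pipeline (spectral processing, Hill
fitting, uptake statistics) can be exercised against data whose
generating parameters are known exactly.  The generators mirror the
structure of the real measurements:

* titrations — Hill-shaped signal versus ligand concentration with
  additive Gaussian noise (default 2% of the signal dynamic range);
* band spectra — sums of Gaussian bands on a linear baseline whose
  heights (and optionally positions) move linearly with the bound
  fraction, as protein amide bands do during complexation;
* uptake tables — a linear three-compartment exchange scheme
  (solution <-> cell-wall <-> intracellular) with first-order efflux
  that an adjuvant suppresses after a delayed onset, emulating the
  time-resolved drug-distribution tables of the fluorescence assay.

All randomness is drawn from ``numpy.random.default_rng(seed)``; a fixed
seed reproduces the series bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import TitrationSeries, hill_curve
from .kinetics import propagate
from .spectra import Spectrum
from .uptake import UptakeTable

__all__ = [
    "TitrationGroundTruth",
    "Band",
    "SpectrumGroundTruth",
    "UptakeGroundTruth",
    "generate_titration",
    "generate_spectrum_series",
    "generate_uptake",
]


def _default_concentrations() -> np.ndarray:
    return np.logspace(-8.0, -5.0, 12)


@dataclass(frozen=True)
class TitrationGroundTruth:
    """Generating parameters of one Hill-shaped titration.

    ``neg_lg_Kd`` is -lg Kd with Kd in M^n; the per-site midpoint used in
    the isotherm is K = 10**(-neg_lg_Kd / n) so that lg Kd = n lg K.
    ``noise_sd`` is the SD of additive Gaussian noise in signal units
    (default 0.02 = 2% of the unit dynamic range).
    """

    xi0: float = 0.0
    xi_inf: float = 1.0
    n: float = 1.5
    neg_lg_Kd: float = 6.5
    noise_sd: float = 0.02
    concentrations: np.ndarray = field(default_factory=_default_concentrations)
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n <= 0:
            raise ValueError("Hill coefficient n must be positive")
        object.__setattr__(self, "concentrations", conc)

    @property
    def K(self) -> float:
        """Per-site midpoint concentration (M)."""
        return 10.0 ** (-self.neg_lg_Kd / self.n)


def generate_titration(gt: TitrationGroundTruth) -> TitrationSeries:
    """Sample a titration: xi_i = Hill(L_i) + eps_i, eps ~ N(0, noise_sd)."""
    rng = np.random.default_rng(gt.seed)
    clean = hill_curve(gt.concentrations, gt.xi0, gt.xi_inf, gt.K, gt.n)
    noisy = clean + rng.normal(0.0, gt.noise_sd, size=clean.shape)
    return TitrationSeries(
        ligand_conc=gt.concentrations,
        signal=noisy,
        meta={"ground_truth_n": gt.n, "ground_truth_neg_lg_Kd": gt.neg_lg_Kd,
              "noise_sd": gt.noise_sd, "seed": gt.seed},
    )


@dataclass(frozen=True)
class Band:
    """One Gaussian band whose height tracks the bound fraction theta.

    ``height_free``/``height_bound`` are the peak absorbances at theta = 0
    and theta = 1; ``center_shift`` moves the band centre linearly with
    theta (cm^-1, positive = short-wave shift), emulating the position
    shifts seen on complexation.
    """

    center: float
    width: float
    height_free: float
    height_bound: float
    center_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")


def _default_bands() -> tuple[Band, ...]:
    # amide I and amide II analogues: intensity drops on complexation
    return (
        Band(center=1650.0, width=25.0, height_free=1.0, height_bound=0.55),
        Band(center=1550.0, width=25.0, height_free=0.8, height_bound=0.50),
    )


@dataclass(frozen=True)
class SpectrumGroundTruth:
    """Generating parameters for a series of band spectra."""

    bands: tuple[Band, ...] = field(default_factory=_default_bands)
    baseline_slope: float = 0.0
    baseline_offset: float = 0.0
    noise_sd: float = 0.0
    grid_min: float = 900.0
    grid_max: float = 3000.0
    grid_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0 or self.grid_max <= self.grid_min:
            raise ValueError("invalid wavenumber grid")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.arange(self.grid_min, self.grid_max + 0.5 * self.grid_step,
                         self.grid_step)


def generate_spectrum_series(
    gt: SpectrumGroundTruth, theta_per_level
) -> list[Spectrum]:
    """One spectrum per bound-fraction level theta in [0, 1].

    Band heights (and centres) interpolate linearly between their free and
    bound endpoint values; a linear baseline and Gaussian noise are added.
    """
    thetas = np.asarray(theta_per_level, dtype=float)
    if np.any((thetas < 0) | (thetas > 1)):
        raise ValueError("theta values must lie in [0, 1]")
    rng = np.random.default_rng(gt.seed)
    nu = gt.wavenumbers
    out = []
    for th in thetas:
        a = gt.baseline_offset + gt.baseline_slope * nu
        for b in gt.bands:
            h = b.height_free + th * (b.height_bound - b.height_free)
            c = b.center + th * b.center_shift
            a = a + h * np.exp(-0.5 * ((nu - c) / b.width) ** 2)
        if gt.noise_sd > 0:
            a = a + rng.normal(0.0, gt.noise_sd, size=nu.shape)
        out.append(Spectrum(nu, a))
    return out


def _default_timepoints() -> np.ndarray:
    return np.array([0.0, 15.0, 45.0, 120.0, 840.0])


@dataclass(frozen=True)
class UptakeGroundTruth:
    """Rates of the three-compartment uptake scheme (all first order).

    Compartments: S (solution), W (cell-wall adsorbed), I (intracellular).

        dS/dt = -k_on S + k_off W + k_out_eff(t) I
        dW/dt =  k_on S - k_off W - k_in_eff W
        dI/dt =  k_in_eff W - k_out_eff(t) I

    With the adjuvant arm, membrane permeabilization raises the
    internalization rate, k_in_eff = k_in (1 + perm_boost), and efflux is
    suppressed by a fraction ``inh_frac`` once the inhibitor has had time
    to act: k_out_eff(t) = k_out (1 - inh_frac * 1[t >= inh_onset_min]).
    The delayed step onset reflects that efflux-pump inhibition develops
    over tens of minutes rather than instantly.  Total analyte S + W + I
    is conserved exactly by the scheme.
    """

    c_total_drug: float = 47.0        # μM
    c_total_adjuvant: float = 6.0     # mM, descriptor of the adjuvant arm
    k_on: float = 0.15                # 1/min, solution -> wall
    k_off: float = 0.01               # 1/min, wall -> solution
    k_in: float = 0.03                # 1/min, wall -> intracellular
    k_out: float = 0.2                # 1/min, efflux
    perm_boost: float = 0.6
    inh_frac: float = 0.8
    inh_onset_min: float = 30.0
    timepoints: np.ndarray = field(default_factory=_default_timepoints)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_in", "k_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.perm_boost < 0:
            raise ValueError("perm_boost must be non-negative")
        if not 0.0 <= self.inh_frac <= 1.0:
            raise ValueError("inh_frac must lie in [0, 1]")
        if self.c_total_drug <= 0:
            raise ValueError("c_total_drug must be positive")
        t = np.asarray(self.timepoints, dtype=float)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be non-negative and increasing")
        object.__setattr__(self, "timepoints", t)


def generate_uptake(
    gt: UptakeGroundTruth, with_adjuvant: bool = False, analyte: str = "MF"
) -> UptakeTable:
    """Integrate the three-compartment scheme at the requested timepoints.

    The scheme is linear with piecewise-constant rates, so the solution is
    computed exactly with matrix exponentials (one propagator per phase);
    mass conservation holds to machine precision.
    """
    traj = propagate(
        gt.c_total_drug, gt.timepoints,
        gt.k_on, gt.k_off, gt.k_in, gt.k_out,
        perm_boost=gt.perm_boost, inh_frac=gt.inh_frac,
        inh_onset=gt.inh_onset_min, with_adjuvant=with_adjuvant,
    )
    frame = pd.DataFrame(
        np.column_stack([gt.timepoints, np.clip(traj, 0.0, None)]),
        columns=["time_min", "c_solution", "c_adsorbed", "c_absorbed"],
    )
    frame.insert(1, "analyte", analyte)
    return UptakeTable(data=frame, dose={analyte: gt.c_total_drug})
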