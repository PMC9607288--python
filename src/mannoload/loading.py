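"""Mass-action drug-loading equilibrium: bound drug, EE and LC.

A carrier (ligand) bearing N equivalent, independent drug-binding sites
at total concentration C_L loads a drug at total concentration C_M with
per-site dissociation constant Kd:

    Kd = N (C_M - C_b)(C_L - C_b / N) / C_b,

where C_b is the bound-drug concentration.  Rearranged, C_b solves

    C_b^2 - (C_M + N C_L + Kd) C_b + N C_L C_M = 0,

whose smaller root is the physical one (the larger root always exceeds
min(C_M, N C_L), i.e. would bind more drug than exists or more than the
sites can hold).  Derived quantities:

    EE (%) = 100 C_b / C_M                (entrapment efficiency)
    LC (%) = 100 N m_drug / m_ligand      (loading capacity, by mass)

Site counts may be split into cyclodextrin-torus sites (N_CD, taken as
a fixed occupancy fraction of the torus count) and polymer-matrix sites
(N_polymer).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "LoadingSystem",
    "LoadingResult",
    "CD_TORUS_OCCUPANCY",
    "MOXIFLOXACIN_FREE_BASE",
    "MOXIFLOXACIN_HCL",
    "solve_bound",
    "entrapment_efficiency",
    "loading_capacity",
    "n_cd_sites",
    "n_polymer_sites",
]

#: Fraction of cyclodextrin tori assumed drug-occupied at saturation.
CD_TORUS_OCCUPANCY = 0.9

#: Moxifloxacin molar masses, g/mol.
MOXIFLOXACIN_FREE_BASE = 401.4
MOXIFLOXACIN_HCL = 437.9


@dataclass(frozen=True)
class LoadingSystem:
    """One carrier/drug loading system.

    Kd in M (per-site), N drug molecules per carrier molecule, total
    concentrations in M, molar masses in g/mol.
    """

    Kd: float
    N: float
    c_ligand_total: float
    c_drug_total: float
    m_drug: float = MOXIFLOXACIN_FREE_BASE
    m_ligand: float = 1.0

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")
        if self.N < 0:
            raise ValueError("N must be non-negative")
        if self.c_ligand_total <= 0 or self.c_drug_total <= 0:
            raise ValueError("total concentrations must be positive")
        if self.m_drug <= 0 or self.m_ligand <= 0:
            raise ValueError("molar masses must be positive")

    @classmethod
    def from_neg_lg_kd(cls, neg_lg_kd: float, **kwargs) -> "LoadingSystem":
        return cls(Kd=10.0 ** (-neg_lg_kd), **kwargs)


@dataclass(frozen=True)
class LoadingResult:
    c_bound: float
    ee_percent: float
    lc_percent: float
    discriminant: float
    chosen_root: str  # "smaller" | "degenerate"


def solve_bound(sys: LoadingSystem) -> float:
    """Bound-drug concentration C_b (M), the physical quadratic root.

    For N = 0 (no sites) returns 0 with a warning.  The discriminant is
    provably positive for valid inputs; a negative value indicates
    corrupted input and is rejected.
    """
    if sys.N == 0:
        warnings.warn("N = 0: carrier has no binding sites; c_bound = 0",
                      stacklevel=2)
        return 0.0
    cm, ns = sys.c_drug_total, sys.N * sys.c_ligand_total
    b = cm + ns + sys.Kd
    disc = b * b - 4.0 * ns * cm
    if disc < 0:
        raise ValueError("negative discriminant: invalid loading system")
    # smaller root, in the numerically stable form
    cb = 2.0 * ns * cm / (b + math.sqrt(disc))
    upper = min(cm, ns)
    if not -1e-12 * upper <= cb <= upper * (1.0 + 1e-12):
        raise AssertionError("physical-root invariant violated")
    return float(min(max(cb, 0.0), upper))


def entrapment_efficiency(sys: LoadingSystem) -> float:
    """EE (%) = 100 * C_bound / C_drug_total."""
    return 100.0 * solve_bound(sys) / sys.c_drug_total


def loading_capacity(sys: LoadingSystem) -> float:
    """LC (%) = 100 * N * m_drug / m_ligand (independent of concentrations)."""
    return 100.0 * sys.N * sys.m_drug / sys.m_ligand


def load(sys: LoadingSystem) -> LoadingResult:
    """Solve the system and return bound drug, EE and LC together."""
    cm, ns = sys.c_drug_total, sys.N * sys.c_ligand_total
    cb = solve_bound(sys)
    b = cm + ns + sys.Kd
    return LoadingResult(
        c_bound=cb,
        ee_percent=100.0 * cb / cm,
        lc_percent=loading_capacity(sys),
        discriminant=b * b - 4.0 * ns * cm,
        chosen_root="degenerate" if sys.N == 0 else "smaller",
    )


def n_cd_sites(cd_tori_count: float, occupancy: float = CD_TORUS_OCCUPANCY) -> float:
    """Drug molecules held in cyclodextrin tori: occupancy × torus count."""
    if cd_tori_count < 0:
        raise ValueError("torus count must be non-negative")
    return occupancy * cd_tori_count


def n_polymer_sites(
    Kd: float,
    c_ligand: float,
    theta_target: float = 0.95,
    n_cd: float = 0.0,
) -> float:
    """Polymer-matrix site count from the drug:ligand ratio at high binding.

    The carrier is loaded to capacity: at drug:ligand mole ratio R the
    carrier offers R sites per molecule, and R is chosen so that the
    equilibrium bound fraction of the drug equals ``theta_target``.
    With C_M = R·C_L and N = R the quadratic collapses to
    Kd·C_b = (C_M − C_b)², giving the closed form

        R = Kd · θ* / ((1 − θ*)² · C_L).

    Cyclodextrin-held drug molecules (``n_cd``) are subtracted; the
    result is floored at 0.  θ* = 1 is unattainable at finite
    concentration and is rejected.
    """
    if Kd <= 0 or c_ligand <= 0:
        raise ValueError("Kd and c_ligand must be positive")
    if not 0.0 <= theta_target <= 1.0:
        raise ValueError("theta_target must lie in [0, 1]")
    if theta_target == 1.0:
        raise ValueError(
            "theta_target = 1 is unattainable at finite Kd and concentration"
        )
    ratio = Kd * theta_target / ((1.0 - theta_target) ** 2 * c_ligand)
    return max(ratio - n_cd, 0.0)
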