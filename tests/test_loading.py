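"""Loading equilibrium: quadratic solver vs bisection oracle, EE/LC
values for the studied carriers, site-count rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mannoload import (
    LoadingSystem,
    entrapment_efficiency,
    loading_capacity,
    n_cd_sites,
    n_polymer_sites,
    solve_bound,
)
from mannoload.loading import MOXIFLOXACIN_FREE_BASE, MOXIFLOXACIN_HCL


def bisect_bound(sys):
    """Independent oracle: bisection on f(Cb) = Kd·Cb − (C_M−Cb)(N·C_L−Cb),
    monotone-increasing on [0, min(C_M, N·C_L)].  Evaluated in 50-digit
    decimal arithmetic: the product term cancels catastrophically near
    the root in binary floats, which would make a float oracle less
    accurate than the solver it is meant to check."""
    from decimal import Decimal, getcontext

    getcontext().prec = 50
    kd = Decimal(sys.Kd)
    cm = Decimal(sys.c_drug_total)
    ns = Decimal(sys.N) * Decimal(sys.c_ligand_total)

    def f(cb):
        return kd * cb - (cm - cb) * (ns - cb)

    lo, hi = Decimal(0), min(cm, ns)
    for _ in range(150):
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return float((lo + hi) / 2)


# (−lg Kd, N, m_ligand g/mol, printed EE ± , printed LC ±) per carrier
CARRIERS = [
    ("amCD-triMan", 4.0, 1, 2100.0, (9, 1), (20, 3)),
    ("PEI1.8-triMan", 3.3, 4, 15000.0, (24, 3), (11, 2)),
    ("PEI10-triMan", 3.8, 17, 45000.0, (84, 6), (15, 3)),
]

C_LIGAND = 1e-4  # M
C_DRUG = 1e-3    # M


def carrier_system(neg_lg_kd, n_sites, m_ligand):
    return LoadingSystem.from_neg_lg_kd(
        neg_lg_kd, N=n_sites, c_ligand_total=C_LIGAND, c_drug_total=C_DRUG,
        m_ligand=m_ligand,
    )


class TestSolveBound:
    @pytest.mark.parametrize("label,nlk,n,m_lig,ee,lc", CARRIERS)
    def test_published_entrapment_efficiencies(self, label, nlk, n, m_lig, ee, lc):
        sys = carrier_system(nlk, n, m_lig)
        assert entrapment_efficiency(sys) == pytest.approx(ee[0], abs=ee[1])

    def test_first_carrier_bound_concentration(self):
        sys = carrier_system(4.0, 1, 2100.0)
        assert solve_bound(sys) == pytest.approx(9.0e-5, rel=2e-2)

    def test_strong_binding_limit_fills_all_sites(self):
        sys = LoadingSystem(Kd=1e-15, N=1, c_ligand_total=1e-4, c_drug_total=1e-3)
        assert solve_bound(sys) == pytest.approx(1e-4, rel=1e-9)

    def test_weak_binding_limit_binds_nothing(self):
        sys = LoadingSystem(Kd=1e6, N=1, c_ligand_total=1e-4, c_drug_total=1e-3)
        assert entrapment_efficiency(sys) == pytest.approx(0.0, abs=1e-4)

    def test_excess_sites_strong_binding_entraps_everything(self):
        sys = LoadingSystem(Kd=1e-15, N=20, c_ligand_total=1e-4, c_drug_total=1e-3)
        assert entrapment_efficiency(sys) == pytest.approx(100.0, abs=1e-6)

    def test_agrees_with_bisection_oracle_over_random_sweep(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            sys = LoadingSystem(
                Kd=10 ** rng.uniform(-8, 0),
                N=rng.uniform(0.1, 30),
                c_ligand_total=10 ** rng.uniform(-6, -2),
                c_drug_total=10 ** rng.uniform(-5, -1),
            )
            cb = solve_bound(sys)
            ref = bisect_bound(sys)
            assert cb == pytest.approx(ref, rel=1e-10, abs=1e-300)

    def test_mass_conservation_identities(self):
        sys = carrier_system(3.3, 4, 15000.0)
        cb = solve_bound(sys)
        free_drug = sys.c_drug_total - cb
        free_sites = sys.N * sys.c_ligand_total - cb
        assert free_drug + cb == pytest.approx(sys.c_drug_total, rel=1e-12)
        assert free_sites + cb == pytest.approx(
            sys.N * sys.c_ligand_total, rel=1e-12
        )
        # and the equilibrium relation itself holds at the root
        assert sys.Kd * cb == pytest.approx(free_drug * free_sites, rel=1e-9)

    def test_zero_sites_degenerate(self):
        sys = LoadingSystem(Kd=1e-4, N=0, c_ligand_total=1e-4, c_drug_total=1e-3)
        with pytest.warns(UserWarning, match="no binding sites"):
            assert solve_bound(sys) == 0.0

    @given(
        lg_kd=st.floats(-8, 0),
        n=st.floats(0.1, 30),
        lg_cl=st.floats(-6, -2),
        lg_cm=st.floats(-5, -1),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_root_is_physical(self, lg_kd, n, lg_cl, lg_cm):
        sys = LoadingSystem(
            Kd=10**lg_kd, N=n, c_ligand_total=10**lg_cl, c_drug_total=10**lg_cm
        )
        cb = solve_bound(sys)
        assert 0.0 <= cb <= min(sys.c_drug_total, sys.N * sys.c_ligand_total)

    @given(
        lg_kd=st.floats(-7, -1),
        factor=st.floats(1.1, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ee_monotone_decreasing_in_kd(self, lg_kd, factor):
        base = LoadingSystem(
            Kd=10**lg_kd, N=4, c_ligand_total=1e-4, c_drug_total=1e-3
        )
        weaker = LoadingSystem(
            Kd=base.Kd * factor, N=4, c_ligand_total=1e-4, c_drug_total=1e-3
        )
        assert entrapment_efficiency(weaker) <= entrapment_efficiency(base) + 1e-9

    @given(factor=st.floats(1.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ee_monotone_increasing_in_sites_and_ligand(self, factor):
        base = LoadingSystem(Kd=1e-4, N=4, c_ligand_total=1e-4, c_drug_total=1e-3)
        more_sites = LoadingSystem(
            Kd=1e-4, N=4 * factor, c_ligand_total=1e-4, c_drug_total=1e-3
        )
        more_ligand = LoadingSystem(
            Kd=1e-4, N=4, c_ligand_total=1e-4 * factor, c_drug_total=1e-3
        )
        ee0 = entrapment_efficiency(base)
        assert entrapment_efficiency(more_sites) >= ee0 - 1e-9
        assert entrapment_efficiency(more_ligand) >= ee0 - 1e-9


class TestLoadingCapacity:
    @pytest.mark.parametrize("label,nlk,n,m_lig,ee,lc", CARRIERS)
    def test_published_loading_capacities(self, label, nlk, n, m_lig, ee, lc):
        sys = carrier_system(nlk, n, m_lig)
        assert loading_capacity(sys) == pytest.approx(lc[0], abs=lc[1])

    def test_free_base_value_for_lightest_carrier(self):
        sys = LoadingSystem(
            Kd=1e-4, N=1, c_ligand_total=1e-4, c_drug_total=1e-3,
            m_drug=MOXIFLOXACIN_FREE_BASE, m_ligand=2100.0,
        )
        assert loading_capacity(sys) == pytest.approx(19.11, abs=0.01)

    def test_hydrochloride_variant_also_within_printed_band(self):
        sys = LoadingSystem(
            Kd=1e-4, N=1, c_ligand_total=1e-4, c_drug_total=1e-3,
            m_drug=MOXIFLOXACIN_HCL, m_ligand=2100.0,
        )
        assert loading_capacity(sys) == pytest.approx(20, abs=3)

    def test_zero_sites_gives_zero(self):
        sys = LoadingSystem(Kd=1e-4, N=0, c_ligand_total=1e-4, c_drug_total=1e-3,
                            m_ligand=2100.0)
        assert loading_capacity(sys) == 0.0

    def test_independent_of_concentrations(self):
        a = LoadingSystem(Kd=1e-4, N=2, c_ligand_total=1e-4, c_drug_total=1e-3,
                          m_ligand=1000.0)
        b = LoadingSystem(Kd=1e-4, N=2, c_ligand_total=5e-3, c_drug_total=2e-2,
                          m_ligand=1000.0)
        assert loading_capacity(a) == loading_capacity(b)


class TestSiteRules:
    def test_cd_occupancy_rule(self):
        assert n_cd_sites(1) == pytest.approx(0.9)
        assert n_cd_sites(0) == 0.0
        assert n_cd_sites(10) == pytest.approx(9.0)

    def test_negative_torus_count_rejected(self):
        with pytest.raises(ValueError):
            n_cd_sites(-1)

    def test_polymer_sites_match_grid_search_oracle(self):
        """Closed form vs brute-force scan of the self-consistent ratio."""
        kd, cl, theta = 10**-3.3, 1e-4, 0.95
        target = n_polymer_sites(kd, cl, theta_target=theta)
        ratios = np.linspace(max(target - 5, 0.01), target + 5, 200001)
        # bound fraction at ratio R with N = R sites, C_M = R*C_L:
        # Kd*Cb = (C_M - Cb)^2  ->  theta from the quadratic solver
        best, best_err = None, np.inf
        for r in ratios:
            sys = LoadingSystem(
                Kd=kd, N=r, c_ligand_total=cl, c_drug_total=r * cl
            )
            err = abs(entrapment_efficiency(sys) / 100.0 - theta)
            if err < best_err:
                best, best_err = r, err
        assert target == pytest.approx(best, rel=1e-3)

    def test_zero_target_gives_zero_sites(self):
        assert n_polymer_sites(1e-4, 1e-4, theta_target=0.0) == 0.0

    def test_cd_sites_subtracted_with_floor_at_zero(self):
        full = n_polymer_sites(10**-3.3, 1e-4)
        assert n_polymer_sites(10**-3.3, 1e-4, n_cd=1.0) == pytest.approx(full - 1.0)
        assert n_polymer_sites(10**-3.3, 1e-4, n_cd=full + 5.0) == 0.0

    def test_full_binding_target_unattainable(self):
        with pytest.raises(ValueError, match="unattainable"):
            n_polymer_sites(1e-4, 1e-4, theta_target=1.0)
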