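import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sabsim.chemistry import derive_chemistry
from sabsim.metabolism import (CYANO_PROCESSES, HETERO_PROCESSES, CyanoState,
                               ExtracellularState, HeteroState, KineticParams,
                               aw_ramp, aw_tent, branching_fraction,
                               combine_limitations, cyano_rates, darkness,
                               hetero_rates, light_response,
                               maintenance_and_decay, maintenance_requirement,
                               ph_window)


def make_chem(a_w, S_HCO3=2.4e-3, S_OA=0.0, T_star=25.0):
    return derive_chemistry(S_HCO3, S_OA, a_w, T_star)


def replete_cyano(p, M=1.0):
    return CyanoState(M_C=M, Q_SOC=0.5 * (p.Q_SOC_min + p.Q_SOC_max),
                      Q_N=0.5 * (p.Q_N_min + p.Q_N_max),
                      Q_ATP=0.5 * p.Q_ATP_max, Q_NADPH=0.5 * p.Q_NADPH_max)


def replete_hetero(p, M=0.2):
    return HeteroState(M_H=M, Q_SOC=0.5 * (p.Q_SOC_min + p.Q_SOC_max),
                       Q_N=0.5 * (p.Q_N_min + p.Q_N_max),
                       Q_ATP=0.5 * p.Q_ATP_max)


def rich_ex():
    return ExtracellularState(M_POL=0.1, M_CDB=0.1, M_NDB=0.01,
                              S_TOA=1.0, S_OAminus=0.1, S_HCO3=2.4e-3)


class TestLimitationPrimitives:
    @pytest.mark.parametrize("phis, expected_f, expected_name", [
        ({"a": 1.0, "b": 1.0, "c": 1.0}, 1.0, "a"),
        ({"x": 0.3, "y": 0.7}, 0.3, "x"),
        ({"x": 0.5, "y": 0.0, "z": 0.9}, 0.0, "y"),
    ])
    def test_liebig_minimum(self, phis, expected_f, expected_name):
        f, name = combine_limitations(phis)
        assert f == expected_f and name == expected_name

    def test_out_of_range_factor_rejected(self):
        with pytest.raises(ValueError):
            combine_limitations({"bad": 1.2})

    @pytest.mark.parametrize("a_w, expected", [
        (1.0, 1.0), (0.6, 0.0), (0.8, 0.5), (0.2, 0.0),
    ])
    def test_aw_ramp(self, a_w, expected):
        assert aw_ramp(a_w, 0.6) == pytest.approx(expected)

    @pytest.mark.parametrize("a_w, expected", [
        (1.0, 0.0), (0.8, 1.0), (0.6, 0.0), (0.9, 0.5), (0.7, 0.5),
    ])
    def test_aw_tent(self, a_w, expected):
        assert aw_tent(a_w, 0.6, 0.8) == pytest.approx(expected)

    def test_light_monod(self):
        assert light_response(0.0, 100.0) == 0.0
        assert light_response(100.0, 100.0) == pytest.approx(0.5)

    def test_light_haldane_interior_maximum(self):
        K_I, K_inh = 100.0, 3000.0
        I_grid = np.linspace(0.0, 10000.0, 20001)
        vals = np.array([light_response(I, K_I, K_inh) for I in I_grid])
        I_opt = math.sqrt(K_I * K_inh)
        assert abs(I_grid[vals.argmax()] - I_opt) < 1.0
        assert vals.max() == pytest.approx(1.0, abs=1e-6)   # normalized peak
        assert vals[-1] < vals.max()                        # photoinhibition

    @pytest.mark.parametrize("pH, expected", [
        (7.0, 1.0), (4.5, 0.0), (9.5, 0.0), (3.0, 0.0), (11.0, 0.0),
    ])
    def test_ph_window(self, pH, expected):
        assert ph_window(pH, 4.5, 9.5) == pytest.approx(expected)

    def test_ph_window_invalid_bounds(self):
        with pytest.raises(ValueError):
            ph_window(7.0, 9.0, 4.0)

    @pytest.mark.parametrize("S_O2, S_DIC, gamma, expected", [
        (0.0, 0.02, 10.0, 1.0),
        (0.002, 0.02, 10.0, 0.5),
        (0.004, 0.02, 10.0, 1.0 / 3.0),
    ])
    def test_branching_fraction(self, S_O2, S_DIC, gamma, expected):
        assert branching_fraction(S_O2, S_DIC, gamma) == pytest.approx(expected)

    def test_branching_zero_substrate_convention(self):
        assert branching_fraction(0.1, 0.0, 10.0) == 0.0


class TestMaintenance:
    def test_linear_demand_in_water_stress(self):
        assert maintenance_requirement(1.0, 0.01, 0.2) == pytest.approx(0.01)
        assert maintenance_requirement(0.0, 0.01, 0.2) == pytest.approx(0.21)
        assert (maintenance_requirement(0.7, 0.01, 0.2)
                > maintenance_requirement(0.9, 0.01, 0.2))

    def test_sufficiency_no_decay(self):
        f_main, f_d = maintenance_and_decay(omega=1.0, f_star_main=0.1,
                                            Q_ATP=10.0, k_d=0.005, K_ATP=0.01)
        assert f_main == pytest.approx(0.1)
        assert f_d == 0.0

    def test_total_deficit_full_decay(self):
        f_main, f_d = maintenance_and_decay(0.0, 0.1, 0.0, 0.005, 0.01)
        assert f_main == 0.0
        assert f_d == pytest.approx(0.005)

    def test_proportional_deficit(self):
        # omega at half the demand with ATP-replete pool: half-rate decay
        f_main, f_d = maintenance_and_decay(0.05, 0.1, 1e6, 0.005, 0.01)
        assert f_main == pytest.approx(0.05, rel=1e-4)
        assert f_d == pytest.approx(0.0025, rel=1e-4)

    def test_no_requirement_no_decay(self):
        assert maintenance_and_decay(0.0, 0.0, 0.0, 0.005, 0.01) == (0.0, 0.0)


class TestCyanoRates:
    def test_darkness_shuts_down_photosynthesis_and_growth(self, kinetics):
        pr = cyano_rates(replete_cyano(kinetics), rich_ex(), make_chem(0.9),
                         I=0.0, p=kinetics)
        for name in ("nc", "cy", "fix", "fix_co2", "photo", "photo_co2", "C_growth"):
            assert pr.rates[name] == 0.0
        # nighttime processes may run
        assert pr.rates["C_resp"] > 0.0

    def test_water_suppression_leaves_only_decay(self, kinetics):
        pr = cyano_rates(replete_cyano(kinetics), rich_ex(),
                         make_chem(kinetics.a_w_min), I=800.0, p=kinetics)
        for name in CYANO_PROCESSES:
            if name.startswith("C_d") or name == "C_main":
                continue
            assert pr.rates[name] == 0.0, name
        assert pr.rates["C_d"] == pytest.approx(kinetics.k_d * 1.0)

    def test_unlimited_nc_attains_maximum(self, kinetics):
        # every factor of the non-cyclic chain constructed to equal 1:
        # ideal water, optimal light, empty carrier pools
        I_opt = math.sqrt(kinetics.K_I * kinetics.K_I_inh)
        cy = CyanoState(M_C=2.0, Q_SOC=0.25, Q_N=0.1, Q_ATP=0.0, Q_NADPH=0.0)
        pr = cyano_rates(cy, rich_ex(), make_chem(1.0), I=I_opt, p=kinetics)
        assert pr.rates["nc"] == pytest.approx(kinetics.k_nc * 2.0, rel=1e-6)

    def test_branch_conservation_and_pure_fixation_without_oxygen(self, kinetics):
        p = kinetics
        cy = replete_cyano(p)
        chem = derive_chemistry(2.4e-3, 0.0, 0.9, 25.0)
        chem_no_o2 = type(chem)(S_CO2=chem.S_CO2, S_O2=0.0, S_HCO3=chem.S_HCO3,
                                S_DIC=chem.S_DIC, S_H=chem.S_H, pH=chem.pH,
                                a_w=chem.a_w, T_star=chem.T_star)
        pr = cyano_rates(cy, rich_ex(), chem_no_o2, I=500.0, p=p)
        assert pr.rates["photo"] + pr.rates["photo_co2"] == 0.0
        assert (pr.rates["fix"] + pr.rates["fix_co2"]
                == pytest.approx(p.k_fix * cy.M_C * pr.f["fix"]))

    def test_zero_biomass_zeroes_all_rates(self, kinetics):
        cy = CyanoState(M_C=0.0, Q_SOC=0.0, Q_N=0.0, Q_ATP=0.0, Q_NADPH=0.0)
        pr = cyano_rates(cy, rich_ex(), make_chem(0.9), I=500.0, p=kinetics)
        assert all(pr.rates[name] == 0.0 for name in CYANO_PROCESSES)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 2500.0),
           st.floats(0.0, 0.5), st.floats(0.0, 0.1))
    def test_rates_bounded_and_branches_conserve(self, a_w, I, Q_SOC, Q_ATP):
        p = KineticParams()
        cy = CyanoState(M_C=1.0, Q_SOC=Q_SOC, Q_N=0.1, Q_ATP=Q_ATP, Q_NADPH=0.05)
        pr = cyano_rates(cy, rich_ex(), make_chem(a_w), I=I, p=p)
        for name, k_max in p.max_rates.items():
            if name in pr.rates and name in CYANO_PROCESSES:
                assert -1e-12 <= pr.rates[name] <= k_max * cy.M_C + 1e-12
        total = (pr.rates["fix"] + pr.rates["fix_co2"]
                 + pr.rates["photo"] + pr.rates["photo_co2"])
        assert total == pytest.approx(p.k_fix * cy.M_C * pr.f["fix"], abs=1e-12)

    def test_monotone_in_water_activity(self, kinetics):
        # ramp-limited processes are non-decreasing in a_w on [a_w_min, 1]
        rates = []
        for a_w in np.linspace(kinetics.a_w_min, 1.0, 9):
            pr = cyano_rates(replete_cyano(kinetics), rich_ex(),
                             make_chem(a_w), I=300.0, p=kinetics)
            rates.append(pr.rates["nc"])
        assert all(b >= a - 1e-12 for a, b in zip(rates, rates[1:]))


class TestHeteroRates:
    def test_no_substrates_no_feeding(self, kinetics):
        ex = ExtracellularState(M_POL=0.0, M_CDB=0.0, M_NDB=0.0,
                                S_TOA=0.0, S_OAminus=0.0, S_HCO3=2.4e-3)
        pr = hetero_rates(replete_hetero(kinetics), ex, make_chem(0.9),
                          I=0.0, V=1e-4, p=kinetics)
        for name in ("POL_scav", "CDB_scav", "NDB_scav", "H_uptake"):
            assert pr.rates[name] == 0.0

    def test_water_suppression_leaves_only_decay(self, kinetics):
        pr = hetero_rates(replete_hetero(kinetics), rich_ex(),
                          make_chem(kinetics.a_w_min), I=0.0, V=1e-4, p=kinetics)
        for name in HETERO_PROCESSES:
            if name.startswith("H_d") or name == "H_main":
                continue
            assert pr.rates[name] == 0.0, name
        assert pr.rates["H_d"] > 0.0

    def test_empty_carbon_quota_stops_respiration_and_growth(self, kinetics):
        h = HeteroState(M_H=0.2, Q_SOC=kinetics.Q_SOC_min, Q_N=0.1, Q_ATP=0.05)
        pr = hetero_rates(h, rich_ex(), make_chem(0.9), I=0.0, V=1e-4, p=kinetics)
        assert pr.rates["H_resp"] == 0.0
        assert pr.rates["H_growth"] == 0.0

    def test_growth_runs_in_daylight(self, kinetics):
        # heterotrophs have no light dependence
        pr = hetero_rates(replete_hetero(kinetics), rich_ex(), make_chem(0.9),
                          I=1500.0, V=1e-4, p=kinetics)
        assert pr.rates["H_growth"] > 0.0

    def test_strict_paper_decay_variants(self, kinetics):
        # literal printed forms stay available behind flags
        f_main, f_d = maintenance_and_decay(0.05, 0.1, 1e6, 0.005, 0.01,
                                            strict_gamma=True)
        assert f_d == pytest.approx(0.005 * 0.5, rel=1e-4)
        strict = dataclasses.replace(kinetics, strict_hetero_decay_mass=True)
        h = HeteroState(M_H=0.01, Q_SOC=1e-3, Q_N=0.1, Q_ATP=0.0)
        pr = hetero_rates(h, rich_ex(), make_chem(0.9), I=0.0, V=1e-4,
                          p=strict, M_C=1.0)
        default = hetero_rates(h, rich_ex(), make_chem(0.9), I=0.0, V=1e-4,
                               p=kinetics, M_C=1.0)
        # decay flux scales with the cyanobacterial mass under the flag
        assert pr.rates["H_d"] > default.rates["H_d"]

    def test_darkness_factor_shape(self, kinetics):
        assert darkness(0.0, kinetics.K_I_dark) == 1.0
        assert darkness(kinetics.K_I_dark, kinetics.K_I_dark) == pytest.approx(0.5)
        assert darkness(2000.0, kinetics.K_I_dark) < 1e-3
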