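import numpy as np
import pytest
from dataclasses import replace

from oraflux.acat import (DEFAULT_ASF_GASTROPLUS, DEFAULT_ASF_OPTIMIZED,
                          FormulationSpec, Scenario, build_physiology,
                          parameter_sweep, regional_absorption, simulate_acat)
from oraflux.biopharm import WeibullFit
from oraflux.synthetic_data import gen_dissolution
from oraflux.biopharm import fit_weibull


@pytest.fixture(scope="module")
def grid():
    return np.arange(0.1, 30.01, 0.1)


@pytest.fixture(scope="module")
def fasted(drug):
    return build_physiology("fasted")


class TestBuildPhysiology:
    def test_optimized_asf_values(self, fasted):
        by_name = {c.name: c for c in fasted.compartments}
        assert by_name["Duodenum"].asf == pytest.approx(36.44)
        assert by_name["Stomach"].asf == 0.0
        assert by_name["AscColon"].asf == pytest.approx(1.038)

    def test_default_asf_column(self):
        phys = build_physiology("fasted", DEFAULT_ASF_GASTROPLUS)
        by_name = {c.name: c for c in phys.compartments}
        assert by_name["Duodenum"].asf == pytest.approx(2.673)

    def test_fed_solubilities_from_biorelevant_media(self):
        phys = build_physiology("fed")
        by_name = {c.name: c for c in phys.compartments}
        assert by_name["Stomach"].solubility_local == pytest.approx(24.0)
        assert by_name["Jejunum1"].solubility_local == pytest.approx(16.8)

    def test_fasted_gastric_ph_and_solubility(self, fasted):
        stomach = fasted.compartments[0]
        assert stomach.ph == pytest.approx(1.6)
        assert stomach.solubility_local == pytest.approx(11.0)

    def test_colon_water_fraction_reduced(self, fasted):
        colon = {c.name: c for c in fasted.compartments}["AscColon"]
        assert colon.water_fraction == pytest.approx(0.02)

    def test_fed_slows_gastric_emptying(self):
        fa = build_physiology("fasted")
        fe = build_physiology("fed")
        assert fe.gastric_emptying_half_time > fa.gastric_emptying_half_time

    def test_overrides_replace_fields_verbatim(self):
        phys = build_physiology("fasted",
                                overrides={"Stomach": {"fluid_volume": 250.0}})
        assert phys.compartments[0].fluid_volume == 250.0

    def test_missing_asf_entry_raises(self):
        with pytest.raises(KeyError):
            build_physiology("fasted", {"Stomach": 0.0})


class TestSimulateACAT:
    def test_zero_permeability_means_no_absorption(self, drug, disposition,
                                                   fasted, grid):
        no_perm = replace(drug, peff=1e-12)
        res = simulate_acat(no_perm, FormulationSpec("solution", 10.0),
                            fasted, disposition,
                            np.arange(0.5, 150.01, 0.5))
        assert res.metrics.f_percent == pytest.approx(0.0, abs=1e-6)
        # everything has washed out of the 21 h-mean-residence gut by 150 h
        assert res.mass_balance["exited"][-1] == pytest.approx(10.0,
                                                               rel=1e-2)

    def test_unlimited_solubility_and_asf_absorbs_everything(
            self, drug, disposition, grid):
        from oraflux.biopharm import SolubilityEntry, SolubilityTable
        huge = SolubilityTable((SolubilityEntry("x", 7.0, 1e7, "fasted"),))
        hot = replace(drug, solubility=huge)
        asf = {k: (1e6 if v > 0 else 1e6) for k, v in
               DEFAULT_ASF_OPTIMIZED.items()}
        phys = build_physiology("fasted", asf, solubility=huge)
        res = simulate_acat(hot, FormulationSpec("solution", 10.0), phys,
                            disposition, grid)
        assert res.metrics.f_percent > 99.0

    def test_mass_balance_holds_at_every_time(self, drug, disposition,
                                              fasted, grid):
        res = simulate_acat(drug, FormulationSpec("ir_tablet_psd", 20.0,
                                                  psd=drug.psd),
                            fasted, disposition, grid)
        mb = res.mass_balance
        total = (mb["undissolved"] + mb["dissolved"] + mb["absorbed"]
                 + mb["exited"])
        assert np.max(np.abs(total - 20.0)) / 20.0 < 1e-3

    def test_solver_tolerance_convergence(self, drug, disposition, fasted,
                                          grid):
        """Tightening rtol tenfold moves Cmax and AUC by <0.1%."""
        form = FormulationSpec("solution", 10.0)
        a = simulate_acat(drug, form, fasted, disposition, grid, rtol=1e-8)
        b = simulate_acat(drug, form, fasted, disposition, grid, rtol=1e-9)
        assert a.metrics.cmax == pytest.approx(b.metrics.cmax, rel=1e-3)
        assert a.metrics.auc_last == pytest.approx(b.metrics.auc_last,
                                                   rel=1e-3)

    def test_transit_absorption_analytic_oracle(self, drug, disposition,
                                                grid):
        """With no solubility limit, sequential first-order transit +
        absorption has the closed-form absorbed fraction
        sum_c ka_c/(ka_c+kt_c) * prod_{j<c} kt_j/(kt_j+ka_j)."""
        from oraflux.biopharm import SolubilityEntry, SolubilityTable
        huge = SolubilityTable((SolubilityEntry("x", 7.0, 1e9, "fasted"),))
        hot = replace(drug, solubility=huge)
        phys = build_physiology("fasted", solubility=huge)
        res = simulate_acat(hot, FormulationSpec("solution", 10.0), phys,
                            disposition, np.arange(0.1, 60.01, 0.1))
        kt = np.array([c.transit_rate for c in phys.compartments])
        ka = hot.peff * 1e-4 * 3600 * np.array([c.asf
                                                for c in phys.compartments])
        frac, survive = 0.0, 1.0
        for k_abs, k_tr in zip(ka, kt):
            frac += survive * k_abs / (k_abs + k_tr)
            survive *= k_tr / (k_abs + k_tr)
        assert res.metrics.f_percent / 100 == pytest.approx(frac, rel=2e-3)

    def test_reference_solution_run_within_twofold_of_printed(
            self, drug, disposition, fasted, grid):
        """Fasted 10 mg solution with the optimized ASFs lands within
        2-fold of the printed Cmax 212.23 ug/L and AUC 1058 ug.h/L."""
        res = simulate_acat(drug, FormulationSpec("solution", 10.0), fasted,
                            disposition, grid)
        assert 212.23 / 2 <= res.metrics.cmax <= 212.23 * 2
        assert 1058 / 2 <= res.metrics.auc_inf <= 1058 * 2

    def test_fed_beats_fasted_for_release_driven_tablet(self, drug,
                                                        disposition, grid):
        wf = fit_weibull(gen_dissolution("fasted", replicates=1,
                                         noise_cv=0.0)[0])
        we = fit_weibull(gen_dissolution("fed", replicates=1,
                                         noise_cv=0.0)[0])
        fa = simulate_acat(drug, FormulationSpec("release_profile_driven",
                                                 20.0, release_curve=wf),
                           build_physiology("fasted"), disposition, grid)
        fe = simulate_acat(drug, FormulationSpec("release_profile_driven",
                                                 20.0, release_curve=we),
                           build_physiology("fed"), disposition, grid)
        assert fe.metrics.auc_inf >= fa.metrics.auc_inf
        fa_reg = regional_absorption(fa)
        fe_reg = regional_absorption(fe)
        assert (fe_reg["Duodenum"] + fe_reg["Jejunum1"]
                > fa_reg["Duodenum"] + fa_reg["Jejunum1"])


class TestRegionalAbsorption:
    def test_zero_permeability_all_zero(self, drug, disposition, fasted,
                                        grid):
        res = simulate_acat(replace(drug, peff=1e-12),
                            FormulationSpec("solution", 5.0), fasted,
                            disposition, grid)
        assert all(v == pytest.approx(0.0, abs=1e-8)
                   for v in regional_absorption(res).values())

    def test_fractions_sum_to_f_percent(self, drug, disposition, fasted,
                                        grid):
        res = simulate_acat(drug, FormulationSpec("solution", 10.0), fasted,
                            disposition, grid)
        total = sum(regional_absorption(res).values())
        assert total == pytest.approx(res.metrics.f_percent / 100, rel=1e-6)

    def test_single_compartment_absorption(self, drug, disposition, grid):
        asf = {k: 0.0 for k in DEFAULT_ASF_OPTIMIZED}
        asf["Jejunum1"] = 36.0
        phys = build_physiology("fasted", asf)
        res = simulate_acat(drug, FormulationSpec("solution", 10.0), phys,
                            disposition, grid)
        reg = regional_absorption(res)
        assert reg["Jejunum1"] == pytest.approx(res.metrics.f_percent / 100,
                                                rel=1e-6)
        assert sum(v for k, v in reg.items() if k != "Jejunum1") < 1e-9


class TestParameterSweep:
    @pytest.fixture(scope="class")
    def base(self, drug, disposition):
        return Scenario(drug,
                        FormulationSpec("ir_tablet_psd", 20.0, psd=drug.psd),
                        build_physiology("fasted"), disposition,
                        np.arange(0.2, 24.01, 0.2))

    def test_f_percent_monotone_in_peff(self, base):
        rows = parameter_sweep(base, "peff", [0.1, 0.31, 1.0], "f_percent")
        vals = [m for _, m in rows]
        assert vals == sorted(vals)

    def test_f_percent_antimonotone_in_particle_radius(self, base):
        rows = parameter_sweep(base, "psd_scale", [0.5, 2.0, 8.0],
                               "f_percent")
        vals = [m for _, m in rows]
        assert vals == sorted(vals, reverse=True)

    def test_single_value_equals_base_run(self, base):
        rows = parameter_sweep(base, "peff", [base.drug.peff], "cmax")
        res = simulate_acat(base.drug, base.formulation, base.physiology,
                            base.disposition, base.grid)
        assert rows[0][1] == pytest.approx(res.metrics.cmax, rel=1e-9)

    def test_unknown_parameter_rejected(self, base):
        with pytest.raises(ValueError):
            parameter_sweep(base, "not_a_parameter", [1.0])
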