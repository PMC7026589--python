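"""Damage model: lesion deposition, trapping kinetics, tail transform, viability."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hepacomet.model import (
    DEFAULT_PARAMS,
    ConfigurationError,
    DamageScenario,
    Genotype,
    Inhibitors,
    LesionState,
    ValidationError,
    lesions_from_dose,
    scenario_tail_pct,
    ssb_timecourse,
    tail_fraction_from_state,
    viability,
)
from hepacomet.presets import agent_preset, make_scenario


def sc(agent, dose, **kw):
    return make_scenario(agent, dose, **kw)


class TestLesionsFromDose:
    @pytest.mark.parametrize(
        "dose_gy,expected", [(1.0, 1000.0), (3.6, 3600.0), (9.0, 9000.0)]
    )
    def test_gamma_deposits_1000_ssb_per_gy(self, dose_gy, expected):
        state = lesions_from_dose(
            sc("gamma", dose_gy, time_h=0.0), agent_preset("gamma")
        )
        assert state.ssb == pytest.approx(expected)
        assert state.bulky == state.ber == state.crosslinks == 0

    @pytest.mark.parametrize("agent", ["gamma", "uv_c", "aflatoxin_b1", "cisplatin"])
    def test_zero_dose_deposits_nothing(self, agent):
        state = lesions_from_dose(sc(agent, 0.0), agent_preset(agent))
        assert state.bulky == state.ber == state.crosslinks == state.ssb == 0

    def test_cyp_inhibitor_suppresses_activated_agent(self):
        preset = agent_preset("aflatoxin_b1")
        base = lesions_from_dose(sc("aflatoxin_b1", 1.0), preset)
        ket = lesions_from_dose(sc("aflatoxin_b1", 1.0, ket=True), preset)
        # HepaRG KET residual is 1% CYP3A4 activity
        assert ket.bulky == pytest.approx(0.01 * base.bulky)

    def test_no_metabolic_capacity_no_lesions(self):
        state = lesions_from_dose(
            sc("aflatoxin_b1", 3.0, cell_line_name="TK6"), agent_preset("aflatoxin_b1")
        )
        assert state.bulky == 0.0

    def test_hepg2_cyp3a4_is_one_percent_of_heparg(self):
        preset = agent_preset("aflatoxin_b1")
        heparg = lesions_from_dose(sc("aflatoxin_b1", 1.0), preset)
        hepg2 = lesions_from_dose(
            sc("aflatoxin_b1", 1.0, cell_line_name="HepG2"), preset
        )
        assert hepg2.bulky == pytest.approx(0.01 * heparg.bulky)

    def test_crosslinker_populates_crosslinks_only(self):
        state = lesions_from_dose(sc("cisplatin", 10.0), agent_preset("cisplatin"))
        assert state.crosslinks > 0 and state.bulky == 0 and state.ssb == 0

    def test_mismatched_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            lesions_from_dose(sc("uv_c", 5.0), agent_preset("gamma"))

    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            DamageScenario(agent="uv_c", dose=-1.0)


class TestSsbTimecourse:
    def test_time_zero_returns_baseline_only(self):
        lesions = LesionState(bulky=1e5)
        out = ssb_timecourse(lesions, sc("uv_c", 5.0, time_h=0.0))
        assert out == pytest.approx(DEFAULT_PARAMS.baseline_ssb)

    @pytest.mark.parametrize("genotype", [Genotype.XPG_NULL, Genotype.XPA_NULL])
    def test_incision_dead_genotypes_trap_nothing(self, genotype):
        lesions = LesionState(bulky=1e5)
        out = ssb_timecourse(
            lesions, sc("uv_c", 5.0, genotype=genotype, hu_arac=True)
        )
        assert out == pytest.approx(DEFAULT_PARAMS.baseline_ssb)

    def test_epistasis_null_genotype_below_5pct_of_trapped_wt(self):
        lesions = LesionState(bulky=1e5)
        base = DEFAULT_PARAMS.baseline_ssb
        wt = ssb_timecourse(lesions, sc("uv_c", 5.0, hu_arac=True)) - base
        for geno in (Genotype.XPG_NULL, Genotype.XPA_NULL):
            null = ssb_timecourse(lesions, sc("uv_c", 5.0, genotype=geno, hu_arac=True)) - base
            assert null <= 0.05 * wt

    def test_ligation_dead_mutant_accumulates_without_inhibitor(self):
        lesions = LesionState(bulky=1e5)
        e791a = ssb_timecourse(lesions, sc("uv_c", 5.0, genotype=Genotype.XPG_E791A))
        wt = ssb_timecourse(lesions, sc("uv_c", 5.0))
        assert e791a > 5 * wt

    def test_zero_resolution_limit_is_cumulative_and_monotone(self):
        # k_res -> 0: trapped SSBs equal cumulative incisions, nondecreasing
        from dataclasses import replace

        params = replace(DEFAULT_PARAMS, k_res=0.0)
        lesions = LesionState(bulky=1e4)
        times = np.linspace(0.0, 6.0, 25)
        vals = [
            ssb_timecourse(lesions, sc("uv_c", 5.0, time_h=float(t)), params)
            for t in times
        ]
        assert np.all(np.diff(vals) >= -1e-9)
        expected = 1e4 * (1 - math.exp(-params.k_inc * 6.0))
        assert vals[-1] - params.baseline_ssb == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize(
        "hu,genotype",
        [(False, Genotype.WT), (True, Genotype.WT), (True, Genotype.XPG_E791A)],
    )
    def test_closed_form_matches_ode_integration(self, hu, genotype):
        """Independent oracle: numerically integrate the two-compartment
        kinetics and compare with the closed-form timecourse."""
        p = DEFAULT_PARAMS
        lesions = LesionState(bulky=5e4, ber=2e4, ssb=1e3)
        k_in = p.k_inc
        k_out = 0.0 if genotype is Genotype.XPG_E791A else p.k_res * (
            p.f_inhib if hu else 1.0
        )
        ber_out = p.ber_k_res * (p.f_inhib if hu else 1.0)
        k_dir = p.k_res * (p.f_inhib if hu else 1.0)

        def rhs(t, y):
            bulky, s_b, ber, s_e, s_d = y
            return [
                -k_in * bulky,
                k_in * bulky - k_out * s_b,
                -p.ber_k_inc * ber,
                p.ber_k_inc * ber - ber_out * s_e,
                -k_dir * s_d,
            ]

        for t in (0.25, 1.0, 4.0):
            sol = solve_ivp(
                rhs, (0, t), [lesions.bulky, 0, lesions.ber, 0, lesions.ssb],
                rtol=1e-10, atol=1e-8,
            )
            numeric = sol.y[1, -1] + sol.y[3, -1] + sol.y[4, -1]
            scenario = sc("uv_c", 5.0, time_h=t, genotype=genotype, hu_arac=hu)
            closed = ssb_timecourse(lesions, scenario)
            spont = closed - numeric - p.baseline_ssb  # spontaneous trapping term
            if hu or genotype is Genotype.XPG_E791A:
                assert 0 <= spont <= p.spont_trap_ssb + 1e-6
                closed -= spont
            assert closed - p.baseline_ssb == pytest.approx(numeric, rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            DamageScenario(agent="uv_c", dose=1.0, time_h=-0.5)


class TestTailTransform:
    def test_baseline_maps_to_basal_ten_percent(self):
        assert tail_fraction_from_state(DEFAULT_PARAMS.baseline_ssb) == pytest.approx(10.0)

    def test_saturates_at_75_percent(self):
        assert tail_fraction_from_state(1e9) == pytest.approx(75.0, abs=1e-6)

    def test_monotone_nondecreasing_in_ssb(self):
        grid = np.geomspace(1.0, 1e7, 60)
        vals = [tail_fraction_from_state(s) for s in grid]
        assert np.all(np.diff(vals) >= 0)
        assert all(10.0 <= v <= 75.0 for v in vals)

    def test_crosslinks_suppress_migration_below_background(self):
        heavy = tail_fraction_from_state(DEFAULT_PARAMS.baseline_ssb, crosslinks=2e4)
        assert heavy < 10.0


class TestScenarioLandmarks:
    """The shipped presets must evaluate to the assay's landmark values."""

    def test_untreated_is_basal(self, landmarks):
        assert scenario_tail_pct(
            landmarks["untreated"], agent_preset("uv_c")
        ) == pytest.approx(10.0, abs=1e-9)

    def test_uv_only_one_hour_is_twenty(self, landmarks):
        assert scenario_tail_pct(
            landmarks["uv_1h"], agent_preset("uv_c")
        ) == pytest.approx(20.0, abs=1e-9)

    def test_uv_trapped_in_steady_state_band(self, landmarks):
        val = scenario_tail_pct(landmarks["uv_1h_huarac"], agent_preset("uv_c"))
        assert 73.0 <= val <= 78.0

    def test_trapped_plateau_holds_to_four_hours(self):
        for t in (0.5, 1.0, 2.0, 4.0):
            val = scenario_tail_pct(
                sc("uv_c", 5.0, time_h=t, cell_line_name="fibroblast", hu_arac=True),
                agent_preset("uv_c"),
            )
            assert 73.0 <= val <= 78.0

    def test_trapped_to_control_ratio_is_about_four(self, landmarks):
        trapped = scenario_tail_pct(landmarks["uv_1h_huarac"], agent_preset("uv_c"))
        control = scenario_tail_pct(landmarks["uv_1h"], agent_preset("uv_c"))
        assert round(trapped / control) == 4

    def test_huarac_alone_gives_slight_nonsignificant_increase(self, landmarks):
        val = scenario_tail_pct(landmarks["huarac_only"], agent_preset("uv_c"))
        assert 10.0 < val < 11.5

    def test_cisplatin_delta_nonpositive_at_every_dose(self):
        preset = agent_preset("cisplatin")
        basal = scenario_tail_pct(sc("cisplatin", 0.0), preset)
        for dose in (1.0, 5.0, 10.0, 20.0, 40.0, 100.0):
            val = scenario_tail_pct(sc("cisplatin", dose), preset)
            assert val - basal <= 0

    @pytest.mark.parametrize("agent", ["uv_c", "aflatoxin_b1", "ndma", "etoposide"])
    def test_tail_monotone_in_dose_for_non_crosslinkers(self, agent):
        preset = agent_preset(agent)
        unit = {"uv_c": 2.0}.get(agent, 1.0)
        vals = [
            scenario_tail_pct(sc(agent, d * unit, hu_arac=True), preset)
            for d in [0, 0.5, 1, 2, 4, 8]
        ]
        assert np.all(np.diff(vals) >= 0)


class TestViability:
    def test_vehicle_is_fully_viable(self):
        v = viability(sc("etoposide", 0.0, vehicle=True), agent_preset("etoposide"))
        assert v == 1.0

    def test_huarac_cotreatment_keeps_at_least_80pct_survival(self):
        v = viability(sc("uv_c", 0.0, hu_arac=True), agent_preset("uv_c"))
        assert v >= 0.80

    def test_pca_top_dose_kills_about_half(self):
        v = viability(sc("pca", 5.0), agent_preset("pca"))
        assert v == pytest.approx(0.50, abs=0.02)

    def test_cytotoxic_positives_fall_below_half(self):
        assert viability(sc("hydroquinone", 0.33), agent_preset("hydroquinone")) < 0.50
        assert viability(sc("chloramphenicol", 3.1), agent_preset("chloramphenicol")) < 0.50
        # chloramphenicol below its top dose stays viable
        assert viability(sc("chloramphenicol", 1.55), agent_preset("chloramphenicol")) > 0.50

    @pytest.mark.parametrize("agent", ["pca", "hydroquinone", "cisplatin", "ndma"])
    def test_monotone_nonincreasing_in_dose(self, agent):
        preset = agent_preset(agent)
        doses = np.linspace(0, 50, 30)
        vals = [viability(sc(agent, float(d)), preset) for d in doses]
        assert np.all(np.diff(vals) <= 1e-12)
        assert all(0.0 <= v <= 1.0 for v in vals)
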