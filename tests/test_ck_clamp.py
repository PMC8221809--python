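import math

import numpy as np
import pytest
from scipy.optimize import brentq

from helpers import species_fraction_oracle
from oxphoskit.ck_clamp import (
    DEFAULT_PARAMS,
    GAS_CONSTANT_KJ,
    ClampComposition,
    EquilibriumError,
    ThermoParameterSet,
    ValidationError,
    apparent_ck_constant,
    binding_polynomial,
    delta_g_atp,
    solve_adp,
    solve_free_mg,
    titration_curve,
)

MM = 1e-3


class TestApparentCkConstant:
    def test_identity_at_reference_conditions(self):
        p = DEFAULT_PARAMS
        k = apparent_ck_constant(p, p.ref_ph, p.ref_mg_free, p.ref_temperature)
        assert k == p.k_ck_ref

    def test_matches_species_fraction_oracle(self):
        p = DEFAULT_PARAMS
        ph, mg = p.ref_ph + 0.5, p.ref_mg_free
        polys = species_fraction_oracle(p.binding_log10, ph, mg)
        polys_ref = species_fraction_oracle(p.binding_log10, p.ref_ph, p.ref_mg_free)
        expected = (
            p.k_ck_ref
            * (10**-ph * polys["atp"] / (polys["adp"] * polys["pcr"]))
            / (10**-p.ref_ph * polys_ref["atp"] / (polys_ref["adp"] * polys_ref["pcr"]))
        )
        got = apparent_ck_constant(p, ph, mg, p.ref_temperature)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_ph_sweep_smooth_and_monotone(self):
        p = DEFAULT_PARAMS
        phs = np.linspace(6.5, 7.5, 21)
        ks = [apparent_ck_constant(p, ph, 1e-3, 310.15) for ph in phs]
        # oracle direction: the explicit proton factor dominates -> K' falls with pH
        polys_lo = species_fraction_oracle(p.binding_log10, 6.5, 1e-3)
        polys_hi = species_fraction_oracle(p.binding_log10, 7.5, 1e-3)
        direction = (
            10**-6.5 * polys_lo["atp"] / (polys_lo["adp"] * polys_lo["pcr"])
            - 10**-7.5 * polys_hi["atp"] / (polys_hi["adp"] * polys_hi["pcr"])
        )
        assert direction > 0
        assert all(a > b for a, b in zip(ks, ks[1:]))
        rel_steps = np.diff(np.log(ks))
        assert np.all(np.abs(np.diff(rel_steps)) < 0.05)  # smooth

    def test_out_of_range_names_field(self):
        with pytest.raises(ValidationError, match="ph"):
            apparent_ck_constant(DEFAULT_PARAMS, 4.0, 1e-3, 310.15)
        with pytest.raises(ValidationError, match="temperature"):
            apparent_ck_constant(DEFAULT_PARAMS, 7.0, 1e-3, 400.0)


class TestSolveAdp:
    def test_direct_arithmetic(self, identity_params):
        comp = ClampComposition.from_millimolar(5, 5, 5, 10, 5, ph=7.2)
        adp = solve_adp(comp, identity_params, mg_free_override=1e-3)
        assert adp == pytest.approx(50e-6, rel=1e-12)

    def test_zero_creatine(self, identity_params):
        comp = ClampComposition.from_millimolar(5, 5, 0, 10, 5, ph=7.2)
        assert solve_adp(comp, identity_params) == 0.0

    def test_pcr_doubling_halves_adp(self, identity_params):
        c1 = ClampComposition.from_millimolar(5, 5, 5, 10, 5, ph=7.2)
        c2 = ClampComposition.from_millimolar(5, 10, 5, 10, 5, ph=7.2)
        a1 = solve_adp(c1, identity_params, mg_free_override=1e-3)
        a2 = solve_adp(c2, identity_params, mg_free_override=1e-3)
        assert a2 == pytest.approx(a1 / 2, rel=1e-12)

    def test_zero_pcr_is_undefined(self, identity_params):
        comp = ClampComposition.from_millimolar(5, 0, 5, 10, 5, ph=7.2)
        with pytest.raises(EquilibriumError):
            solve_adp(comp, identity_params)

    def test_bounded_by_total_atp_in_physiological_range(self):
        comp = ClampComposition.from_millimolar(5, 6, 5, 10, 5, ph=7.2)
        adp = solve_adp(comp)
        assert 0 < adp < comp.atp_total

    def test_agrees_with_root_finding_speciation_oracle(self):
        """Conservation-based free-Mg root + CK expression, 100 random mixes."""
        rng = np.random.default_rng(7)
        p = DEFAULT_PARAMS
        b = {k: 10.0**v for k, v in p.binding_log10.items()}
        for _ in range(100):
            comp = ClampComposition.from_millimolar(
                atp_total=rng.uniform(1, 10),
                pcr=rng.uniform(0.5, 25),
                cr=rng.uniform(1, 20),
                pi_total=rng.uniform(1, 20),
                mg_total=rng.uniform(1, 10),
                ph=rng.uniform(6.8, 7.6),
            )
            h = 10.0**-comp.ph

            def conservation(m, adp):
                bound = 0.0
                for sp, total in (
                    ("atp", comp.atp_total), ("adp", adp),
                    ("pi", comp.pi_total), ("pcr", comp.pcr),
                ):
                    if sp == "atp":
                        w = m * b["mg_atp"] + h * b["h_atp"] * m * b["mg_hatp"]
                    elif sp == "adp":
                        w = m * b["mg_adp"] + h * b["h_adp"] * m * b["mg_hadp"]
                    elif sp == "pi":
                        w = m * b["mg_pi"]
                    else:
                        w = m * b["mg_pcr"]
                    bound += total * w / binding_polynomial(sp, h, m, p)
                return m + bound - comp.mg_total

            adp_oracle = 0.0
            for _ in range(60):
                m = brentq(conservation, 1e-15, comp.mg_total, args=(adp_oracle,), xtol=1e-16)
                k = apparent_ck_constant(p, comp.ph, m, comp.temperature)
                new = comp.atp_total * comp.cr / (k * comp.pcr)
                if abs(new - adp_oracle) < 1e-16:
                    break
                adp_oracle = new
            assert solve_adp(comp, p) == pytest.approx(adp_oracle, abs=1e-9)


class TestDeltaG:
    # frozen model outputs for the standard composition (regression anchors)
    FROZEN = {1.0: -53.900, 6.0: -58.521, 15.0: -60.883, 21.0: -61.750}

    @pytest.mark.parametrize("pcr_mm,expected", sorted(FROZEN.items()))
    def test_standard_composition_regression(self, pcr_mm, expected):
        comp = ClampComposition.from_millimolar(5, pcr_mm, 5, 10, 5, ph=7.2)
        assert delta_g_atp(comp) == pytest.approx(expected, abs=2e-3)

    def test_log_term_vanishes_when_quotient_is_one(self):
        params = ThermoParameterSet(
            k_ck_ref=100.0, ref_ph=7.2, ref_mg_free=1e-3, ref_temperature=310.15
        )
        # Cr * Pi / (K' * PCr) = 1 M  =>  dG == dG0' at reference conditions
        comp = ClampComposition(
            atp_total=5e-3, pcr=0.01, cr=1.0, pi_total=1.0, mg_total=5e-3, ph=7.2
        )
        dg = delta_g_atp(comp, params, mg_free_override=1e-3)
        assert dg == pytest.approx(params.dg0_atp_ref, abs=1e-9)

    def test_more_negative_with_larger_pcr(self, methods_composition):
        from dataclasses import replace

        lo = delta_g_atp(replace(methods_composition, pcr=1 * MM))
        hi = delta_g_atp(replace(methods_composition, pcr=21 * MM))
        assert hi < lo

    def test_zero_atp_or_pi_raises(self):
        with pytest.raises(EquilibriumError):
            delta_g_atp(ClampComposition.from_millimolar(0, 1, 5, 10, 5))
        with pytest.raises(EquilibriumError):
            delta_g_atp(ClampComposition.from_millimolar(5, 1, 5, 0, 5))

    def test_units_convention_round_trip(self):
        a = ClampComposition.from_millimolar(5, 6, 5, 10, 5, ph=7.2)
        b = ClampComposition(
            atp_total=0.005, pcr=0.006, cr=0.005, pi_total=0.010, mg_total=0.005, ph=7.2
        )
        assert delta_g_atp(a) == delta_g_atp(b)


class TestTitrationCurve:
    def test_printed_protocol_monotone_and_tagged(self, methods_composition):
        pts = titration_curve(methods_composition, [1 * MM, 6 * MM, 15 * MM, 21 * MM])
        dgs = [p.dg_atp for p in pts]
        assert all(b < a for a, b in zip(dgs, dgs[1:]))
        assert all(p.source_label for p in pts)
        assert all(p.atp_adp_ratio == pytest.approx(
            methods_composition.atp_total / p.adp_free) for p in pts)

    def test_singleton_equals_delta_g(self, methods_composition):
        from dataclasses import replace

        (pt,) = titration_curve(methods_composition, [6 * MM])
        assert pt.dg_atp == delta_g_atp(replace(methods_composition, pcr=6 * MM))

    def test_non_monotone_levels_rejected(self, methods_composition):
        with pytest.raises(ValidationError):
            titration_curve(methods_composition, [6 * MM, 1 * MM])
        with pytest.raises(ValidationError):
            titration_curve(methods_composition, [1 * MM, 1 * MM])

    def test_monotone_decreasing_on_random_compositions(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            comp = ClampComposition.from_millimolar(
                atp_total=rng.uniform(1, 10), pcr=1.0,
                cr=rng.uniform(1, 20), pi_total=rng.uniform(1, 20),
                mg_total=rng.uniform(1, 10), ph=rng.uniform(6.8, 7.6),
                temperature=rng.uniform(298, 313),
            )
            levels = np.sort(rng.uniform(0.5, 30, size=4)) * MM
            if np.any(np.diff(levels) <= 0):
                continue
            dgs = [p.dg_atp for p in titration_curve(comp, list(levels))]
            assert all(b < a for a, b in zip(dgs, dgs[1:]))


class TestValidation:
    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError, match="atp_total"):
            ClampComposition(atp_total=-1.0, pcr=1e-3, cr=1e-3, pi_total=1e-3, mg_total=0)

    def test_ph_and_temperature_ranges(self):
        with pytest.raises(ValidationError, match="ph"):
            ClampComposition.from_millimolar(5, 1, 5, 10, 5, ph=4.0)
        with pytest.raises(ValidationError, match="temperature"):
            ClampComposition.from_millimolar(5, 1, 5, 10, 5, temperature=350.0)

    def test_source_label_is_mandatory(self):
        with pytest.raises(ValidationError, match="source_label"):
            ThermoParameterSet(source_label="")

    def test_free_mg_fixed_point_conserves_mass(self, methods_composition):
        p = DEFAULT_PARAMS
        m = solve_free_mg(methods_composition, p, tol=1e-12)
        h = 10.0**-methods_composition.ph
        b = {k: 10.0**v for k, v in p.binding_log10.items()}
        bound = (
            methods_composition.atp_total
            * (m * b["mg_atp"] + h * b["h_atp"] * m * b["mg_hatp"])
            / binding_polynomial("atp", h, m, p)
            + methods_composition.pi_total * m * b["mg_pi"] / binding_polynomial("pi", h, m, p)
            + methods_composition.pcr * m * b["mg_pcr"] / binding_polynomial("pcr", h, m, p)
        )
        assert m + bound == pytest.approx(methods_composition.mg_total, abs=1e-9)
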