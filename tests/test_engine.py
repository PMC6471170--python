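"""PK engine: rate law, clearances, simulation against closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalpk.compounds import apply_perturbation
from renalpk.engine import (
    DoseRegimen,
    hepatic_clearance,
    intrinsic_clearance,
    mm_rate,
    renal_clearance,
    simulate,
)
from renalpk.nca import compute_nca


def auc_pipeline(compound, subject, dose=60.0, mode="linear"):
    """Simulate with a grid long enough for the terminal phase, then NCA."""
    probe = simulate(compound, subject, DoseRegimen(dose), t_end=48.0, n_points=25)
    t_half = np.log(2.0) / probe.meta["k_el"]
    t_end = max(48.0, 9.0 * t_half)
    prof = simulate(compound, subject, DoseRegimen(dose), t_end=t_end,
                    n_points=3001, mode=mode)
    return compute_nca(prof)


class TestMMRate:
    def test_half_saturation(self):
        assert mm_rate(s=20.0, vmax=10.0, km=20.0, r=0.0) == pytest.approx(5.0)

    def test_inhibition_doubles_apparent_km(self):
        assert mm_rate(s=20.0, vmax=10.0, km=20.0, r=1.0) == pytest.approx(10.0 / 3)

    def test_linear_range_intrinsic_clearance(self):
        s = 1e-9
        for r in (0.0, 4.0):
            assert mm_rate(s, 10.0, 20.0, r) / s == pytest.approx(
                10.0 / (20.0 * (1 + r)), rel=1e-6
            )

    @settings(max_examples=200, deadline=None)
    @given(
        s1=st.floats(0.01, 1e3),
        s2=st.floats(0.01, 1e3),
        r1=st.floats(0, 100),
        r2=st.floats(0, 100),
    )
    def test_monotone_in_substrate_and_inhibition(self, s1, s2, r1, r2):
        lo_s, hi_s = sorted((s1, s2))
        lo_r, hi_r = sorted((r1, r2))
        assert mm_rate(hi_s, 5.0, 10.0, lo_r) >= mm_rate(lo_s, 5.0, 10.0, lo_r)
        assert mm_rate(lo_s, 5.0, 10.0, hi_r) <= mm_rate(lo_s, 5.0, 10.0, lo_r)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mm_rate(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            mm_rate(1.0, 1.0, 1.0, r=-0.5)


class TestClearances:
    def test_clint_linear_in_abundance(self, nifedipine, healthy_subject):
        import dataclasses

        doubled = dataclasses.replace(
            healthy_subject,
            enzyme_abundance={
                k: 2 * v for k, v in healthy_subject.enzyme_abundance.items()
            },
        )
        assert intrinsic_clearance(nifedipine, doubled) == pytest.approx(
            2 * intrinsic_clearance(nifedipine, healthy_subject)
        )

    def test_clint_scales_inverse_one_plus_r(
        self, single_pathway_low_extraction, healthy_subject
    ):
        c0 = intrinsic_clearance(single_pathway_low_extraction, healthy_subject)
        c1 = intrinsic_clearance(
            apply_perturbation(single_pathway_low_extraction, r_map={"CYP3A4": 1.0}),
            healthy_subject,
        )
        assert c1 == pytest.approx(c0 / 2)

    def test_clint_additive_over_pathways(self, nifedipine, healthy_subject):
        """Inhibiting one of two pathways to extinction leaves the other's share."""
        total = intrinsic_clearance(nifedipine, healthy_subject)
        inhibited = intrinsic_clearance(
            apply_perturbation(nifedipine, r_map={"CYP3A4": 1e12}), healthy_subject
        )
        import dataclasses

        only_3a5 = dataclasses.replace(
            nifedipine, pathways=(nifedipine.pathway("CYP3A5"),)
        )
        assert inhibited == pytest.approx(
            intrinsic_clearance(only_3a5, healthy_subject), rel=1e-6
        )
        assert inhibited < total

    def test_well_stirred_flow_limit(self):
        assert hepatic_clearance(1e12, 0.5, 90.0) == pytest.approx(90.0, rel=1e-6)

    def test_well_stirred_restrictive_limit(self):
        fu_b, clint, q = 0.01, 400.0, 90.0  # fu_b*clint/q = 0.044
        cl = hepatic_clearance(clint, fu_b, q)
        assert cl == pytest.approx(fu_b * clint, rel=0.05)
        assert hepatic_clearance(clint, 2 * fu_b, q) == pytest.approx(2 * cl, rel=0.05)

    @settings(max_examples=100, deadline=None)
    @given(
        clint=st.floats(0.1, 1e5),
        fu_b=st.floats(1e-3, 1.0),
        q=st.floats(30.0, 150.0),
    )
    def test_well_stirred_closed_form_and_bound(self, clint, fu_b, q):
        cl = hepatic_clearance(clint, fu_b, q)
        assert cl == pytest.approx(q * fu_b * clint / (q + fu_b * clint), rel=1e-12)
        assert 0 < cl < q

    def test_renal_clearance_proportional_to_fu_and_gfr(self, healthy_subject):
        import dataclasses

        from renalpk.compounds import load_compound

        zdv = load_compound("zidovudine")
        cl = renal_clearance(zdv, healthy_subject)
        assert cl == pytest.approx(
            zdv.fu * healthy_subject.gfr * 0.18 * 0.06, rel=1e-12
        )
        half_gfr = dataclasses.replace(healthy_subject, gfr=healthy_subject.gfr / 2)
        assert renal_clearance(zdv, half_gfr) == pytest.approx(cl / 2)


class TestSimulate:
    def test_null_dose_gives_zero_profile(self, nifedipine, healthy_subject):
        prof = simulate(nifedipine, healthy_subject, DoseRegimen(0.0))
        assert np.all(prof.conc == 0)

    def test_oral_profile_starts_at_zero(self, nifedipine, healthy_subject):
        prof = simulate(nifedipine, healthy_subject, DoseRegimen(60.0))
        assert prof.conc[0] == 0.0
        assert np.all(prof.conc >= 0)

    def test_ode_matches_closed_form_linear_solution(
        self, single_pathway_low_extraction, healthy_subject
    ):
        """Numerical integration reproduces the analytic oral solution.

        The compound operates far below KM, so the saturable ODE system is an
        independent route to the same linear kinetics.
        """
        lin = auc_pipeline(single_pathway_low_extraction, healthy_subject, dose=10.0)
        ode = auc_pipeline(
            single_pathway_low_extraction, healthy_subject, dose=10.0, mode="mm"
        )
        assert ode.auc_inf == pytest.approx(lin.auc_inf, rel=0.01)
        assert ode.cmax == pytest.approx(lin.cmax, rel=0.01)

    def test_mass_balance(self, nifedipine, healthy_subject):
        prof = simulate(
            nifedipine, healthy_subject, DoseRegimen(60.0), t_end=96, mode="mm"
        )
        assert prof.meta["mass_balance_error"] < 1e-6

    def test_oral_auc_identity(self, single_pathway_low_extraction, healthy_subject):
        """Well-stirred + hepatic-only elimination: AUC = fa·fg·D/(fu·CLint_u).

        Independent closed-form identity (the (1-E) first-pass factor cancels
        the flow dependence of CL_h exactly for oral dosing).
        """
        c = single_pathway_low_extraction
        dose = 60.0
        res = auc_pipeline(c, healthy_subject, dose)
        clint = intrinsic_clearance(c, healthy_subject)
        expected = c.f_abs * c.f_gut * dose / (c.fu * clint) * 1000.0  # ng·h/mL
        assert res.auc_inf == pytest.approx(expected, rel=0.005)

    @pytest.mark.parametrize("r", [1.0, 10.0, 100.0])
    def test_one_plus_r_auc_law(
        self, single_pathway_low_extraction, healthy_subject, r
    ):
        """Oral AUC at inhibition R is (1+R)x the uninhibited AUC (within 2%)."""
        base = auc_pipeline(single_pathway_low_extraction, healthy_subject).auc_inf
        inhibited = auc_pipeline(
            apply_perturbation(single_pathway_low_extraction, r_map={"CYP3A4": r}),
            healthy_subject,
        ).auc_inf
        assert inhibited / base == pytest.approx(1 + r, rel=0.02)

    def test_inverse_fu_auc_law(self, single_pathway_low_extraction, healthy_subject):
        """fu 0.04 -> 1.0 drops oral AUC 25-fold (within 2%)."""
        lo = apply_perturbation(single_pathway_low_extraction, fu_target=0.04)
        hi = apply_perturbation(single_pathway_low_extraction, fu_target=1.0)
        ratio = (
            auc_pipeline(lo, healthy_subject).auc_inf
            / auc_pipeline(hi, healthy_subject).auc_inf
        )
        assert ratio == pytest.approx(25.0, rel=0.02)

    @pytest.mark.parametrize("fold", [2.0, 5.0])
    def test_expression_fold_auc_law(
        self, single_pathway_low_extraction, healthy_subject, fold
    ):
        """k-fold expression increase drops oral AUC k-fold (within 2%)."""
        base = auc_pipeline(single_pathway_low_extraction, healthy_subject).auc_inf
        up = auc_pipeline(
            apply_perturbation(
                single_pathway_low_extraction, expression_fold={"CYP3A4": fold}
            ),
            healthy_subject,
        ).auc_inf
        assert base / up == pytest.approx(fold, rel=0.02)

    def test_auc_monotone_in_each_factor(self, nifedipine, healthy_subject):
        """AUC falls with fu and expression, rises with R and falling GFR."""
        import dataclasses

        from renalpk.compounds import load_compound

        base = auc_pipeline(nifedipine, healthy_subject).auc_inf
        assert (
            auc_pipeline(
                apply_perturbation(nifedipine, fu_multiplier=1.5), healthy_subject
            ).auc_inf
            < base
        )
        assert (
            auc_pipeline(
                apply_perturbation(nifedipine, expression_fold={"CYP3A4": 2.0}),
                healthy_subject,
            ).auc_inf
            < base
        )
        assert (
            auc_pipeline(
                apply_perturbation(nifedipine, r_map={"CYP3A4": 1.0}), healthy_subject
            ).auc_inf
            > base
        )
        zdv = load_compound("zidovudine")  # renal_filtration_fraction > 0
        low_gfr = dataclasses.replace(healthy_subject, gfr=healthy_subject.gfr / 10)
        assert (
            auc_pipeline(zdv, low_gfr).auc_inf
            > auc_pipeline(zdv, healthy_subject).auc_inf
        )

    def test_solver_tolerance_refinement(self, nifedipine, healthy_subject):
        """Tightening rtol 10x changes the Michaelis-Menten AUC by < 0.1%."""
        kw = dict(t_end=96.0, n_points=501, mode="mm")
        a = simulate(nifedipine, healthy_subject, DoseRegimen(60.0), rtol=1e-6, **kw)
        b = simulate(nifedipine, healthy_subject, DoseRegimen(60.0), rtol=1e-7, **kw)
        auc_a = compute_nca(a).auc_inf
        auc_b = compute_nca(b).auc_inf
        assert abs(auc_a - auc_b) / auc_b < 1e-3

    def test_short_grid_warns_about_coverage(self, nifedipine, healthy_subject):
        slow = apply_perturbation(nifedipine, r_map={"CYP3A4": 100.0})
        with pytest.warns(UserWarning, match="half-lives"):
            simulate(slow, healthy_subject, DoseRegimen(60.0), t_end=24.0)
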