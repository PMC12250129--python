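import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from rltkit import biodist
from rltkit.dosimetry import (
    DoseReport,
    ExpFit,
    HumanTimeActivity,
    PhantomMasses,
    ResidenceTimeSet,
    SMatrix,
    build_smatrix,
    cumulated_activity,
    cumulated_activity_trapezoid,
    effective_dose,
    extrapolate_to_human,
    fit_time_activity,
    load_phantom,
    load_smatrix,
    load_tissue_weights,
    organ_doses,
    remainder_of_body,
)
from rltkit.errors import InputError
from rltkit.nuclide import decay_factor
from rltkit.synth import LNCAP_BIODIST, SimulationConfig, simulate_worksheets

MAX_TOTAL_TAU_H = 161.52 / math.log(2)  # every decay happens at most once


class TestExtrapolation:
    def test_mass_scaling_formula(self, nuc):
        # 10 %IA/g x 0.025 kg x (1800 g / 70 kg) = 6.4286 %IA at t=0
        table = pd.DataFrame(
            [{"organ": "liver", "time_h": 0.0, "mean_pia_g": 10.0, "sd": 0.0, "n": 1}]
        )
        phantom = PhantomMasses({"liver": 1800.0}, 70.0)
        curves, excluded = extrapolate_to_human(table, 0.025, phantom, nuc)
        assert excluded == []
        assert curves[0].pct_ia[0] == pytest.approx(6.4286, abs=2e-4)

    def test_decay_restored_on_extrapolated_curve(self, nuc):
        table = pd.DataFrame(
            [
                {"organ": "liver", "time_h": t, "mean_pia_g": 10.0, "sd": 0.0, "n": 1}
                for t in (0.0, 24.0)
            ]
        )
        phantom = PhantomMasses({"liver": 1800.0}, 70.0)
        curves, _ = extrapolate_to_human(table, 0.025, phantom, nuc)
        ratio = curves[0].pct_ia[1] / curves[0].pct_ia[0]
        assert ratio == pytest.approx(decay_factor(24.0, nuc))

    def test_identity_phantom_preserves_curve(self, nuc):
        """With organ g/kgTB = 1/animal_kg the scaling is a no-op at t=0."""
        animal_kg = 0.025
        phantom = PhantomMasses({"x": 70.0 / animal_kg}, 70.0)
        table = pd.DataFrame(
            [{"organ": "x", "time_h": 0.0, "mean_pia_g": 3.7, "sd": 0.0, "n": 1}]
        )
        curves, _ = extrapolate_to_human(table, animal_kg, phantom, nuc)
        assert curves[0].pct_ia[0] == pytest.approx(3.7, rel=1e-12)

    def test_unmatched_organ_excluded_not_fatal(self, nuc, zero_noise_table):
        curves, excluded = extrapolate_to_human(
            zero_noise_table, 0.025, load_phantom(), nuc
        )
        assert "tumor" in excluded
        assert {c.organ for c in curves} == {
            "blood", "kidney", "liver", "lung", "muscle", "spleen",
        }

    def test_zero_phantom_mass_rejected(self):
        with pytest.raises(InputError):
            PhantomMasses({"liver": 0.0}, 70.0)


class TestTimeActivityFit:
    def test_biexponential_recovery(self, nuc):
        t = np.array([1.0, 4.0, 24.0, 48.0])
        y = 60.0 * np.exp(-0.1 * t) + 40.0 * np.exp(-0.01 * t)
        fit = fit_time_activity(HumanTimeActivity("x", t, y), nuc, model="bi")
        assert fit.model == "bi"
        (c1, r1), (c2, r2) = fit.terms  # sorted fast-to-slow
        assert c1 == pytest.approx(60.0, rel=1e-4)
        assert r1 == pytest.approx(0.1, rel=1e-4)
        assert c2 == pytest.approx(40.0, rel=1e-4)
        assert r2 == pytest.approx(0.01, rel=1e-4)

    def test_pure_physical_decay_hits_rate_bound(self, nuc):
        t = np.array([0.0, 48.0])
        y = 100.0 * np.array([decay_factor(ti, nuc) for ti in t])
        fit = fit_time_activity(HumanTimeActivity("x", t, y), nuc, model="mono")
        assert fit.terms[0][1] == pytest.approx(nuc.lambda_phys, rel=1e-6)

    def test_all_zero_curve(self, nuc):
        t = np.array([1.0, 4.0, 24.0])
        fit = fit_time_activity(HumanTimeActivity("x", t, np.zeros(3)), nuc)
        assert fit.terms == [] and cumulated_activity(fit) == 0.0

    def test_rates_never_below_physical(self, nuc):
        # biologically impossible slow disappearance is clamped to lambda
        t = np.array([1.0, 10.0, 30.0, 48.0])
        y = 50.0 * np.exp(-1e-4 * t)
        fit = fit_time_activity(HumanTimeActivity("x", t, y), nuc, model="mono")
        assert fit.terms[0][1] >= nuc.lambda_phys - 1e-15

    def test_auto_prefers_mono_on_mono_data(self, nuc):
        t = np.array([1.0, 4.0, 12.0, 24.0, 36.0, 48.0])
        y = 30.0 * np.exp(-0.05 * t)
        fit = fit_time_activity(HumanTimeActivity("x", t, y), nuc, model="auto")
        assert fit.model == "mono"

    def test_too_few_points_rejected(self, nuc):
        c = HumanTimeActivity("x", np.array([1.0, 4.0]), np.array([1.0, 0.5]))
        with pytest.raises(InputError):
            fit_time_activity(c, nuc, model="bi")


class TestCumulatedActivity:
    def test_physical_decay_closed_form(self, nuc):
        # 100 %IA decaying only physically integrates to T1/2 / ln 2
        fit = ExpFit("x", [(100.0, nuc.lambda_phys)], "mono")
        assert cumulated_activity(fit) == pytest.approx(233.03, abs=0.01)

    def test_sum_of_term_ratios(self):
        fit = ExpFit("x", [(60.0, 0.1), (40.0, 0.01)], "bi")
        assert cumulated_activity(fit) == pytest.approx(46.0)

    def test_zero_terms(self):
        assert cumulated_activity(ExpFit("x", [], "zero")) == 0.0

    @given(
        c1=st.floats(0.1, 80.0),
        c2=st.floats(0.1, 20.0),
        r1=st.floats(0.005, 1.0),
        r2=st.floats(0.005, 1.0),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_matches_numeric_quadrature(self, c1, c2, r1, r2):
        """tau equals the numerically integrated fitted curve to <= 0.1%."""
        fit = ExpFit("x", [(c1, r1), (c2, r2)], "bi")
        numeric = quad(lambda t: fit(t) / 100.0, 0.0, np.inf, limit=200)[0]
        assert cumulated_activity(fit) == pytest.approx(numeric, rel=1e-3)

    def test_trapezoid_fallback_with_physical_tail(self, nuc):
        t = np.array([0.0, 10.0])
        y = np.array([100.0, 100.0])
        tau = cumulated_activity_trapezoid(HumanTimeActivity("x", t, y), nuc)
        assert tau == pytest.approx(10.0 + 1.0 / nuc.lambda_phys)


class TestRemainder:
    def test_simple_difference(self):
        taus = ResidenceTimeSet({"a": 60.0, "b": 40.0})
        full = remainder_of_body(taus, 150.0)
        assert full.taus_h["remainder"] == pytest.approx(50.0)

    def test_physical_whole_body(self):
        taus = ResidenceTimeSet({"a": 33.03})
        full = remainder_of_body(taus, 233.03)
        assert full.taus_h["remainder"] == pytest.approx(200.0)

    def test_overshoot_clamped_with_warning(self):
        taus = ResidenceTimeSet({"a": 100.0})
        with pytest.warns(UserWarning, match="clamped"):
            full = remainder_of_body(taus, 99.9)
        assert full.taus_h["remainder"] == 0.0


class TestDoseEngine:
    def test_identity_smatrix(self):
        s = SMatrix(pd.DataFrame(np.eye(2), index=["liver", "kidney"],
                                 columns=["liver", "kidney"]))
        report = organ_doses(ResidenceTimeSet({"liver": 2.0}), s)
        assert report.absorbed_mgy_per_mbq == {"liver": 2.0, "kidney": 0.0}

    def test_hand_computed_matrix_product(self):
        s = SMatrix(pd.DataFrame([[1.0, 0.1], [0.2, 2.0]],
                                 index=["a", "b"], columns=["a", "b"]))
        report = organ_doses(ResidenceTimeSet({"a": 3.0, "b": 4.0}), s)
        assert report.absorbed_mgy_per_mbq["a"] == pytest.approx(3.4)
        assert report.absorbed_mgy_per_mbq["b"] == pytest.approx(8.6)

    @given(
        tau_a=st.floats(0.0, 100.0),
        tau_b=st.floats(0.0, 100.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=30, derandomize=True)
    def test_linearity_in_residence_times(self, tau_a, tau_b, scale):
        s = SMatrix(pd.DataFrame([[0.5, 0.01], [0.02, 1.5]],
                                 index=["a", "b"], columns=["a", "b"]))
        d1 = organ_doses(ResidenceTimeSet({"a": tau_a, "b": tau_b}), s)
        d2 = organ_doses(
            ResidenceTimeSet({"a": scale * tau_a, "b": scale * tau_b}), s
        )
        for organ in ("a", "b"):
            assert d2.absorbed_mgy_per_mbq[organ] == pytest.approx(
                scale * d1.absorbed_mgy_per_mbq[organ], rel=1e-9, abs=1e-12
            )

    def test_missing_source_warned_and_excluded(self):
        s = SMatrix(pd.DataFrame([[1.0]], index=["a"], columns=["a"]))
        with pytest.warns(UserWarning, match="missing"):
            report = organ_doses(ResidenceTimeSet({"a": 1.0, "ghost": 5.0}), s)
        assert report.absorbed_mgy_per_mbq["a"] == 1.0


class TestEffectiveDose:
    def test_uniform_dose_identity(self):
        weights = load_tissue_weights()
        d = DoseReport({o: 0.42 for o in ("kidney", "liver", "lung", "spleen")})
        assert effective_dose(d, weights) == pytest.approx(0.42)

    def test_single_tissue_full_weight(self):
        d = DoseReport({"liver": 1.7})
        assert effective_dose(d, {"liver": 1.0, "REMAINDER": 0.0}) == pytest.approx(1.7)

    def test_remainder_is_mass_weighted_mean(self):
        d = DoseReport({"liver": 2.0, "kidney": 4.0})
        weights = {"lung": 0.5, "REMAINDER": 0.5}
        masses = {"liver": 3000.0, "kidney": 1000.0}
        h_rem = (2.0 * 3000 + 4.0 * 1000) / 4000  # 2.5
        # lung absent from the report, so it is assigned the remainder dose
        assert effective_dose(d, weights, masses) == pytest.approx(2.5)
        assert h_rem == 2.5

    def test_unnormalised_weights_rejected(self):
        with pytest.raises(InputError):
            effective_dose(DoseReport({"a": 1.0}), {"a": 0.9, "REMAINDER": 0.2})

    def test_effective_bounded_by_max_organ_dose(self):
        weights = load_tissue_weights()
        d = DoseReport({"kidney": 5.0, "liver": 1.0, "lung": 0.1})
        assert effective_dose(d, weights) <= 5.0


class TestSMatrixBuilder:
    def test_electron_self_dose_closed_form(self, nuc):
        s = build_smatrix({"spleen": 180.0}, nuc)
        # 0.5767 x 0.1335 MeV / 0.18 kg
        assert s.table.loc["spleen", "spleen"] == pytest.approx(0.42772, abs=1e-4)

    def test_photon_cross_term(self, nuc):
        s = build_smatrix(
            {"a": 1000.0, "b": 1000.0}, nuc, photon_fractions={("a", "b"): 0.5}
        )
        expected = 0.5767 * nuc.photon_energy_mev * 0.5 / 1.0
        assert s.table.loc["a", "b"] == pytest.approx(expected)
        assert s.table.loc["b", "a"] == 0.0

    def test_packaged_toy_matrix_loads(self):
        s = load_smatrix()
        assert s.table.loc["kidney", "kidney"] > 0
        assert (s.table.to_numpy() >= 0).all()


class TestEndToEnd:
    def test_residence_times_recover_preset_integrals(self, nuc, zero_noise_table):
        """Full chain: worksheets -> %IA/g -> human curves -> fits -> tau
        agrees with direct quadrature of the preset forward model to <= 1%."""
        phantom = load_phantom()
        curves, _ = extrapolate_to_human(zero_noise_table, 0.025, phantom, nuc)
        for curve in curves:
            fit = fit_time_activity(curve, nuc, model="auto")
            tau = cumulated_activity(fit)
            g_per_kg = phantom.organ_g[curve.organ] / phantom.total_body_kg

            def truth(t):
                return (
                    LNCAP_BIODIST.pia_g(curve.organ, t)
                    / 100.0
                    * 0.025
                    * g_per_kg
                    * decay_factor(t, nuc)
                )

            oracle = quad(truth, 0.0, 2000.0, limit=400,
                          points=[1.0, 4.0, 24.0, 48.0])[0]
            assert tau == pytest.approx(oracle, rel=0.01), curve.organ

    def test_total_disintegration_bound(self, nuc, zero_noise_table):
        """Residence times over all regions, remainder included, cannot
        exceed one disintegration per decay: sum tau <= T1/2 / ln 2."""
        phantom = load_phantom()
        curves, _ = extrapolate_to_human(zero_noise_table, 0.025, phantom, nuc)
        taus = {
            c.organ: cumulated_activity(fit_time_activity(c, nuc)) for c in curves
        }
        full = remainder_of_body(
            ResidenceTimeSet(taus), 1.0 / nuc.lambda_phys
        )
        assert full.total() <= MAX_TOTAL_TAU_H + 1e-9
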