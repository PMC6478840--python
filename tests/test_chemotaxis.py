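import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmaze.chemotaxis import (ChemotaxisParameters, Phenotype,
                              accumulation_length, chemotactic_sensitivity,
                              chemotactic_velocity, diffusivity,
                              receptor_response, swim_speed)
from tmaze.errors import (DomainError, SingularPhenotypeError,
                          UndefinedAccumulationError)

P = ChemotaxisParameters()


class TestReceptorResponse:
    def test_zero_gradient_gives_zero(self):
        assert receptor_response(140.0, 0.0, P) == 0.0

    def test_reference_value(self):
        # (K_A-K_I)*gradC/((K_A+C)(K_I+C)) at C=140 µM, gradC=0.1407 µM/µm
        got = receptor_response(140.0, 0.1407, P)
        expected = (2900 - 18) * 0.1407 / ((2900 + 140) * (18 + 140))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(8.44e-4, rel=1e-2)

    def test_log_sensing_window_limit(self):
        # for K_I << C << K_A the response approaches (1 - K_I/K_A)*gradC/C;
        # the relative error is (1+C/K_A)(1+K_I/C) - 1, minimized near the
        # geometric mean sqrt(K_I*K_A) ~ 228 µM where it is ~16%
        C, gradC = 230.0, 0.1
        approx = (1 - P.K_I / P.K_A) * gradC / C
        bound = C / P.K_A + P.K_I / C + 0.02
        assert receptor_response(C, gradC, P) == \
            pytest.approx(approx, rel=bound)

    def test_log_window_shape_after_rescaling(self):
        # rescaled to agree at the window center, the 1/C form tracks the
        # full response within 10% across [5 K_I, K_A/5]
        C0 = np.sqrt(P.K_I * P.K_A)
        scale = receptor_response(C0, 1.0, P) * C0
        for C in np.linspace(5 * P.K_I, P.K_A / 5, 20):
            assert receptor_response(C, 1.0, P) == \
                pytest.approx(scale / C, rel=0.10)

    def test_vanishes_at_saturation(self):
        assert receptor_response(1e9, 1.0, P) < 1e-12

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            receptor_response(-1.0, 0.1, P)


class TestMotilityMaps:
    def test_sensitivity_reference_value(self):
        ph = Phenotype(g=76.0, T_B=0.22)
        # ½ v² (1-a0) g τ_t / T_B with v = 20 µm/s
        assert chemotactic_sensitivity(ph, P, v=20.0) == \
            pytest.approx(0.5 * 400 * (2 / 3) * 76 * 0.2 / 0.22, rel=1e-12)
        assert chemotactic_sensitivity(ph, P, v=20.0) == \
            pytest.approx(9.2e3, rel=0.01)

    def test_sensitivity_linear_in_gain(self):
        a = chemotactic_sensitivity(Phenotype(g=40.0, T_B=0.3), P)
        b = chemotactic_sensitivity(Phenotype(g=80.0, T_B=0.3), P)
        assert b == pytest.approx(2 * a)

    def test_sensitivity_vanishes_at_saturated_activity(self):
        p_sat = ChemotaxisParameters(a_0=1 - 1e-9)
        assert chemotactic_sensitivity(Phenotype(g=76, T_B=0.22), p_sat) \
            == pytest.approx(0.0, abs=1e-3)

    def test_swim_speed(self):
        assert swim_speed(Phenotype(g=76, T_B=0.22), P) == pytest.approx(19.5)
        assert swim_speed(Phenotype(g=76, T_B=1e-9), P) == pytest.approx(25.0)
        assert swim_speed(Phenotype(g=76, T_B=1 - 1e-9), P) == \
            pytest.approx(0.0, abs=1e-6)

    def test_diffusivity_reference_value(self):
        ph = Phenotype(g=76, T_B=0.2)
        # v² τ_t / [3 T_B (1-<cosθ>)] with v = 20
        assert diffusivity(ph, P, v=20.0) == pytest.approx(200.0)

    def test_diffusivity_quadratic_in_speed(self):
        ph = Phenotype(g=76, T_B=0.2)
        assert diffusivity(ph, P, v=10.0) == \
            pytest.approx(diffusivity(ph, P, v=20.0) / 4)

    def test_singular_phenotype_rejected(self):
        with pytest.raises(SingularPhenotypeError):
            Phenotype(g=76.0, T_B=0.0)
        with pytest.raises(SingularPhenotypeError):
            Phenotype(g=76.0, T_B=0.3, N=10.0, H=5.0)  # g != N*H


class TestChemotacticVelocity:
    def test_linear_regime_reference(self):
        vc = chemotactic_velocity(None, 1.407e-3, "linear", P)
        assert vc == pytest.approx(0.90, rel=0.01)
        assert 0.8 <= vc <= 2.5  # expected range for E. coli in this device

    def test_zero_gradient_in_every_regime(self):
        ph = Phenotype(g=76, T_B=0.22)
        for regime in ("linear", "log", "full"):
            assert chemotactic_velocity(140.0, 0.0, regime, P,
                                        phenotype=ph) == 0.0

    def test_full_matches_log_form_with_matched_chi(self):
        # with chi_L matched at the log-window center, the 1/C form tracks
        # the full response within 10% through the window, including the
        # inlet concentration of the high-attractant regime
        ph = Phenotype(g=76, T_B=0.22)
        gradC = 0.1407
        C0 = np.sqrt(P.K_I * P.K_A)
        chi_log_matched = (chemotactic_velocity(C0, gradC, "full", P,
                                                phenotype=ph) * C0 / gradC)
        for C in (140.0, C0, 400.0):
            full = chemotactic_velocity(C, gradC, "full", P, phenotype=ph)
            log = chemotactic_velocity(C, gradC, "log", P,
                                       chi=chi_log_matched)
            assert full == pytest.approx(log, rel=0.10)

    def test_log_regime_domain_error_at_zero_concentration(self):
        with pytest.raises(DomainError):
            chemotactic_velocity(0.0, 0.1, "log", P)


class TestAccumulationLength:
    def test_reference_value(self):
        assert accumulation_length(0.9, 330.0) == pytest.approx(366.7, rel=1e-3)

    def test_undefined_for_nonpositive_drift(self):
        with pytest.raises(UndefinedAccumulationError):
            accumulation_length(0.0, 330.0)

    @settings(max_examples=40, deadline=None)
    @given(v_r=st.floats(min_value=5.0, max_value=60.0),
           g=st.floats(min_value=5.0, max_value=300.0),
           T_B=st.floats(min_value=0.05, max_value=0.8))
    def test_speed_cancellation(self, v_r, g, T_B):
        """The accumulation slope chi0/D is independent of run speed: both
        the sensitivity and the diffusivity scale as v^2."""
        ph = Phenotype(g=g, T_B=T_B)
        ratios = []
        for vr in (v_r, 2 * v_r):
            p = ChemotaxisParameters(v_run=vr)
            ratios.append(chemotactic_sensitivity(ph, p) / diffusivity(ph, p))
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(g=st.floats(min_value=1.0, max_value=500.0),
           T_B=st.floats(min_value=0.01, max_value=0.99))
    def test_all_outputs_positive_and_finite(self, g, T_B):
        ph = Phenotype(g=g, T_B=T_B)
        for val in (chemotactic_sensitivity(ph, P), swim_speed(ph, P),
                    diffusivity(ph, P)):
            assert np.isfinite(val) and val > 0
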