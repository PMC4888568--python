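"""Stimulation protocols, feedback perturbations, dose-response."""

import numpy as np
import pytest

from ruleisp.experiments import (
    Perturbation,
    Protocol,
    ProtocolError,
    apply_perturbation,
    glut4_dose_response,
    normalize_for_comparison,
    run_insulin_protocol,
    zero_feedback_rates,
)
from ruleisp.network import generate_network


def _max_rel_diff(a, b):
    return np.max(np.abs(a - b)) / max(np.max(np.abs(a)), 1e-12)


class TestProtocol:
    def test_zero_dose_leaves_all_observables_at_baseline(self, isp_model):
        res = run_insulin_protocol(isp_model, Protocol(insulin_nM=0.0))
        for name in isp_model.observables:
            y = res.observable_by_name(name)
            assert np.max(np.abs(y - y[0])) <= 1e-3 * max(abs(y[0]), 1.0), name

    def test_standard_run_covers_the_grid_with_all_species(self, isp_result):
        assert isp_result.times[0] == 0.0
        assert isp_result.times[-1] == pytest.approx(60.0)
        assert isp_result.trajectories.shape == (61, len(isp_result.times))

    def test_negative_dose_is_a_validation_error(self):
        with pytest.raises(ProtocolError):
            Protocol(insulin_nM=-5.0)

    def test_pre_equilibration_matches_direct_start(self, isp_model):
        """The listed initial conditions are the resting state, so the
        optional pre-equilibration flag changes nothing material."""
        direct = run_insulin_protocol(isp_model, Protocol(insulin_nM=100.0, t_end=10.0))
        pre = run_insulin_protocol(
            isp_model, Protocol(insulin_nM=100.0, t_end=10.0), pre_equilibrate=True
        )
        assert _max_rel_diff(
            direct.observable_by_name("pAKT_S473"), pre.observable_by_name("pAKT_S473")
        ) < 1e-3


class TestPerturbations:
    def test_identity_scaling_reproduces_the_complete_model(self, isp_model, isp_result):
        scaled = apply_perturbation(isp_model, Perturbation("scale_parameter", "k15", 1.0))
        res = run_insulin_protocol(scaled, Protocol(insulin_nM=100.0))
        for name in ("GLUT4_mem", "ppERK"):
            assert _max_rel_diff(
                res.observable_by_name(name), isp_result.observable_by_name(name)
            ) < 1e-9

    def test_original_model_is_untouched(self, isp_model):
        n_rules = len(isp_model.rules)
        k15 = isp_model.parameters["k15"]
        apply_perturbation(isp_model, Perturbation("remove_rule_set", "p70S6K-IRS1"))
        apply_perturbation(isp_model, Perturbation("scale_parameter", "k15", 2.0))
        assert len(isp_model.rules) == n_rules
        assert isp_model.parameters["k15"] == k15

    def test_unknown_targets_list_valid_choices(self, isp_model):
        with pytest.raises(ProtocolError) as exc:
            apply_perturbation(isp_model, Perturbation("remove_rule_set", "nope"))
        assert "p70S6K-IRS1" in str(exc.value)
        with pytest.raises(ProtocolError):
            apply_perturbation(isp_model, Perturbation("scale_parameter", "nope", 2.0))

    def test_remove_then_restore_is_identity_on_the_network(self, isp_model):
        removed = apply_perturbation(
            isp_model, Perturbation("remove_rule_set", "ERK1/2-GRB2/SOS")
        )
        restored = removed.copy()
        by_name = {r.name: r for r in isp_model.rules}
        restored.rules = [by_name[r.name] for r in isp_model.rules]
        n0, n1 = generate_network(isp_model), generate_network(restored)
        assert n0.labels == n1.labels
        assert n0.content_hash() == n1.content_hash()

    def test_rule_removal_equals_zeroed_rates(self, isp_model):
        """Deleting a feedback's rules and zeroing their rate constants must
        give identical trajectories."""
        removed = apply_perturbation(
            isp_model, Perturbation("remove_rule_set", "p70S6K-IRS1")
        )
        zeroed = zero_feedback_rates(isp_model, "p70S6K-IRS1")
        r1 = run_insulin_protocol(removed, Protocol(insulin_nM=100.0, t_end=30.0))
        r2 = run_insulin_protocol(zeroed, Protocol(insulin_nM=100.0, t_end=30.0))
        for name in ("GLUT4_mem", "ppERK", "pIRS1_Ser"):
            assert _max_rel_diff(
                r1.observable_by_name(name), r2.observable_by_name(name)
            ) < 1e-7, name


class TestFeedbackStructure:
    def test_erk_feedback_removal_leaves_glut4_superimposable(
        self, isp_result, isp_result_wo_erk_feedback
    ):
        """The ERK1/2->GRB2/SOS loop acts downstream of everything the
        GLUT4 branch reads: its removal must leave the GLUT4-membrane
        trajectory identical within solver tolerance while clearly
        changing doubly phosphorylated ERK."""
        glut4_full = isp_result.observable_by_name("GLUT4_mem")
        glut4_wo = isp_result_wo_erk_feedback.observable_by_name("GLUT4_mem")
        assert _max_rel_diff(glut4_full, glut4_wo) < 1e-6
        pperk_full = isp_result.observable_by_name("ppERK")
        pperk_wo = isp_result_wo_erk_feedback.observable_by_name("ppERK")
        assert _max_rel_diff(pperk_full, pperk_wo) > 0.05

    def test_p70_feedback_removal_changes_both_endpoints(
        self, isp_result, isp_result_wo_p70_feedback
    ):
        for name in ("GLUT4_mem", "ppERK"):
            assert _max_rel_diff(
                isp_result.observable_by_name(name),
                isp_result_wo_p70_feedback.observable_by_name(name),
            ) > 1e-3, name


class TestDoseResponse:
    DOSES = (0.1, 1.0, 10.0, 100.0)

    def test_complete_model_response_is_nondecreasing_in_dose(self, isp_model):
        dr = glut4_dose_response(isp_model, (0.0,) + self.DOSES)
        values = [dr[d] for d in sorted(dr)]
        assert all(b >= a - 1e-6 for a, b in zip(values, values[1:]))

    def test_enhanced_p70_feedback_lowers_glut4_at_every_dose(self, isp_model):
        """Doubling k15 (a 100 % stronger p70S6K-IRS1 feedback) must reduce
        insulin-stimulated glucose-transporter translocation at every dose."""
        enhanced = apply_perturbation(
            isp_model, Perturbation("scale_parameter", "k15", 2.0)
        )
        dr_full = glut4_dose_response(isp_model, self.DOSES)
        dr_enh = glut4_dose_response(enhanced, self.DOSES)
        for d in self.DOSES:
            assert dr_enh[d] < dr_full[d], d

    def test_feedback_removal_raises_glut4_at_every_dose(self, isp_model):
        removed = apply_perturbation(
            isp_model, Perturbation("remove_rule_set", "p70S6K-IRS1")
        )
        dr_full = glut4_dose_response(isp_model, self.DOSES)
        dr_wo = glut4_dose_response(removed, self.DOSES)
        for d in self.DOSES:
            assert dr_wo[d] > dr_full[d], d

    def test_zero_dose_returns_baseline_value(self, isp_model):
        dr = glut4_dose_response(isp_model, (0.0,))
        assert dr[0.0] == pytest.approx(4000.0, rel=1e-3)

    def test_empty_dose_list_is_an_error(self, isp_model):
        with pytest.raises(ProtocolError):
            glut4_dose_response(isp_model, ())


class TestNormalization:
    def test_linear_example(self):
        assert np.allclose(
            normalize_for_comparison(np.array([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0]
        )

    def test_constant_trace_maps_to_zeros(self):
        assert np.allclose(normalize_for_comparison(np.full(5, 3.7)), 0.0)

    def test_output_always_within_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = normalize_for_comparison(rng.normal(size=50) * rng.uniform(0.1, 100))
            assert y.min() >= 0.0 and y.max() <= 1.0
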