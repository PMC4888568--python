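"""Local parametric sensitivity: analytic limits, robustness, report rules."""

import math

import numpy as np
import pytest
import scipy.integrate as si

from ruleisp.experiments import Perturbation, apply_perturbation
from ruleisp.fixtures import generate_fixture
from ruleisp.sensitivity import (
    SensitivitySpec,
    local_sensitivity_timecourse,
    overall_sensitivity,
    sensitivity_report,
)


def _linear_overall_sensitivity_wrt_k(t0, t1, k=10.0, d=0.5, y0=2.0):
    """Closed form for y' = k - d*y: s_k(t) = (1-e^{-dt})(k/d)/y(t)."""

    def s(t):
        y = k / d + (y0 - k / d) * math.exp(-d * t)
        return (1 - math.exp(-d * t)) * (k / d) / y

    val, _ = si.quad(s, t0, t1, limit=200)
    return 100.0 * val / (t1 - t0)


class TestAnalyticLimits:
    def test_linear_fixture_matches_closed_form_to_4_significant_digits(self):
        f = generate_fixture("linear")
        t, s = local_sensitivity_timecourse(
            f.model, "Y_total", "k", window=(0, 60), grid_dt=0.1, initial=[2.0]
        )
        S = overall_sensitivity(s, t)
        ref = _linear_overall_sensitivity_wrt_k(0, 60)
        assert abs(S - ref) / abs(ref) < 5e-4  # 4 significant digits

    def test_steady_state_sensitivity_wrt_production_is_100_percent(self):
        """At steady state y = k/d, so a relative change in k transfers
        one-to-one: s = +1."""
        f = generate_fixture("linear")
        t, s = local_sensitivity_timecourse(
            f.model, "Y_total", "k", window=(0, 60), grid_dt=0.5, initial=[2.0]
        )
        assert s[-1] == pytest.approx(1.0, abs=1e-6)

    def test_forward_and_central_differences_agree_on_nonlinear_fixture(self):
        """At delta = 0.1 % the one-sided scheme must agree with the central
        scheme within 1 % relative on a Hill-nonlinear model."""
        f = generate_fixture("hill_feedback")
        vals = {}
        for scheme in ("forward", "central"):
            t, s = local_sensitivity_timecourse(
                f.model, "A_on", "vmax", window=(0, 30), grid_dt=0.1,
                scheme=scheme, initial=[900.0, 100.0],
            )
            vals[scheme] = overall_sensitivity(s, t)
        assert abs(vals["forward"] - vals["central"]) / abs(vals["central"]) < 0.01


class TestOverallSensitivity:
    def test_constant_trace_averages_to_itself(self):
        t = np.linspace(0, 60, 301)
        assert overall_sensitivity(np.full_like(t, 0.42), t) == pytest.approx(42.0)

    def test_linear_ramp_on_unit_window_averages_to_half(self):
        t = np.linspace(0, 1, 1001)
        assert overall_sensitivity(t.copy(), t) == pytest.approx(50.0, rel=1e-5)

    def test_empty_window_is_an_error(self):
        with pytest.raises(ValueError):
            overall_sensitivity(np.array([1.0]), np.array([0.0]))

    def test_masked_points_are_excluded_not_dropped_silently(self):
        t = np.linspace(0, 10, 101)
        s = np.ma.masked_where(t < 5, np.ones_like(t))
        assert overall_sensitivity(s, t) == pytest.approx(100.0)


class TestIspSensitivity:
    def test_parameter_with_no_path_to_output_has_zero_sensitivity(self, isp_model):
        """kcat39 acts only on the GRB2/SOS catalytic arm, which the GLUT4
        branch never reads."""
        t, s = local_sensitivity_timecourse(
            isp_model, "GLUT4_mem", "kcat39", grid_dt=1.0
        )
        assert abs(overall_sensitivity(s, t)) < 1e-2

    def test_sign_consistency_first_order_check(self, isp_model):
        """Increasing a parameter with S>0 by 1 % must increase the
        time-averaged output (and vice versa for S<0)."""
        from ruleisp.experiments import Protocol, run_insulin_protocol

        for pname in ("k13p", "k_13"):
            t, s = local_sensitivity_timecourse(isp_model, "GLUT4_mem", pname, grid_dt=0.5)
            S = overall_sensitivity(s, t)
            bumped = apply_perturbation(
                isp_model, Perturbation("scale_parameter", pname, 1.01)
            )
            base = run_insulin_protocol(isp_model, Protocol(grid_dt=0.5))
            up = run_insulin_protocol(bumped, Protocol(grid_dt=0.5))
            delta = np.trapezoid(
                up.observable_by_name("GLUT4_mem") - base.observable_by_name("GLUT4_mem"),
                base.times,
            )
            assert math.copysign(1, delta) == math.copysign(1, S), pname

    def test_halving_delta_changes_coefficients_by_less_than_2_percent(self, isp_model):
        for pname in ("k13p", "k_7", "kcat33"):
            out = "GLUT4_mem" if "13" in pname else "ppERK"
            vals = []
            for delta in (1e-3, 5e-4):
                t, s = local_sensitivity_timecourse(
                    isp_model, out, pname, delta=delta, grid_dt=0.5
                )
                vals.append(overall_sensitivity(s, t))
            assert abs(vals[0] - vals[1]) / max(abs(vals[1]), 1e-9) < 0.02, pname


@pytest.fixture(scope="module")
def small_report(isp_model):
    variants = {
        "complete": isp_model,
        "wo_p70S6K": apply_perturbation(
            isp_model, Perturbation("remove_rule_set", "p70S6K-IRS1")
        ),
        "wo_ERK": apply_perturbation(
            isp_model, Perturbation("remove_rule_set", "ERK1/2-GRB2/SOS")
        ),
    }
    spec = SensitivitySpec(
        parameters=("k13p", "k_13", "k15", "Kd_p70", "kcat33", "kcat39", "k_2"),
        grid_dt=0.5,
    )
    return sensitivity_report(variants, spec)


class TestReport:

    def test_rows_ranked_by_absolute_value_in_complete_model(self, small_report):
        for out in ("GLUT4_mem", "ppERK"):
            df = small_report.table(out)
            ranks = df["complete"].abs().fillna(-1.0).to_numpy()
            assert all(a >= b - 1e-12 for a, b in zip(ranks, ranks[1:]))

    def test_subthreshold_rows_excluded(self, small_report):
        # k_2 (second insulin binding) is far below 0.1 % for GLUT4
        assert "k_2" not in set(small_report.table("GLUT4_mem")["parameter"])

    def test_removed_parameters_show_null_marker(self, small_report):
        df = small_report.table("ppERK").set_index("parameter")
        assert np.isnan(df.loc["k15", "wo_p70S6K"])
        assert np.isnan(df.loc["kcat39", "wo_ERK"])

    def test_erk_feedback_column_identical_for_glut4(self, small_report):
        """Removing the ERK1/2-GRB2/SOS feedback cannot change any GLUT4
        sensitivity coefficient."""
        df = small_report.table("GLUT4_mem")
        both = df[["complete", "wo_ERK"]].dropna()
        assert np.allclose(both["complete"], both["wo_ERK"], rtol=1e-3, atol=1e-3)

    def test_process_annotations_present(self, small_report):
        df = small_report.table("GLUT4_mem")
        assert (df["process"] != "").all()
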