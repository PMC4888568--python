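import pytest

from ruleisp.experiments import Perturbation, Protocol, apply_perturbation, run_insulin_protocol
from ruleisp.isp import build_isp_model
from ruleisp.network import generate_network


@pytest.fixture(scope="session")
def isp_model():
    return build_isp_model(insulin_nM=100.0)


@pytest.fixture(scope="session")
def isp_network(isp_model):
    return generate_network(isp_model)


@pytest.fixture(scope="session")
def isp_result(isp_model):
    """Standard 60 min, 100 nM insulin stimulation of the complete model."""
    return run_insulin_protocol(isp_model, Protocol(insulin_nM=100.0))


@pytest.fixture(scope="session")
def isp_result_wo_erk_feedback(isp_model):
    m = apply_perturbation(isp_model, Perturbation("remove_rule_set", "ERK1/2-GRB2/SOS"))
    return run_insulin_protocol(m, Protocol(insulin_nM=100.0))


@pytest.fixture(scope="session")
def isp_result_wo_p70_feedback(isp_model):
    m = apply_perturbation(isp_model, Perturbation("remove_rule_set", "p70S6K-IRS1"))
    return run_insulin_protocol(m, Protocol(insulin_nM=100.0))
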