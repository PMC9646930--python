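import numpy as np
import pytest

from clpnet.centrality import (COGNITION_CLUSTER, SYMPTOM_CLUSTER,
                               ClusterAssignment)
from clpnet.data_model import VariableSpec, default_schema
from clpnet.ggm import ContemporaneousNetwork
from clpnet.synthetic import make_truth, simulate_panel


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def clusters(schema):
    return ClusterAssignment.from_roles(schema)


@pytest.fixture(scope="session")
def complete_panel(schema):
    """Moderately sized complete simulated panel shared by read-only tests."""
    truth = make_truth(seed=101, density=0.2, effect_range=(0.15, 0.35),
                       missing_rate=0.0)
    return simulate_panel(truth, 1500, schema, seed=101)


@pytest.fixture(scope="session")
def wide_schema():
    """Continuous schema whose affine map is effectively linear (no clipping,
    no ordinal rounding), for tests of the latent structure itself."""
    roles = ["symptom"] * 5 + ["cognition"] * 4 + ["covariate"] * 4
    return tuple(VariableSpec(f"x{i}", r, -100, 100) for i, r in enumerate(roles))


def toy_network(a_c=0.3, b_c=-0.2, a_b=0.5):
    """3-node fixture: clusters {A, B} vs {C}; edges A-C, B-C, A-B."""
    pcor = np.array([[0.0, a_b, a_c],
                     [a_b, 0.0, b_c],
                     [a_c, b_c, 0.0]])
    net = ContemporaneousNetwork(
        pcor=pcor, node_labels=("A", "B", "C"), lambda_selected=0.1,
        lambda_path=np.array([0.2, 0.1]), ebic_path=np.array([1.0, 0.5]),
        edge_counts=np.array([0, 3]), n_used=100, wave_label="w1", gamma=0.5)
    assignment = ClusterAssignment({"A": SYMPTOM_CLUSTER, "B": SYMPTOM_CLUSTER,
                                    "C": COGNITION_CLUSTER})
    return net, assignment


@pytest.fixture
def toy_bridge_fixture():
    return toy_network()
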