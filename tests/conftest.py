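import numpy as np
import pytest

from lapdyn.cohort import CohortConfig, SimulationParams, generate_cohort
from lapdyn.domain import (assemble_fem, build_graph_domain, compute_basis,
                           synthetic_connectome, unit_square_mesh)


@pytest.fixture(scope="session")
def two_node():
    dom = build_graph_domain(np.array([[0.0, 1.0], [1.0, 0.0]]))
    return dom, compute_basis(dom, 2)


@pytest.fixture(scope="session")
def graph10():
    rng = np.random.default_rng(3)
    W = rng.uniform(0.0, 1.0, (10, 10))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    dom = build_graph_domain(W)
    return dom, compute_basis(dom, 10)


@pytest.fixture(scope="session")
def square_fem():
    fem = assemble_fem(unit_square_mesh(10))
    return fem, compute_basis(fem, 12)


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free 6-patient cohort on a small connectome (shared by several
    training tests)."""
    dom = synthetic_connectome(16, seed=4)
    basis = compute_basis(dom, 10)
    cfg = CohortConfig(n_patients=6, seed=11, visit_counts=4,
                       noise_sigma=0.0, jitter_sigma=0.0,
                       progression_sigma=0.0)
    return dom, basis, generate_cohort(cfg, dom, basis=basis)
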