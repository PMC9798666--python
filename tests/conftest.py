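import numpy as np
import pytest

from dtimf import (SolverConfig, SyntheticSpec, build_graph_operators,
                   generate_synthetic)

# the seeded planted instance used by the solver-level checks
SOLVER_SPEC = SyntheticSpec(n_drugs=40, n_targets=30, k_true=4,
                            density=0.08, noise_sd=0.05, seed=7)
# the larger instance used by the cross-validation checks
CV_SPEC = SyntheticSpec(n_drugs=60, n_targets=40, k_true=4,
                        density=0.08, noise_sd=0.05, seed=0)


@pytest.fixture(scope="session")
def solver_instance():
    """Planted 40x30 instance plus graph operators (p=5)."""
    interactions, drug_sim, target_sim, truth = generate_synthetic(SOLVER_SPEC)
    gd = build_graph_operators(drug_sim.S, 5)
    gt = build_graph_operators(target_sim.S, 5)
    return interactions, drug_sim, target_sim, truth, gd, gt


@pytest.fixture(scope="session")
def cv_dataset():
    """Planted 60x40 triple for cross-validation runs."""
    interactions, drug_sim, target_sim, _ = generate_synthetic(CV_SPEC)
    return interactions, drug_sim, target_sim


@pytest.fixture(scope="session")
def masked_instance(solver_instance):
    """The 40x30 instance with 10% of positives held out of training."""
    interactions = solver_instance[0]
    rng = np.random.default_rng(11)
    pos = np.argwhere(interactions.Z == 1)
    held = pos[rng.choice(len(pos), size=round(0.1 * len(pos)),
                          replace=False)]
    Z_train = interactions.Z.copy()
    Z_train[held[:, 0], held[:, 1]] = 0.0
    return Z_train, held


@pytest.fixture()
def small_rng():
    return np.random.default_rng(42)


def random_block_state(rng, n=6, m=5, k=2):
    """A random solver state + config + Laplacians for gradient checks."""
    from dtimf.solver import SolverState

    def lap(d):
        W = rng.uniform(size=(d, d))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        from dtimf import normalized_laplacian
        return normalized_laplacian(W)[2]

    state = SolverState(
        X=rng.normal(size=(n, k)), Y=rng.normal(size=(m, k)),
        M=rng.normal(size=(n, m)), U=rng.uniform(size=(n, k)),
        V=rng.uniform(size=(k, m)), Lambda=rng.normal(size=(n, k)),
        Pi=rng.normal(size=(k, m)))
    config = SolverConfig(k=k, lambda_d=0.05, lambda_t=0.07,
                          alpha=0.5, beta=0.3)
    return state, config, lap(n), lap(m)
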