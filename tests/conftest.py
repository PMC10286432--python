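import numpy as np
import pandas as pd
import pytest

import splitcar as sc


@pytest.fixture(scope="session")
def path3():
    """Path graph 1-2-3 (one connected component)."""
    return sc.AdjacencyGraph.from_edges(["a", "b", "c"], [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def two_chains():
    """Disconnected graph: chain {0,1} and chain {2,3,4}."""
    return sc.AdjacencyGraph.from_edges(list("abcde"), [(0, 1), (2, 3), (3, 4)])


@pytest.fixture(scope="session")
def small_bundle():
    """A small two-region synthetic dataset shared across tests."""
    return sc.scenario("common_baseline", lattice=(4, 3, 3, 3))


@pytest.fixture(scope="session")
def small_summaries(small_bundle):
    return small_bundle.summaries()


def random_two_region_problem(rng, max_areas=20):
    """Random disconnected map with Gaussian pseudo-summaries, n <= max_areas."""
    while True:
        dims = rng.integers(2, 4, size=4)
        if 2 * (dims[0] * dims[1] + dims[2] * dims[3]) <= 2 * max_areas:
            break
    g, _ = sc.make_lattice_regions(*dims)
    n = g.n_areas
    y = rng.normal(-1.0, 0.6, n)
    var = rng.uniform(0.05, 0.6, n)
    unobs = rng.random(n) < 0.15
    summ = pd.DataFrame(
        {
            "n": 10,
            "p_hat": 0.5,
            "var_p": 0.01,
            "y_logit": np.where(unobs, np.nan, y),
            "var_logit": np.where(unobs, np.nan, var),
            "status": np.where(unobs, "unsampled", "observed"),
        },
        index=list(g.area_ids),
    )
    return g, summ


def dense_constrained_moments(Q, b, A):
    """Brute-force oracle: dense conditioning of N(Q^-1 b, Q^-1) on Ax = 0."""
    Q = np.asarray(Q.todense() if hasattr(Q, "todense") else Q, dtype=float)
    A = np.atleast_2d(A)
    if A.shape[0]:
        c = max(1.0, np.mean(np.abs(np.diag(Q))))
        Q = Q + c * A.T @ A
    Sigma = np.linalg.inv(Q)
    mu = Sigma @ b
    if A.shape[0] == 0:
        return mu, Sigma
    SA = Sigma @ A.T
    S = A @ SA
    mu_c = mu - SA @ np.linalg.solve(S, A @ mu)
    Sigma_c = Sigma - SA @ np.linalg.solve(S, SA.T)
    return mu_c, Sigma_c
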