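"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately re-derive quantities by brute force
(path enumeration, numeric integration, dense multivariate normals) so
they stay independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate

import waxphylo as wp


@pytest.fixture
def three_tip_tree() -> wp.Phylogeny:
    return wp.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def default_dataset() -> wp.SyntheticDataset:
    """One default synthetic study reused by read-only tests."""
    return wp.simulate_study(wp.SyntheticConfig(seed=0))


def random_tree(rng: np.random.Generator, n_tips: int,
                ultrametric: bool = False) -> wp.Phylogeny:
    """Random tree: Yule topology with (optionally) jittered branch lengths."""
    base = wp.simulate_tree(n_tips, seed=int(rng.integers(2**31)))
    if ultrametric:
        return base
    blen = base.blen * rng.uniform(0.3, 1.7, size=base.n_nodes)
    blen[0] = 0.0
    return wp.Phylogeny(base.parent, blen, base.labels)


# ---------------------------------------------------------------------------
# Brute-force oracles


def root_path_edges(tree: wp.Phylogeny, node: int) -> list[int]:
    path = []
    v = node
    while v != 0:
        path.append(v)
        v = tree.parent[v]
    return path[::-1]


def shared_path_vcv(tree: wp.Phylogeny) -> np.ndarray:
    """BM covariance by explicit root-path edge intersection."""
    n = tree.n_tips
    C = np.zeros((n, n))
    paths = [root_path_edges(tree, t) for t in tree.tips]
    for i in range(n):
        for j in range(n):
            shared = set(paths[i]) & set(paths[j])
            C[i, j] = sum(tree.blen[v] for v in shared)
    return C


def ou_mean_weights_quad(tree: wp.Phylogeny, painting: wp.RegimePainting,
                         alpha: float) -> np.ndarray:
    """OU expectation weights by numeric integration over path segments."""
    W = np.zeros((tree.n_tips, 1 + painting.n_regimes))
    for i, tip in enumerate(tree.tips):
        Ti = tree.depth[tip]
        W[i, 0] = np.exp(-alpha * Ti)
        for v in root_path_edges(tree, tip):
            ta = tree.depth[tree.parent[v]]
            tb = tree.depth[v]
            val, _ = integrate.quad(
                lambda t: alpha * np.exp(-alpha * (Ti - t)), ta, tb,
                epsabs=1e-13, epsrel=1e-13,
            )
            W[i, 1 + painting.node_regime[v]] += val
    return W


def ou_cov_quad(tree: wp.Phylogeny, alpha: float, sigma2: float) -> np.ndarray:
    """OU tip covariance by numeric integration over the shared path."""
    n = tree.n_tips
    C = shared_path_vcv(tree)
    T = np.diag(C)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ta = C[i, j]
            if ta == 0:
                continue
            val, _ = integrate.quad(
                lambda t: sigma2 * np.exp(-alpha * (T[i] - t))
                * np.exp(-alpha * (T[j] - t)),
                0.0, ta, epsabs=1e-13, epsrel=1e-13,
            )
            V[i, j] = val
    return V


def dense_mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    from scipy.stats import multivariate_normal
    return float(multivariate_normal(mean=mean, cov=cov).logpdf(y))
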