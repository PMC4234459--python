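"""Phylogenetic comparative engine.

Continuous-trait models on a rooted, branch-length phylogeny:

* Brownian motion (BM): tip values are multivariate normal with mean
  ``z0`` and covariance ``sigma2 * C`` where ``C_ij`` is the shared
  root-to-MRCA path length.
* Pagel's lambda: the off-diagonal of ``C`` is multiplied by
  ``lambda in [0, 1]``; the ML estimate measures phylogenetic signal and
  its significance is assessed by permuting trait values across tips.
* Multi-regime Ornstein-Uhlenbeck (Hansen) models: each branch is
  painted with a selective regime carrying its own optimum ``theta_r``;
  with selection strength ``alpha`` and diffusion ``sigma2``, tip
  expectations are exponentially weighted mixtures of the root state and
  the optima visited along the root-to-tip path, and covariances decay
  with phylogenetic distance.

Model fits are compared with the small-sample-corrected Akaike criterion
(AICc).  Ancestral states under BM are the GLS/ML point estimates.
Trees are read and written as Newick via dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Phylogeny", "RegimePainting", "EvolutionModelFit", "PhyloSignalResult",
    "read_newick", "write_newick", "vcv_matrix", "lambda_transform",
    "bm_loglik", "fit_brownian", "fit_lambda", "paint_regimes",
    "ou_expectation_weights", "ou_covariance", "ou_loglik", "fit_ou",
    "aicc", "compare_models", "ancestral_states",
    "simulate_bm", "simulate_ou",
]


# ---------------------------------------------------------------------------
# Tree container and Newick I/O


class Phylogeny:
    """Rooted tree with branch lengths, stored as parent/child arrays.

    Nodes are indexed in preorder with the root at index 0.  ``parent[0]``
    is -1 and the root branch length is 0.  Tip labels are unique.
    """

    def __init__(self, parent: np.ndarray, blen: np.ndarray,
                 labels: dict[int, str]):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        if np.any(self.blen < 0):
            raise ValueError("negative branch length")
        self.n_nodes = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(1, self.n_nodes):
            self.children[self.parent[v]].append(v)
        self.tips = np.array(
            [v for v in range(self.n_nodes) if not self.children[v]], dtype=int
        )
        if len(self.tips) < 2:
            raise ValueError("tree must have at least 2 tips")
        self.labels = dict(labels)
        tip_labels = [self.labels.get(v) for v in self.tips]
        if any(l is None for l in tip_labels):
            raise ValueError("every tip must be labeled")
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {', '.join(dupes)}")
        self.tip_labels: list[str] = tip_labels  # order matches self.tips
        self._tip_index = {l: i for i, l in enumerate(self.tip_labels)}
        self._node_of_label = {self.labels[v]: v for v in self.tips}
        # depth of each node from the root
        self.depth = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            self.depth[v] = self.depth[self.parent[v]] + self.blen[v]
        self._mrca_depth: np.ndarray | None = None

    # -- construction -------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def height(self) -> float:
        return float(self.depth[self.tips].max())

    @property
    def tip_depths(self) -> np.ndarray:
        return self.depth[self.tips]

    def tip_node(self, label: str) -> int:
        try:
            return self._node_of_label[label]
        except KeyError:
            raise KeyError(f"unknown tip label {label!r}") from None

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def mrca(self, nodes: list[int]) -> int:
        """Most recent common ancestor of a set of nodes."""
        paths = []
        for v in nodes:
            path = []
            while v != -1:
                path.append(v)
                v = self.parent[v]
            paths.append(path[::-1])
        anc = 0
        for level in zip(*paths):
            if len(set(level)) == 1:
                anc = level[0]
            else:
                break
        return anc

    def subtree_nodes(self, root: int) -> list[int]:
        out, stack = [], [root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def mrca_depth_matrix(self) -> np.ndarray:
        """Depth of the MRCA for every node pair (all nodes, not just tips)."""
        if self._mrca_depth is not None:
            return self._mrca_depth
        n = self.n_nodes
        M = np.zeros((n, n))
        desc: dict[int, list[int]] = {}
        for v in self.postorder():
            M[v, v] = self.depth[v]
            groups = [desc.pop(c) for c in self.children[v]]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    gi = np.array(groups[i])
                    gj = np.array(groups[j])
                    M[np.ix_(gi, gj)] = self.depth[v]
                    M[np.ix_(gj, gi)] = self.depth[v]
            below = [u for g in groups for u in g]
            if below:
                M[v, below] = self.depth[v]
                M[below, v] = self.depth[v]
            desc[v] = below + [v]
        self._mrca_depth = M
        return M

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, default_blen: float = 1.0) -> "Phylogeny":
        return read_newick(text, default_blen=default_blen)

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                body = self.labels[v]
            else:
                inner = ",".join(fmt(c) for c in self.children[v])
                body = f"({inner})" + self.labels.get(v, "")
            if v == 0:
                return body
            return f"{body}:{self.blen[v]:.12g}"

        return fmt(0) + ";"


def read_newick(text: str, default_blen: float = 1.0) -> Phylogeny:
    """Parse a single Newick tree.  Polytomies are allowed.

    Branches without an explicit length get ``default_blen`` (1.0, the
    all-ones convention used for topological-only analyses).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    index: dict[dendropy.Node, int] = {}
    parent, blen, labels = [], [], {}
    for i, node in enumerate(dtree.preorder_node_iter()):
        index[node] = i
        parent.append(index[node.parent_node] if node.parent_node else -1)
        blen.append(0.0 if node.parent_node is None
                    else (node.edge.length if node.edge.length is not None
                          else default_blen))
        name = None
        if node.taxon is not None:
            name = node.taxon.label
        elif node.label:
            name = node.label
        if node.is_leaf():
            if name is None:
                raise ValueError("Newick parse error: unlabeled tip")
            labels[i] = name
        elif name is not None:
            labels[i] = name
    return Phylogeny(np.array(parent), np.array(blen), labels)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------------
# Covariance structures


def vcv_matrix(tree: Phylogeny) -> np.ndarray:
    """Brownian covariance structure: C_ij = depth of MRCA(i, j)."""
    M = tree.mrca_depth_matrix()
    return M[np.ix_(tree.tips, tree.tips)].copy()


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonals scaled by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    Cl = lam * np.asarray(C, dtype=float)
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def ou_covariance(tree: Phylogeny, alpha: float, sigma2: float) -> np.ndarray:
    """OU stationary-increment covariance among tips (non-ultrametric form).

    V_ij = sigma2/(2 alpha) * exp(-alpha (T_i + T_j - 2 t_a)) *
           (1 - exp(-2 alpha t_a)),  t_a = root-to-MRCA depth.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    C = vcv_matrix(tree)
    T = np.diag(C)
    D = T[:, None] + T[None, :] - 2 * C  # phylogenetic distance
    return sigma2 / (2 * alpha) * np.exp(-alpha * D) * (-np.expm1(-2 * alpha * C))


# ---------------------------------------------------------------------------
# Regime painting


@dataclass
class RegimePainting:
    """Regime id of the branch subtending each node; the root carries
    ``root_regime``.  Regime ids are contiguous from 0."""

    node_regime: np.ndarray
    root_regime: int
    n_regimes: int

    def __post_init__(self) -> None:
        regs = set(self.node_regime.tolist()) | {self.root_regime}
        if regs != set(range(self.n_regimes)):
            raise ValueError(
                f"regime ids {sorted(regs)} are not contiguous 0..{self.n_regimes - 1}"
            )


def paint_regimes(
    tree: Phylogeny,
    clade_specs: list[tuple[int, list[str]]],
    root_regime: int = 0,
) -> RegimePainting:
    """Paint branches by clade membership.

    Each spec is ``(regime_id, tip_labels)``; the clade is the MRCA of the
    named tips and the painting covers every branch in the clade including
    its stem.  Nested clades override their parents (specs are applied
    largest-first), so e.g. a BEP regime nested inside a monocot regime
    yields three connected branch sets.  Unpainted branches carry the root
    regime.
    """
    node_regime = np.full(tree.n_nodes, root_regime, dtype=int)
    resolved = []
    for regime_id, tip_labels in clade_specs:
        nodes = [tree.tip_node(l) for l in tip_labels]
        anc = tree.mrca(nodes) if len(nodes) > 1 else nodes[0]
        sub = tree.subtree_nodes(anc)
        resolved.append((len(sub), regime_id, sub))
    for _, regime_id, sub in sorted(resolved, key=lambda t: -t[0]):
        node_regime[sub] = regime_id
    n_regimes = int(max(node_regime.max(), root_regime)) + 1
    return RegimePainting(node_regime=node_regime, root_regime=root_regime,
                          n_regimes=n_regimes)


def single_regime_painting(tree: Phylogeny) -> RegimePainting:
    return paint_regimes(tree, [])


# ---------------------------------------------------------------------------
# Likelihoods


def _align(tree: Phylogeny, x) -> tuple[np.ndarray, np.ndarray]:
    """Map trait values onto tip order; returns (tip positions, values).

    ``x`` is a mapping or pandas Series keyed by tip label; tips without a
    (finite) value are dropped.
    """
    if isinstance(x, pd.Series):
        data = x.to_dict()
    else:
        data = dict(x)
    idx, vals = [], []
    for i, label in enumerate(tree.tip_labels):
        v = data.get(label)
        if v is not None and np.isfinite(v):
            idx.append(i)
            vals.append(float(v))
    unknown = set(data) - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"trait labels not on tree: {sorted(unknown)[:5]}")
    return np.array(idx, dtype=int), np.array(vals)


def _mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    n = len(y)
    cf = cho_factor(cov, lower=True)
    logdet = 2 * np.sum(np.log(np.diag(cf[0])))
    r = y - mean
    quad = r @ cho_solve(cf, r)
    return float(-0.5 * (n * math.log(2 * math.pi) + logdet + quad))


def bm_loglik(tree: Phylogeny, x, sigma2: float, z0: float) -> float:
    """Log-likelihood of tip values under Brownian motion."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    idx, y = _align(tree, x)
    if len(y) < 2:
        raise ValueError("need at least 2 tips with data")
    C = vcv_matrix(tree)[np.ix_(idx, idx)]
    return _mvn_loglik(y, np.full(len(y), z0), sigma2 * C)


@dataclass
class EvolutionModelFit:
    """Fitted parameters and fit statistics of a BM or OU model."""

    model: str
    sigma2: float
    lnl: float
    k: int
    n: int
    aicc: float
    z0: float
    alpha: float | None = None
    theta: np.ndarray | None = None
    flags: tuple[str, ...] = ()
    root_mode: str | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "sigma2": self.sigma2,
            "alpha": self.alpha,
            "theta": None if self.theta is None else list(map(float, self.theta)),
            "z0": self.z0,
            "lnL": self.lnl,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "flags": list(self.flags),
        }


def _gls_bm(y: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """Closed-form ML fit of (z0, sigma2) under covariance sigma2*C.

    Returns (z0_hat, sigma2_hat, lnl)."""
    n = len(y)
    cf = cho_factor(C, lower=True)
    logdetC = 2 * np.sum(np.log(np.diag(cf[0])))
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    z0 = float(ones @ cho_solve(cf, y) / (ones @ Ci1))
    r = y - z0
    s2 = float(r @ cho_solve(cf, r) / n)
    if s2 <= 0 or not np.isfinite(s2):
        return z0, 0.0, math.inf
    lnl = -0.5 * (n * math.log(2 * math.pi * s2) + logdetC + n)
    return z0, s2, float(lnl)


def aicc(lnl: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_brownian(tree: Phylogeny, x) -> EvolutionModelFit:
    """ML Brownian-motion fit: GLS root state and closed-form rate."""
    idx, y = _align(tree, x)
    if len(y) < 2:
        raise ValueError("need at least 2 tips with data to fit BM")
    C = vcv_matrix(tree)[np.ix_(idx, idx)]
    z0, s2, lnl = _gls_bm(y, C)
    flags: list[str] = []
    if s2 == 0.0:
        flags.append("degenerate_zero_variance")
        lnl = math.inf
    n = len(y)
    if not np.isfinite(lnl):
        crit = -math.inf
    elif n <= 3:  # AICc needs n > k + 1
        crit = math.nan
        flags.append("aicc_undefined_small_n")
    else:
        crit = aicc(lnl, 2, n)
    return EvolutionModelFit(
        model="BM", sigma2=s2, lnl=lnl, k=2, n=n, aicc=crit,
        z0=z0, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Pagel's lambda


@dataclass
class PhyloSignalResult:
    """ML Pagel's lambda with permutation significance."""

    lambda_hat: float
    lnl_lambda: float
    lnl_zero: float
    p_value: float | None
    n_randomizations: int
    p_lrt: float


def _profile_lambda_lnl(y: np.ndarray, C: np.ndarray, lam: float) -> float:
    _, _, lnl = _gls_bm(y, lambda_transform(C, lam))
    return lnl


def _ml_lambda(y: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    res = optimize.minimize_scalar(
        lambda lam: -_profile_lambda_lnl(y, C, lam),
        bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [(float(res.x), -float(res.fun))]
    for lam in (0.0, 1.0):
        candidates.append((lam, _profile_lambda_lnl(y, C, lam)))
    lam_hat, lnl = max(candidates, key=lambda t: t[1])
    if not np.isfinite(lnl):
        raise ValueError(f"non-finite likelihood at lambda={lam_hat}")
    return lam_hat, lnl


def fit_lambda(
    tree: Phylogeny,
    x,
    n_randomizations: int = 1000,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Pagel's lambda by bounded ML, with permutation significance.

    The p-value permutes trait values across tips and compares the
    likelihood improvement of the fitted lambda over lambda = 0 against the
    permutation distribution: p = (1 + #{LR_perm >= LR_obs}) / (B + 1).
    A chi-square(1) likelihood-ratio p-value is reported alongside.
    """
    idx, y = _align(tree, x)
    if len(y) < 4:
        raise ValueError("need at least 4 tips with data")
    C = vcv_matrix(tree)[np.ix_(idx, idx)]
    lam_hat, lnl_hat = _ml_lambda(y, C)
    lnl0 = _profile_lambda_lnl(y, C, 0.0)
    lr_obs = lnl_hat - lnl0
    p_lrt = float(stats.chi2.sf(max(2 * lr_obs, 0.0), df=1))
    p_value = None
    if n_randomizations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_randomizations):
            yp = rng.permutation(y)
            _, lnl_p = _ml_lambda(yp, C)
            lr_p = lnl_p - _profile_lambda_lnl(yp, C, 0.0)
            if lr_p >= lr_obs - 1e-12:
                exceed += 1
        p_value = (1 + exceed) / (n_randomizations + 1)
    return PhyloSignalResult(
        lambda_hat=lam_hat, lnl_lambda=lnl_hat, lnl_zero=lnl0,
        p_value=p_value, n_randomizations=n_randomizations, p_lrt=p_lrt,
    )


# ---------------------------------------------------------------------------
# Multi-regime OU


def ou_expectation_weights(
    tree: Phylogeny, painting: RegimePainting, alpha: float
) -> np.ndarray:
    """Tip-expectation design: E[x_i] = W_i0 z0 + sum_r W_ir theta_r.

    ``W`` has shape (n_tips, 1 + n_regimes); column 0 weights the root
    state (exp(-alpha T_i)), column 1+r weights optimum r by the summed
    exponential windows of regime-r segments on the root-to-tip path.
    Rows sum to 1 by telescoping.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    R = painting.n_regimes
    W = np.zeros((tree.n_tips, 1 + R))
    for i, tip in enumerate(tree.tips):
        Ti = tree.depth[tip]
        W[i, 0] = math.exp(-alpha * Ti)
        v = tip
        while v != 0:
            ta = tree.depth[tree.parent[v]]
            tb = tree.depth[v]
            r = painting.node_regime[v]
            W[i, 1 + r] += math.exp(-alpha * (Ti - tb)) - math.exp(-alpha * (Ti - ta))
            v = tree.parent[v]
    return W


def ou_loglik(
    tree: Phylogeny, x, painting: RegimePainting,
    alpha: float, sigma2: float, theta: np.ndarray, z0: float,
) -> float:
    """Log-likelihood of tip values under a painted OU model."""
    idx, y = _align(tree, x)
    W = ou_expectation_weights(tree, painting, alpha)[idx]
    theta = np.asarray(theta, dtype=float)
    mean = W[:, 0] * z0 + W[:, 1:] @ theta
    V = ou_covariance(tree, alpha, sigma2)[np.ix_(idx, idx)]
    return _mvn_loglik(y, mean, V)


def _ou_profile(
    y: np.ndarray, W: np.ndarray, V1: np.ndarray,
    root_regime: int, root_mode: str,
) -> tuple[float, np.ndarray, float, float]:
    """Profile out (theta, z0, sigma2) at fixed alpha.

    ``V1`` is the OU covariance at sigma2 = 1.  Returns
    (lnl, theta_hat, z0_hat, sigma2_hat)."""
    n = len(y)
    if root_mode == "root_regime_optimum":
        X = W[:, 1:].copy()
        X[:, root_regime] += W[:, 0]
    elif root_mode == "estimated":
        X = W.copy()
    else:
        raise ValueError(f"unknown root_mode {root_mode!r}")
    cf = cho_factor(V1, lower=True)
    logdetV1 = 2 * np.sum(np.log(np.diag(cf[0])))
    Xi = cho_solve(cf, X)
    try:
        beta = np.linalg.solve(X.T @ Xi, X.T @ cho_solve(cf, y))
    except np.linalg.LinAlgError:
        # numerically collinear design (e.g. alpha so small that a regime's
        # exponential window vanishes); report an unusable candidate
        return -math.inf, np.full(X.shape[1], math.nan), math.nan, 0.0
    r = y - X @ beta
    rss = float(r @ cho_solve(cf, r))
    s2 = rss / n
    if s2 <= 0 or not np.isfinite(s2):
        return -math.inf, beta, math.nan, 0.0
    lnl = -0.5 * (n * math.log(2 * math.pi * s2) + logdetV1 + n)
    if root_mode == "root_regime_optimum":
        theta = beta
        z0 = float(beta[root_regime])
    else:
        z0 = float(beta[0])
        theta = beta[1:]
    return float(lnl), theta, z0, s2


def fit_ou(
    tree: Phylogeny,
    x,
    painting: RegimePainting,
    root_mode: str = "root_regime_optimum",
    alpha_grid_size: int = 60,
    alpha_bounds: tuple[float, float] = (1e-6, 100.0),
) -> EvolutionModelFit:
    """ML multi-optimum OU fit by profile likelihood over alpha.

    For each alpha on a log grid (bounds scaled by tree height) the optima
    (and root state, if estimated) solve GLS normal equations and sigma2
    is profiled in closed form; the best grid point is refined by bounded
    1-D optimization.  With ``root_mode='root_regime_optimum'`` (the
    convention of standard multi-regime OU software, and the default) the
    root state equals the root regime's optimum, so k = 2 + n_regimes.
    """
    idx, y = _align(tree, x)
    R = painting.n_regimes
    if len(y) < R + 2:
        raise ValueError(f"need at least {R + 2} tips with data for {R} regimes")
    # structural identifiability: every regime must lie on some observed
    # tip's root path (the root regime is always identifiable by default,
    # via the root-state weight)
    visited = set()
    for i in idx:
        v = tree.tips[i]
        while v != 0:
            visited.add(int(painting.node_regime[v]))
            v = tree.parent[v]
    if root_mode == "root_regime_optimum":
        visited.add(painting.root_regime)
    missing = set(range(R)) - visited
    if missing:
        raise ValueError(
            f"non-identifiable design: regime(s) {sorted(missing)} never "
            "visited by any observed tip"
        )
    H = tree.height
    lo, hi = alpha_bounds[0] / H, alpha_bounds[1] / H
    alphas = np.geomspace(lo, hi, alpha_grid_size)
    C = vcv_matrix(tree)
    T = np.diag(C)
    D = T[:, None] + T[None, :] - 2 * C
    Csub = np.ix_(idx, idx)

    def profile(alpha: float):
        V1 = (1.0 / (2 * alpha)) * np.exp(-alpha * D) * (-np.expm1(-2 * alpha * C))
        W = ou_expectation_weights(tree, painting, alpha)[idx]
        return _ou_profile(y, W, V1[Csub], painting.root_regime, root_mode)

    lnls = np.array([profile(a)[0] for a in alphas])
    best = int(np.argmax(lnls))
    lo_b = alphas[max(best - 1, 0)]
    hi_b = alphas[min(best + 1, len(alphas) - 1)]
    res = optimize.minimize_scalar(
        lambda la: -profile(math.exp(la))[0],
        bounds=(math.log(lo_b), math.log(hi_b)), method="bounded",
        options={"xatol": 1e-10},
    )
    alpha_hat = float(math.exp(res.x))
    if -float(res.fun) < lnls[best]:
        alpha_hat = float(alphas[best])
    lnl, theta, z0, s2 = profile(alpha_hat)
    flags = []
    if best in (0, len(alphas) - 1):
        flags.append("alpha_at_grid_boundary")
    n = len(y)
    if root_mode == "root_regime_optimum":
        k = 2 + R
    else:
        k = 3 + R
    model = f"OU{R}"
    return EvolutionModelFit(
        model=model, sigma2=s2, lnl=lnl, k=k, n=n,
        aicc=aicc(lnl, k, n), z0=z0, alpha=alpha_hat,
        theta=np.asarray(theta), flags=tuple(flags), root_mode=root_mode,
    )


def compare_models(fits: list[EvolutionModelFit]) -> pd.DataFrame:
    """AICc ranking table, best model first, with delta-AICc column."""
    if not fits:
        raise ValueError("no fits to compare")
    rows = [f.to_dict() for f in fits]
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort")
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Ancestral states


def ancestral_states(tree: Phylogeny, x) -> pd.DataFrame:
    """GLS/ML ancestral values at internal nodes under Brownian motion.

    Conditioning the joint tip/ancestor normal on the observed tips:
    z_anc = z0 + S C^-1 (x - z0), with S the ancestor-tip shared path
    lengths.  Returns a node table (node id, depth, value, is_tip).
    """
    fit = fit_brownian(tree, x)
    idx, y = _align(tree, x)
    M = tree.mrca_depth_matrix()
    obs_nodes = tree.tips[idx]
    C = M[np.ix_(obs_nodes, obs_nodes)]
    cf = cho_factor(C, lower=True)
    resid = cho_solve(cf, y - fit.z0)
    internal = np.array(
        [v for v in range(tree.n_nodes) if tree.children[v]], dtype=int
    )
    S = M[np.ix_(internal, obs_nodes)]
    anc = fit.z0 + S @ resid
    rows = []
    for v, val in zip(internal, anc):
        rows.append((int(v), tree.labels.get(v, f"node{v}"),
                     float(tree.depth[v]), float(val), False))
    for pos, (i, tip) in enumerate(zip(idx, obs_nodes)):
        rows.append((int(tip), tree.tip_labels[i],
                     float(tree.depth[tip]), float(y[pos]), True))
    return pd.DataFrame(
        rows, columns=["node", "label", "depth", "value", "is_tip"]
    ).sort_values("node").reset_index(drop=True)


def annotated_newick(tree: Phylogeny, node_values: pd.DataFrame) -> str:
    """Newick with per-node bracketed comment values (ancestral states)."""
    vals = dict(zip(node_values["node"], node_values["value"]))

    def fmt(v: int) -> str:
        if not tree.children[v]:
            body = tree.labels[v]
        else:
            inner = ",".join(fmt(c) for c in tree.children[v])
            body = f"({inner})" + tree.labels.get(v, "")
        note = f"[&value={vals[v]:.6g}]" if v in vals else ""
        if v == 0:
            return body + note
        return f"{body}{note}:{tree.blen[v]:.12g}"

    return fmt(0) + ";"


# ---------------------------------------------------------------------------
# Simulation


def simulate_bm(tree: Phylogeny, sigma2: float, z0: float,
                seed: int | None = None) -> pd.Series:
    """Simulate tip values under Brownian motion (preorder recursion)."""
    rng = np.random.default_rng(seed)
    state = np.empty(tree.n_nodes)
    state[0] = z0
    for v in range(1, tree.n_nodes):
        mu = state[tree.parent[v]]
        var = sigma2 * tree.blen[v]
        state[v] = mu + (rng.normal(0.0, math.sqrt(var)) if var > 0 else 0.0)
    return pd.Series(state[tree.tips], index=tree.tip_labels)


def simulate_ou(
    tree: Phylogeny, painting: RegimePainting,
    alpha: float, sigma2: float, theta: np.ndarray, z0: float,
    seed: int | None = None,
) -> pd.Series:
    """Simulate tip values under a painted OU process.

    Along a branch of length t in regime r the transition is
    Normal(theta_r + (parent - theta_r) exp(-alpha t),
           sigma2 (1 - exp(-2 alpha t)) / (2 alpha)).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    theta = np.asarray(theta, dtype=float)
    if len(theta) != painting.n_regimes:
        raise ValueError("theta length must match number of regimes")
    rng = np.random.default_rng(seed)
    state = np.empty(tree.n_nodes)
    state[0] = z0
    for v in range(1, tree.n_nodes):
        t = tree.blen[v]
        th = theta[painting.node_regime[v]]
        mu = th + (state[tree.parent[v]] - th) * math.exp(-alpha * t)
        var = sigma2 * (-math.expm1(-2 * alpha * t)) / (2 * alpha)
        state[v] = mu + (rng.normal(0.0, math.sqrt(var)) if var > 0 else 0.0)
    return pd.Series(state[tree.tips], index=tree.tip_labels)
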