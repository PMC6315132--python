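"""Phylogenetic signal: Blomberg's K with a tip-shuffle permutation test, and
Brownian-motion ancestral state estimation.

Blomberg's K compares the mean squared error of tip values around the
phylogenetically correct (GLS) mean, MSE0, with the mean squared error under
the tree's Brownian covariance, MSE, and scales the observed ratio by its
Brownian expectation:

    K = (MSE0 / MSE)  /  E_BM[MSE0 / MSE],
    E_BM[MSE0 / MSE] = (tr(V) - n / sum(V^-1)) / (n - 1).

K ≈ 1 when a trait evolved by Brownian motion on the tree, K ≪ 1 for
convergent or tree-independent (labile) traits, K > 1 when close relatives
are even more similar than Brownian motion predicts.  K is dimensionless:
invariant to affine transforms of the trait and to a global rescaling of
branch lengths.

The permutation test shuffles trait values across tips and asks whether the
observed MSE is smaller (the data fit the tree better) than label-shuffled
data; p uses the add-one rule so it is never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .tree import Phylogeny, PhyloVCV

log = logging.getLogger(__name__)

RIDGE_FACTOR = 1e-8


@dataclass(frozen=True)
class SignalResult:
    """Blomberg's K for one trait, with its permutation p-value."""

    trait: str
    k: float
    p: float
    n_tips: int
    n_permutations: int
    observed_ratio: float
    expected_ratio: float
    mse0: float
    mse: float


@dataclass(frozen=True)
class AncestralStates:
    """GLS/Brownian point estimates of trait values at internal nodes.

    ``table`` has one row per node (tips included) with columns
    ``node`` (identifier), ``depth`` (root-to-node path length), ``value``
    (observed at tips, estimated at internal nodes), ``variance``
    (conditional variance of the estimate; 0 at tips) and ``is_tip``.
    """

    trait: str
    root_value: float
    table: pd.DataFrame


class _VCVSolver:
    """Cached Cholesky machinery for one VCV; adds a logged ridge if singular."""

    def __init__(self, vcv: PhyloVCV):
        self.labels = vcv.labels
        V = vcv.values
        self.n = V.shape[0]
        try:
            self._cho = linalg.cho_factor(V, lower=True)
            self.V = V
        except linalg.LinAlgError:
            ridge = RIDGE_FACTOR * float(np.mean(np.diag(V)))
            log.warning("singular VCV: adding ridge %.3g to the diagonal", ridge)
            self.V = V + ridge * np.eye(self.n)
            self._cho = linalg.cho_factor(self.V, lower=True)
        ones = np.ones(self.n)
        self.u = linalg.cho_solve(self._cho, ones)  # V^-1 1
        self.s = float(ones @ self.u)  # 1' V^-1 1 = sum of V^-1
        self.trace = float(np.trace(self.V))

    def solve(self, B: np.ndarray) -> np.ndarray:
        return linalg.cho_solve(self._cho, B)

    def gls_mean(self, x: np.ndarray) -> float:
        return float(self.u @ x / self.s)


def _align(vcv: PhyloVCV, x) -> tuple[PhyloVCV, np.ndarray, str]:
    if isinstance(x, pd.Series):
        name = str(x.name) if x.name is not None else "trait"
        missing = [l for l in vcv.labels if l not in x.index]
        if missing:
            raise ValueError(f"trait values missing for tips: {missing}")
        vec = x.reindex(list(vcv.labels)).to_numpy(float)
    else:
        vec = np.asarray(x, dtype=float)
        name = "trait"
        if vec.shape != (vcv.n,):
            raise ValueError(f"trait vector length {vec.shape} does not match {vcv.n} tips")
    if np.any(~np.isfinite(vec)):
        raise ValueError("trait vector contains non-finite values")
    return vcv, vec, name


def phylogenetic_mean(vcv: PhyloVCV, x) -> float:
    """GLS estimate of the root value under Brownian motion:
    â = (1' V⁻¹ 1)⁻¹ 1' V⁻¹ x.  Reduces to the arithmetic mean on a star tree."""
    vcv, vec, _ = _align(vcv, x)
    return _VCVSolver(vcv).gls_mean(vec)


def _k_parts(solver: _VCVSolver, x: np.ndarray) -> tuple[float, float, float, float]:
    n = solver.n
    a_hat = solver.gls_mean(x)
    resid = x - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ solver.solve(resid)) / (n - 1)
    if mse == 0:
        raise ValueError("zero trait variance: MSE is 0")
    expected = (solver.trace - n / solver.s) / (n - 1)
    return mse0, mse, expected, a_hat


def blomberg_k(vcv: PhyloVCV, x, trait: str | None = None) -> SignalResult:
    """Blomberg's K for one trait on one tree (no permutation test; p is NaN)."""
    vcv, vec, name = _align(vcv, x)
    if vcv.n < 3:
        raise ValueError("Blomberg's K needs at least 3 tips")
    if np.ptp(vec) == 0:
        raise ValueError("zero trait variance: trait is constant across tips")
    solver = _VCVSolver(vcv)
    mse0, mse, expected, _ = _k_parts(solver, vec)
    observed = mse0 / mse
    return SignalResult(
        trait=trait or name,
        k=observed / expected,
        p=float("nan"),
        n_tips=vcv.n,
        n_permutations=0,
        observed_ratio=observed,
        expected_ratio=expected,
        mse0=mse0,
        mse=mse,
    )


def k_permutation_test(
    vcv: PhyloVCV,
    x,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    trait: str | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-label permutation test.

    Trait values are shuffled across tips ``n_perm`` times; the p-value is
    the add-one-rule fraction of shuffles whose MSE is no larger than the
    observed MSE (small p: the observed data fit the tree's covariance
    better than label-shuffled data, i.e. significant signal).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if seed is None:
        raise ValueError("a seed (or Generator) is required for the permutation test")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = blomberg_k(vcv, x, trait=trait)
    _, vec, _ = _align(vcv, x)
    solver = _VCVSolver(vcv)
    n = solver.n
    # vectorized MSE over permutations: MSE = (x'V⁻¹x − (1'V⁻¹x)²/s) / (n−1)
    perms = rng.permuted(np.tile(vec, (n_perm, 1)), axis=1)
    Vinv_rows = solver.solve(perms.T).T  # (n_perm, n)
    quad = np.einsum("ij,ij->i", Vinv_rows, perms)
    lin = perms @ solver.u
    mse_perm = (quad - lin**2 / solver.s) / (n - 1)
    b = int(np.sum(mse_perm <= base.mse + 1e-12 * abs(base.mse)))
    p = (1 + b) / (1 + n_perm)
    return SignalResult(
        trait=base.trait,
        k=base.k,
        p=p,
        n_tips=base.n_tips,
        n_permutations=n_perm,
        observed_ratio=base.observed_ratio,
        expected_ratio=base.expected_ratio,
        mse0=base.mse0,
        mse=base.mse,
    )


def signal_report(
    tree: Phylogeny,
    traits: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-trait K and permutation p for every column of a trait table.

    Species with a missing value for a trait are dropped from that trait's
    test (the VCV is subset accordingly).  Returns a tidy frame with columns
    trait, K, p, n_tips, n_permutations.
    """
    if seed is None:
        raise ValueError("seed is required")
    vcv_full = tree.vcv()
    rows = []
    ss = np.random.SeedSequence(seed)
    for child, col in zip(ss.spawn(len(traits.columns)), traits.columns):
        series = traits[col].dropna()
        keep = [l for l in vcv_full.labels if l in series.index]
        if len(keep) < 3:
            log.warning("trait %s: fewer than 3 species with data; skipped", col)
            continue
        sub = vcv_full.reorder(keep)
        res = k_permutation_test(
            sub, series.reindex(keep), n_perm=n_perm,
            seed=np.random.default_rng(child), trait=str(col),
        )
        rows.append(
            {"trait": res.trait, "K": res.k, "p": res.p,
             "n_tips": res.n_tips, "n_permutations": res.n_permutations}
        )
    return pd.DataFrame(rows)


def ancestral_states(tree: Phylogeny, x, trait: str | None = None) -> AncestralStates:
    """Maximum-likelihood Brownian-motion states at internal nodes.

    Each internal node u gets the GLS conditional expectation
    x̂_u = â + c_u' V⁻¹ (x − â·1), where c_u[i] = depth of MRCA(u, tip i) is
    the Brownian covariance between node u and tip i.  The root estimate is
    the phylogenetic (GLS) mean; conditional variances use the ML rate
    σ̂² = (x − â)' V⁻¹ (x − â) / n.
    """
    vcv = tree.vcv()
    vcv, vec, name = _align(vcv, x)
    solver = _VCVSolver(vcv)
    a_hat = solver.gls_mean(vec)
    resid = vec - a_hat
    w = solver.solve(resid)  # V⁻¹ (x − â)
    sigma2 = float(resid @ w) / solver.n
    index = {lab: k for k, lab in enumerate(vcv.labels)}
    depths = tree._node_depths()
    V = solver.V

    rows = []
    rep_tip: dict = {}  # node -> index of one descendant tip
    for i, node in enumerate(tree.tree.postorder_node_iter()):
        if node.is_leaf():
            k = index[node.taxon.label]
            rep_tip[node] = k
            rows.append(
                {"node": node.taxon.label, "depth": depths[node],
                 "value": float(vec[k]), "variance": 0.0, "is_tip": True}
            )
        else:
            children = node.child_nodes()
            rep = rep_tip[children[0]]
            rep_tip[node] = rep
            depth = depths[node]
            # cov(u, tip i): depth(u) if i below u, else cov(representative tip, i)
            below = _tips_below(node, index)
            c = V[rep].copy()
            c[below] = depth
            value = a_hat + float(c @ w)
            # GLS prediction variance, including uncertainty in the root mean
            shrink = float(c @ solver.solve(c))
            mean_term = (1.0 - float(c @ solver.u)) ** 2 / solver.s
            var = sigma2 * max(depth - shrink + mean_term, 0.0)
            label = f"node{i}" if node.parent_node is not None else "root"
            rows.append(
                {"node": label, "depth": depth, "value": value,
                 "variance": var, "is_tip": False}
            )
    table = pd.DataFrame(rows)
    root_value = float(table.loc[table["node"] == "root", "value"].iloc[0])
    return AncestralStates(trait=trait or name, root_value=root_value, table=table)


def _tips_below(node, index) -> np.ndarray:
    return np.asarray([index[leaf.taxon.label] for leaf in node.leaf_iter()], dtype=np.intp)
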