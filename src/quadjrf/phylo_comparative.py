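"""Phylogenetic regression and ancestral states under Brownian motion.

Comparative data from a clade are not independent: under Brownian motion the
covariance of a trait between two tips equals the branch length they share
from the root to their most recent common ancestor.  This module builds that
covariance from a rooted, branch-length-bearing tree, fits generalized least
squares regressions of one trait on another with it (PGLS), and estimates
maximum-likelihood ancestral states for continuous traits — used here to
regress joint-reaction-force axis components on quadrate-axis components and
to reconstruct their joint evolutionary history.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

from .errors import TreeError

__all__ = [
    "Phylo",
    "PGLSFit",
    "read_newick",
    "phylo_from_string",
    "brownian_covariance",
    "pgls_fit",
    "ancestral_states",
    "ancestral_correlation",
    "simulate_brownian",
]


@dataclass
class Phylo:
    """A rooted tree with branch lengths; tip labels identify specimens."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise TreeError("tip labels are not unique")
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            if node.edge.length is None:
                who = node.taxon.label if node.taxon else "an internal node"
                raise TreeError(f"missing branch length above {who}")
            if node.edge.length < 0:
                raise TreeError("negative branch length")
        self._labels = labels

    @property
    def tip_labels(self) -> list:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    def depths(self) -> dict:
        """Root-to-node path length for every node (root edge ignored)."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                out[node] = 0.0
            else:
                out[node] = out[node.parent_node] + node.edge.length
        return out


def phylo_from_string(newick: str) -> Phylo:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise TreeError(f"cannot parse newick: {exc}") from exc
    return Phylo(tree)


def read_newick(path) -> Phylo:
    """Read a rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise TreeError(f"cannot parse {path}: {exc}") from exc
    return Phylo(tree)


def brownian_covariance(phylo: Phylo, order=None) -> np.ndarray:
    """n×n Brownian covariance: shared root-to-MRCA path length per tip pair.

    ``order`` fixes the row/column tip ordering (defaults to tree order).
    The diagonal holds root-to-tip depths.  Always symmetric PSD.
    """
    labels = order if order is not None else phylo.tip_labels
    if phylo.n_tips < 2:
        raise TreeError("need at least two tips")
    missing = set(labels) - set(phylo.tip_labels)
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    depths = phylo.depths()
    leaf_by_label = {
        leaf.taxon.label: leaf for leaf in phylo.tree.leaf_node_iter()
    }
    # tip sets per node, bottom-up, filling C at each internal node with the
    # node's depth for tip pairs split across its children.
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    C = np.zeros((n, n))
    for lab in labels:
        C[index[lab], index[lab]] = depths[leaf_by_label[lab]]
    tipsets = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            tipsets[node] = [index[lab]] if lab in index else []
            continue
        child_sets = [tipsets.pop(c) for c in node.child_nodes()]
        d = depths[node]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        C[i, j] = C[j, i] = d
        tipsets[node] = [i for s in child_sets for i in s]
    return C


@dataclass
class PGLSFit:
    """A single-component PGLS regression result."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    t_slope: float
    t_intercept: float
    p_slope: float
    p_intercept: float
    df: int
    sigma2: float

    def ci_slope(self, level: float = 0.95):
        half = stats.t.ppf(0.5 + level / 2.0, self.df) * self.slope_se
        return self.slope - half, self.slope + half


def pgls_fit(x, y, C) -> PGLSFit:
    """GLS regression of ``y`` on ``x`` with residual covariance ∝ ``C``.

    β = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with an intercept column; the residual scale is
    σ² = RSS_GLS/(n−2) and slope/intercept t-tests use n−2 degrees of
    freedom, matching classical GLS reporting.  With C ∝ I this is exactly
    ordinary least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least three observations")
    if y.shape != (n,) or C.shape != (n, n):
        raise ValueError("shape mismatch among x, y, C")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; consider adding a small ridge "
            "term to the diagonal"
        ) from exc
    X = np.column_stack([np.ones(n), x])
    # Whiten: solve L z = v so the model becomes OLS in z-space.
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - 2
    sigma2 = float(resid @ resid) / df
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = beta / se
    p_vals = 2.0 * stats.t.sf(np.abs(t_vals), df)
    return PGLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=float(se[1]),
        intercept_se=float(se[0]),
        t_slope=float(t_vals[1]),
        t_intercept=float(t_vals[0]),
        p_slope=float(p_vals[1]),
        p_intercept=float(p_vals[0]),
        df=df,
        sigma2=sigma2,
    )


def ancestral_states(phylo: Phylo, tip_values: dict) -> dict:
    """Maximum-likelihood Brownian ancestral states for every internal node.

    The joint Gaussian conditional of internal states given tip values is
    maximized by the solution of a sparse linear system in which each branch
    contributes conductance 1/length — weighted squared-change parsimony,
    whose optimum coincides with the ML estimates under Brownian motion.
    Returns ``{node_key: value}`` where node_key is the tip label for leaves
    and ``"node{i}"`` (preorder index) for unlabeled internal nodes.
    """
    missing = [lab for lab in phylo.tip_labels if lab not in tip_values]
    if missing:
        raise TreeError(f"missing tip values for: {missing}")
    nodes = list(phylo.tree.preorder_node_iter())
    key = {}
    for i, node in enumerate(nodes):
        if node.is_leaf():
            key[node] = node.taxon.label
        elif node.label:
            key[node] = node.label
        else:
            key[node] = f"node{i}"
    internal = [nd for nd in nodes if not nd.is_leaf()]
    idx = {nd: i for i, nd in enumerate(internal)}
    n_int = len(internal)
    A = np.zeros((n_int, n_int))
    b = np.zeros(n_int)
    for node in nodes:
        if node.parent_node is None:
            continue
        parent = node.parent_node
        length = node.edge.length
        g = 1.0 / max(length, 1e-12)  # guard zero-length branches
        i = idx[parent]
        A[i, i] += g
        if node.is_leaf():
            b[i] += g * float(tip_values[node.taxon.label])
        else:
            j = idx[node]
            A[i, j] -= g
            A[j, i] -= g
            A[j, j] += g
    values = np.linalg.solve(A, b)
    out = {key[nd]: float(tip_values[nd.taxon.label]) for nd in nodes if nd.is_leaf()}
    for nd in internal:
        out[key[nd]] = float(values[idx[nd]])
    return out


def internal_state_values(phylo: Phylo, states: dict) -> np.ndarray:
    """Internal-node state values in preorder (drops the tips)."""
    nodes = list(phylo.tree.preorder_node_iter())
    vals = []
    for i, node in enumerate(nodes):
        if node.is_leaf():
            continue
        k = node.label if node.label else f"node{i}"
        vals.append(states[k])
    return np.asarray(vals, dtype=float)


def ancestral_correlation(states_x, states_y) -> float:
    """Pearson correlation of two sets of (internal-node) state estimates."""
    x = np.asarray(states_x, dtype=float)
    y = np.asarray(states_y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length lists of at least 3 values")
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")  # undefined-correlation flag
    return float(np.corrcoef(x, y)[0, 1])


def simulate_brownian(
    phylo: Phylo, rate: float, seed: int, root_value: float = 0.0,
    bounds=None,
) -> dict:
    """Simulate one Brownian trait along the tree; returns {tip label: value}.

    ``bounds=(lo, hi)`` reflects the walk into the interval at each node.
    """
    rng = np.random.default_rng(seed)
    values = {}
    out = {}
    for node in phylo.tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = root_value
        else:
            step = rng.normal(0.0, rate * np.sqrt(node.edge.length))
            v = values[node.parent_node] + step
            if bounds is not None:
                lo, hi = bounds
                width = hi - lo
                # reflect into [lo, hi]
                v = abs((v - lo) % (2 * width))
                v = lo + (v if v <= width else 2 * width - v)
            values[node] = v
        if node.is_leaf():
            out[node.taxon.label] = float(values[node])
    return out
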