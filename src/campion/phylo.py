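"""Phylogenetic tree handling: I/O, calibration, covariance, and Brownian simulation.

The tree is the backbone of every comparative analysis in this package:
phylogenetic signal, phylogenetic ANOVA, ancestral-state reconstruction and
phylogenetic PCA all consume either the phylogenetic covariance matrix
(shared root-to-ancestor path lengths between tips) or Brownian-motion
simulations on the tree. Newick parsing and serialization are delegated to
dendropy; the comparative machinery itself works on a light array-backed
representation for speed.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "CalibrationBounds",
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "make_ultrametric",
    "cophenetic_distances",
    "phylo_covariance",
    "lambda_max",
    "simulate_bm",
    "ASR_CALIBRATION",
    "PPCA_CALIBRATION",
]


class TreeError(ValueError):
    """Malformed tree or infeasible tree operation."""


@dataclass(frozen=True)
class CalibrationBounds:
    """Age constraint on a node, in Myr.

    ``taxa`` is None for the root, otherwise the constrained node is the
    most recent common ancestor of the named tips.
    """

    age_min: float
    age_max: float
    taxa: tuple[str, ...] | None = None

    def __post_init__(self):
        if not (0 < self.age_min <= self.age_max):
            raise ValueError(
                f"invalid calibration bounds: need 0 < age_min <= age_max, "
                f"got [{self.age_min}, {self.age_max}]"
            )


#: Calibration presets. The ancestral-state tree is dated with a maximum of
#: 31.7 Myr on the root (Saponaria-Silene split) and a 12.39 Myr minimum on
#: the subgenera split when that clade is identifiable; the morphospace
#: (pPCA) tree constrains the root to [15.14, 26.49] Myr.
ASR_CALIBRATION = (CalibrationBounds(age_min=12.39, age_max=31.7, taxa=None),)
PPCA_CALIBRATION = (CalibrationBounds(age_min=15.14, age_max=26.49, taxa=None),)


class PhyloTree:
    """Rooted tree with branch lengths, array-backed.

    Nodes are indexed 0..n_nodes-1 with tips first (0..n_tips-1, in the
    order they appear in the newick). ``parent[i]`` is the parent index
    (-1 for the root), ``edge_length[i]`` the length of the edge above node
    i (0 for the root).
    """

    def __init__(self, parent, edge_length, tip_labels):
        self.parent = np.asarray(parent, dtype=int)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_tips = len(self.tip_labels)
        self.n_nodes = len(self.parent)
        if np.any(self.edge_length < 0):
            raise TreeError("negative branch length")
        if len(set(self.tip_labels)) != self.n_tips:
            raise TreeError("duplicate tip labels")
        self.root = int(np.where(self.parent < 0)[0][0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.postorder = self._postorder()
        self.preorder = self.postorder[::-1]

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        index = {}
        for i, nd in enumerate(tips):
            index[id(nd)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        elen = np.zeros(n)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                bl = nd.edge.length
                elen[i] = 0.0 if bl is None else float(bl)
        labels = []
        for nd in tips:
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("unlabeled tip")
            labels.append(nd.taxon.label)
        tree = cls(parent, elen, labels)
        nz = np.sum((tree.edge_length == 0) & (np.arange(n) != tree.root))
        if nz:
            logger.info("tree contains %d zero-length branches", nz)
        return tree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"newick parse error: {exc}") from exc
        return cls.from_dendropy(dtree)

    def _postorder(self):
        order, stack = [], [self.root]
        visited = []
        while stack:
            v = stack.pop()
            visited.append(v)
            stack.extend(self.children[v])
        return visited[::-1]

    # -- serialization ------------------------------------------------

    def to_newick(self, internal_ids: bool = False) -> str:
        """Serialize to newick; ``internal_ids`` labels internal nodes with
        their stable node index (the key used by ASR/simmap tables)."""
        def rec(v: int) -> str:
            if not self.children[v]:
                s = self.tip_labels[v]
                if any(c in s for c in "(),:; \t"):
                    s = "'" + s.replace("'", "''") + "'"
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
                if internal_ids:
                    s += f"n{v}"
            if v != self.root:
                s += f":{float(self.edge_length[v])!r}"
            return s

        return rec(self.root) + ";"

    def copy(self, edge_length=None) -> "PhyloTree":
        el = self.edge_length if edge_length is None else np.asarray(edge_length, float)
        return PhyloTree(self.parent.copy(), el.copy(), list(self.tip_labels))

    # -- basic queries -------------------------------------------------

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            if v != self.root:
                d[v] = d[self.parent[v]] + self.edge_length[v]
        return d

    def tip_depths(self) -> np.ndarray:
        return self.depths()[: self.n_tips]

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = self.tip_depths()
        span = d.max() - d.min()
        return bool(span <= rel_tol * max(d.max(), 1e-300))

    def node_ages(self) -> np.ndarray:
        """Ages (time before present) for all nodes; requires ultrametric tree."""
        if not self.is_ultrametric(rel_tol=1e-6):
            warnings.warn("node ages requested on a non-ultrametric tree")
        d = self.depths()
        return d[: self.n_tips].max() - d

    def mrca(self, labels) -> int:
        idx = [self.tip_labels.index(l) for l in labels]
        if not idx:
            raise TreeError("empty taxon set for MRCA")
        # climb ancestor sets
        anc = None
        for i in idx:
            path, v = set(), i
            while v >= 0:
                path.add(v)
                v = self.parent[v]
            anc = path if anc is None else anc & path
        depths = self.depths()
        return max(anc, key=lambda v: depths[v])

    def clade_tips(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if not self.children[u]:
                out.append(u)
            else:
                stack.extend(self.children[u])
        return out


def read_newick(path) -> PhyloTree:
    with open(path, "r", encoding="utf-8") as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Covariance and distances


@dataclass
class PhyloCovariance:
    """Phylogenetic covariance among tips under Pagel's lambda transform.

    ``C[i, j]`` is the shared root-to-MRCA path length between tips i and j,
    with off-diagonals multiplied by ``lam``; the diagonal holds root-to-tip
    depths. lambda = 1 is the untransformed (Brownian) structure, lambda = 0
    the star-equivalent diagonal.
    """

    C: np.ndarray
    tip_labels: list[str]
    lam: float = 1.0


def _mrca_depth_matrix(tree: PhyloTree) -> np.ndarray:
    n = tree.n_tips
    depths = tree.depths()
    C = np.zeros((n, n))
    np.fill_diagonal(C, depths[:n])
    for v in tree.postorder:
        kids = tree.children[v]
        if len(kids) < 2:
            continue
        tipsets = [tree.clade_tips(c) for c in kids]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ia = np.asarray(tipsets[a])
                ib = np.asarray(tipsets[b])
                C[np.ix_(ia, ib)] = depths[v]
                C[np.ix_(ib, ia)] = depths[v]
    return C


def cophenetic_distances(tree: PhyloTree) -> np.ndarray:
    """Pairwise tip-to-tip path-length matrix (branch-length sum)."""
    C = _mrca_depth_matrix(tree)
    d = np.diag(C)
    return d[:, None] + d[None, :] - 2 * C


def lambda_max(tree: PhyloTree, cap: float = 5.0) -> float:
    """Largest lambda keeping the transformed covariance positive semidefinite."""
    C = _mrca_depth_matrix(tree)
    D = np.diag(np.diag(C))
    off = C - D

    def psd(lam):
        return np.linalg.eigvalsh(D + lam * off)[0] >= -1e-10

    if not psd(1.0):
        # pathological (non-ultrametric) case: bisect down from 1
        lo, hi = 0.0, 1.0
    else:
        lo, hi = 1.0, cap
        if psd(cap):
            return cap
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if psd(mid):
            lo = mid
        else:
            hi = mid
    return lo


def phylo_covariance(tree: PhyloTree, lam: float = 1.0) -> PhyloCovariance:
    """Shared-path covariance matrix with Pagel's lambda scaling of off-diagonals."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if lam > 1.0:
        lmax = lambda_max(tree)
        if lam > lmax + 1e-9:
            raise ValueError(f"lambda {lam} exceeds the PSD bound {lmax:.4f} for this tree")
    if not tree.is_ultrametric(rel_tol=1e-6) and lam != 1.0:
        warnings.warn("lambda transform applied to a non-ultrametric tree")
    C = _mrca_depth_matrix(tree)
    D = np.diag(np.diag(C))
    return PhyloCovariance(C=lam * (C - D) + D, tip_labels=list(tree.tip_labels), lam=lam)


def simulate_bm(tree: PhyloTree, sigma2: float = 1.0, n_reps: int = 1,
                seed=None, lam: float = 1.0) -> np.ndarray:
    """Zero-mean Brownian-motion tip values, one column per replicate.

    Draws from N(0, sigma2 * C_lambda); used as the null engine for the
    phylogenetic ANOVA and for parameter-recovery simulations.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    C = phylo_covariance(tree, lam).C
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    Z = rng.standard_normal((tree.n_tips, n_reps))
    return np.sqrt(sigma2) * (L @ Z)


# ---------------------------------------------------------------------------
# Penalized-likelihood dating


def _initial_ages(tree: PhyloTree, root_age: float) -> np.ndarray:
    """Proportional-depth initial ages: scale each node's maximum distance
    to a descendant tip so the root sits at root_age and tips at 0."""
    h = np.zeros(tree.n_nodes)  # max distance to a tip below
    for v in tree.postorder:
        if tree.children[v]:
            h[v] = max(h[c] + tree.edge_length[c] for c in tree.children[v])
    scale = root_age / max(h[tree.root], 1e-12)
    return h * scale


def make_ultrametric(tree: PhyloTree, bounds=PPCA_CALIBRATION,
                     smoothing: float = 0.0, max_iter: int = 500) -> PhyloTree:
    """Date a tree to an ultrametric timescale by penalized likelihood.

    Each branch gets its own substitution rate; the observed branch length b
    given rate r over duration t contributes a Poisson-style term
    b*log(r*t) - r*t, and adjacent branches pay a roughness penalty
    ``smoothing * (r_child - r_parent)^2`` (no smoothing by default). Node
    ages are parameterized as fractions of the parent age so the returned
    tree is ultrametric by construction with ages strictly decreasing from
    root to tips; calibration bounds constrain the root age directly and any
    MRCA constraint through a quadratic penalty (verified after the fit).

    An already-ultrametric input whose root age satisfies every bound is
    returned unchanged.
    """
    bounds = tuple(bounds)
    if not bounds:
        raise ValueError("at least one calibration bound (the root) is required")
    root_bounds = [b for b in bounds if b.taxa is None]
    if len(root_bounds) != 1:
        raise ValueError("exactly one root bound is required")
    rb = root_bounds[0]
    mrca_bounds = [(tree.mrca(b.taxa), b) for b in bounds if b.taxa is not None]
    for node, b in mrca_bounds:
        if b.age_max > rb.age_max + 1e-12:
            raise TreeError("infeasible bounds: internal bound exceeds root maximum")

    # fixed point: already ultrametric and feasible
    if tree.is_ultrametric():
        ages = tree.node_ages()
        ok = rb.age_min - 1e-9 <= ages[tree.root] <= rb.age_max + 1e-9
        ok = ok and all(b.age_min - 1e-9 <= ages[v] <= b.age_max + 1e-9
                        for v, b in mrca_bounds)
        if ok:
            return tree.copy()

    if tree.edge_length.sum() <= 0:
        raise TreeError("tree has zero total length; cannot date")

    # perturb zero-length branches so the Poisson term stays informative
    depth = tree.tip_depths().max()
    blen = tree.edge_length.copy()
    nonroot = np.arange(tree.n_nodes) != tree.root
    tiny = blen[nonroot] <= 0
    if tiny.any():
        logger.info("perturbing %d zero-length branches before dating", tiny.sum())
        b2 = blen[nonroot]
        b2[tiny] = 1e-8 * depth
        blen[nonroot] = b2

    internals = [v for v in tree.preorder
                 if tree.children[v] and v != tree.root]
    n_int = len(internals)
    edges = np.where(nonroot)[0]
    epar = tree.parent[edges]

    root_free = rb.age_max - rb.age_min > 1e-12

    def ages_from(params):
        ages = np.zeros(tree.n_nodes)
        k = 0
        if root_free:
            ages[tree.root] = rb.age_min + (rb.age_max - rb.age_min) * expit(params[0])
            k = 1
        else:
            ages[tree.root] = rb.age_min
        for i, v in enumerate(internals):
            ages[v] = ages[tree.parent[v]] * expit(params[k + i])
        return ages, k + n_int

    def objective(params):
        ages, k = ages_from(params)
        rates = np.exp(params[k:])
        dur = ages[epar] - ages[edges]
        mu = rates * dur
        nll = -np.sum(blen[edges] * np.log(mu) - mu)
        if smoothing > 0:
            rate_of = dict(zip(edges.tolist(), rates.tolist()))
            pen = 0.0
            for e, p in zip(edges, epar):
                if p != tree.root and p in rate_of:
                    pen += (rate_of[e] - rate_of[p]) ** 2
            rkids = [rate_of[c] for c in tree.children[tree.root] if c in rate_of]
            if len(rkids) > 1:
                pen += float(np.var(rkids))
            nll += smoothing * pen
        for v, b in mrca_bounds:
            if ages[v] < b.age_min:
                nll += 1e8 * ((b.age_min - ages[v]) / rb.age_max) ** 2
            elif ages[v] > b.age_max:
                nll += 1e8 * ((ages[v] - b.age_max) / rb.age_max) ** 2
        return nll

    # initialization: proportional depths at the midpoint root age, global rate
    root0 = 0.5 * (rb.age_min + rb.age_max)
    ages0 = _initial_ages(tree, root0)
    x0 = []
    if root_free:
        x0.append(0.0)
    for v in internals:
        frac = ages0[v] / max(ages0[tree.parent[v]], 1e-12)
        x0.append(logit(np.clip(frac, 0.02, 0.98)))
    dur0 = np.maximum(ages0[epar] - ages0[edges], 1e-6 * root0)
    x0.extend(np.log(np.maximum(blen[edges] / dur0, 1e-10)))
    x0 = np.asarray(x0)

    res = minimize(objective, x0, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-12})
    if not np.isfinite(res.fun):
        raise TreeError(f"dating optimizer failed: {res.message}")
    ages, _ = ages_from(res.x)
    for v, b in mrca_bounds:
        if not (b.age_min - 1e-3 <= ages[v] <= b.age_max + 1e-3):
            raise TreeError(
                f"calibration constraint on node {v} not satisfied "
                f"(age {ages[v]:.4f} outside [{b.age_min}, {b.age_max}])")
    new_len = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        if v != tree.root:
            new_len[v] = ages[tree.parent[v]] - ages[v]
    return tree.copy(edge_length=new_len)
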