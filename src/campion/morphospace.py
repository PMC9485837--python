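"""Phylogenetic PCA of the encoded trait matrix, with a standard-PCA fallback.

The phylogenetic PCA estimates Pagel's lambda jointly over all traits under
a multivariate Brownian model, computes GLS (phylogenetic) trait means and
the evolutionary covariance

    P = (X - 1 a')' C_lambda^{-1} (X - 1 a') / (n - 1),

converts P to a correlation matrix, eigendecomposes it, and projects the
standardized, phylogenetically centered data onto the eigenvectors. On a
star phylogeny (or at lambda = 0 with equal tip depths) the procedure
reduces exactly to an ordinary correlation-matrix PCA. Group summaries
provide per-color mean scores and 95% normal ellipses in any two-component
plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .phylo import PhyloTree, lambda_max, phylo_covariance

__all__ = [
    "MorphospaceResult",
    "GroupEllipse",
    "phylogenetic_pca",
    "standard_pca",
    "trait_component_correlations",
    "group_summaries",
]


@dataclass
class MorphospaceResult:
    loadings: pd.DataFrame       # traits x components (eigenvectors)
    scores: pd.DataFrame         # species x components
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # proportions, sum to 1
    lam: float | None            # estimated Pagel's lambda (None for plain PCA)
    phylo_means: pd.Series       # GLS trait means (vector a)
    method: str                  # "pPCA" | "PCA"


@dataclass
class GroupEllipse:
    group: str
    center: np.ndarray           # 2-vector in the chosen component plane
    covariance: np.ndarray       # 2x2 score covariance
    confidence: float = 0.95

    @property
    def semi_axes(self) -> np.ndarray:
        w = np.linalg.eigvalsh(self.covariance)
        q = stats.chi2.ppf(self.confidence, df=2)
        return np.sqrt(np.clip(w, 0, None) * q)[::-1]

    def boundary(self, n: int = 200) -> np.ndarray:
        """Points on the ellipse boundary (n x 2), for plotting or coverage checks."""
        w, V = np.linalg.eigh(self.covariance)
        q = stats.chi2.ppf(self.confidence, df=2)
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        circ = np.stack([np.cos(theta), np.sin(theta)])
        return (self.center[:, None] + V @ (np.sqrt(np.clip(w, 0, None) * q)[:, None] * circ)).T

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(pts) - self.center
        cov = self.covariance + 1e-300 * np.eye(2)
        m = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
        return m <= stats.chi2.ppf(self.confidence, df=2)


def _check_matrix(X: pd.DataFrame):
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in traits {bad}; drop incomplete species first")
    const = X.columns[X.std(ddof=1) == 0].tolist()
    if const:
        raise ValueError(f"constant traits cannot enter a correlation-mode PCA: {const}")


def _mv_profile_loglik(X: np.ndarray, C: np.ndarray) -> float:
    """Profile log-likelihood of multivariate Brownian data X (n x p) on C."""
    n, p = X.shape
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    a = (Ci1 @ X) / (one @ Ci1)
    E = X - a
    CiE = cho_solve(cf, E)
    R = (E.T @ CiE) / n
    sign, logdetR = np.linalg.slogdet(R)
    if sign <= 0:
        return -np.inf
    logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return -0.5 * (n * p * np.log(2 * np.pi) + p * logdetC + n * logdetR + n * p)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude loading of each
    component is positive (ties broken by the first such row)."""
    W = V.copy()
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


def phylogenetic_pca(X: pd.DataFrame, tree: PhyloTree, lam: float | None = None) -> MorphospaceResult:
    """Correlation-mode phylogenetic PCA.

    ``lam`` fixes Pagel's lambda; by default it is estimated by joint ML
    over all traits. Species (rows of X) must match the tree's tips.
    """
    missing = set(tree.tip_labels) - set(X.index)
    if missing:
        raise ValueError(f"trait matrix missing tree tips: {sorted(missing)[:5]}")
    X = X.loc[tree.tip_labels]
    if X.shape[1] < 1:
        raise ValueError("need at least one trait")
    _check_matrix(X)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape

    C1 = phylo_covariance(tree, 1.0).C
    D = np.diag(np.diag(C1))
    off = C1 - D
    if lam is None:
        lmax = lambda_max(tree)

        def nll(l):
            return -_mv_profile_loglik(Xv, D + l * off)

        grid = np.linspace(0.0, lmax, 21)
        vals = [nll(l) for l in grid]
        i = int(np.argmin(vals))
        res = minimize_scalar(nll, bounds=(grid[max(i - 1, 0)], grid[min(i + 1, 20)]),
                              method="bounded", options={"xatol": 1e-8})
        lam = float(res.x) if res.fun <= vals[i] else float(grid[i])
    C = D + lam * off

    cf = cho_factor(C, lower=True)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    a = (Ci1 @ Xv) / (one @ Ci1)
    E = Xv - a
    P = (E.T @ cho_solve(cf, E)) / (n - 1)
    sd = np.sqrt(np.diag(P))
    Rmat = P / np.outer(sd, sd)
    eigvals, V = np.linalg.eigh(Rmat)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    V = _fix_signs(V[:, order])
    scores = (E / sd) @ V

    comps = [f"pPC{i+1}" for i in range(p)]
    return MorphospaceResult(
        loadings=pd.DataFrame(V, index=X.columns, columns=comps),
        scores=pd.DataFrame(scores, index=X.index, columns=comps),
        eigenvalues=eigvals,
        variance_explained=eigvals / eigvals.sum(),
        lam=lam,
        phylo_means=pd.Series(a, index=X.columns),
        method="pPCA",
    )


def standard_pca(X: pd.DataFrame) -> MorphospaceResult:
    """Ordinary PCA of the trait correlation matrix, same conventions."""
    _check_matrix(X)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    a = Xv.mean(axis=0)
    E = Xv - a
    P = E.T @ E / (n - 1)
    sd = np.sqrt(np.diag(P))
    Rmat = P / np.outer(sd, sd)
    eigvals, V = np.linalg.eigh(Rmat)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    V = _fix_signs(V[:, order])
    scores = (E / sd) @ V
    comps = [f"PC{i+1}" for i in range(p)]
    return MorphospaceResult(
        loadings=pd.DataFrame(V, index=X.columns, columns=comps),
        scores=pd.DataFrame(scores, index=X.index, columns=comps),
        eigenvalues=eigvals,
        variance_explained=eigvals / eigvals.sum(),
        lam=None,
        phylo_means=pd.Series(a, index=X.columns),
        method="PCA",
    )


def trait_component_correlations(result: MorphospaceResult, X: pd.DataFrame,
                                 tree: PhyloTree | None = None) -> pd.DataFrame:
    """GLS correlation of each original trait with each component's scores.

    Under the same C_lambda metric used for the ordination; with no tree (or
    lambda = 0 on an equal-depth tree) this is the ordinary Pearson
    correlation of trait values with scores.
    """
    X = X.loc[result.scores.index]
    Xv = X.to_numpy(dtype=float)
    S = result.scores.to_numpy()
    n = len(X)
    if tree is not None and result.lam is not None:
        C = phylo_covariance(tree, result.lam).C
        # reorder covariance to the score row order
        idx = [tree.tip_labels.index(s) for s in result.scores.index]
        C = C[np.ix_(idx, idx)]
    else:
        C = np.eye(n)
    cf = cho_factor(C, lower=True)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    denom = one @ Ci1

    def center(M):
        return M - (Ci1 @ M) / denom

    Ec, Sc = center(Xv), center(S)
    CiE = cho_solve(cf, Ec)
    cov_xs = Ec.T @ cho_solve(cf, Sc)
    var_x = np.sum(Ec * CiE, axis=0)
    var_s = np.sum(Sc * cho_solve(cf, Sc), axis=0)
    corr = cov_xs / np.sqrt(np.outer(var_x, var_s))
    return pd.DataFrame(np.clip(corr, -1, 1), index=X.columns,
                        columns=result.scores.columns)


def plot_morphospace(result: MorphospaceResult, colors: pd.Series,
                     ploidy: pd.Series | None = None,
                     components=("pPC1", "pPC2"), path=None):
    """Scatter of the component plane with group means (stars) and 95%
    ellipses, optionally marking ploidy by symbol; saves SVG if ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = list(components)
    S = result.scores[comps]
    colors = colors.loc[S.index]
    palette = {"white": "#bdbdbd", "pink": "#e377c2", "red": "#d62728"}
    markers = {"diploid": "^", "diploid/polyploid": "s", "polyploid": "o"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in pd.unique(colors):
        pts = S[colors == g]
        if ploidy is not None:
            for pl, mk in markers.items():
                sub = pts[ploidy.loc[pts.index] == pl]
                ax.scatter(sub[comps[0]], sub[comps[1]], marker=mk,
                           color=palette.get(g, "k"), edgecolor="k",
                           label=f"{g} ({pl})" if len(sub) else None)
        else:
            ax.scatter(pts[comps[0]], pts[comps[1]],
                       color=palette.get(g, "k"), edgecolor="k", label=g)
    means, ellipses = group_summaries(result, colors, components=comps)
    for g, e in ellipses.items():
        b = e.boundary()
        ax.plot(b[:, 0], b[:, 1], color=palette.get(g, "k"), lw=1.2)
    ax.scatter(means[comps[0]], means[comps[1]], marker="*", s=180,
               c=[palette.get(g, "k") for g in means.index], edgecolor="k",
               zorder=5)
    v = result.variance_explained
    idx0 = result.scores.columns.get_loc(comps[0])
    idx1 = result.scores.columns.get_loc(comps[1])
    ax.set_xlabel(f"{comps[0]} ({100 * v[idx0]:.1f}%)")
    ax.set_ylabel(f"{comps[1]} ({100 * v[idx1]:.1f}%)")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, format="svg")
        plt.close(fig)
    return fig, ax


def group_summaries(result: MorphospaceResult, colors: pd.Series,
                    components=("pPC1", "pPC2"), confidence: float = 0.95):
    """Per-group mean scores and 95% normal ellipses in a component plane.

    Groups with fewer than 3 members get a mean but no ellipse.
    """
    import warnings

    comps = list(components)
    S = result.scores[comps]
    colors = colors.loc[S.index]
    means, ellipses = {}, {}
    for g in pd.unique(colors):
        pts = S[colors == g].to_numpy()
        means[g] = pts.mean(axis=0)
        if len(pts) >= 3:
            cov = np.cov(pts.T)
            ellipses[g] = GroupEllipse(group=str(g), center=means[g],
                                       covariance=np.atleast_2d(cov),
                                       confidence=confidence)
        else:
            warnings.warn(f"group {g!r} has < 3 members; ellipse omitted")
    means = pd.DataFrame(means, index=comps).T
    return means, ellipses
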