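"""Phylogenetic signal, simulation-based phylogenetic ANOVA, and
Spearman/Holm correlation matrices.

Pagel's lambda is fit by profile maximum likelihood under a multivariate
normal model with covariance sigma^2 * C_lambda (mean and rate profiled out
by GLS) and tested against lambda = 0 with a 1-df likelihood ratio.
Blomberg's K compares the observed ratio of non-phylogenetic to phylogenetic
mean squared error against its Brownian-motion expectation on the tree; its
p-value permutes tip labels. The phylogenetic ANOVA keeps the ordinary
one-way F statistic but replaces its F-distribution null with Brownian
simulations on the tree at the GLS-estimated rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .phylo import PhyloTree, lambda_max, phylo_covariance, simulate_bm

__all__ = [
    "SignalResult",
    "PhylAnovaResult",
    "pagel_lambda",
    "blomberg_k",
    "phyl_anova",
    "spearman_holm",
    "holm_adjust",
]


@dataclass
class SignalResult:
    statistic: str
    estimate: float
    p_value: float
    log_likelihood: float | None = None
    lr_statistic: float | None = None
    n_permutations: int | None = None


@dataclass
class PhylAnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    posthoc: pd.DataFrame  # group_a, group_b, t, df, p_raw, p_holm
    n_sim: int


def _align(tree: PhyloTree, x) -> np.ndarray:
    """Order a tip-indexed vector/Series to the tree's tip order."""
    if isinstance(x, pd.Series):
        missing = set(tree.tip_labels) - set(x.index)
        if missing:
            raise ValueError(f"tip values missing for {sorted(missing)[:5]} ...")
        return x.loc[tree.tip_labels].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape[0] != tree.n_tips:
        raise ValueError("tip vector length does not match tree")
    return x


def _chol(C: np.ndarray):
    """Cholesky with a tiny scaled jitter retry (near-singular trees have
    nearly identical tips after short terminal branches)."""
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(C)))
        return cho_factor(C + jitter * np.eye(len(C)), lower=True)


def _gls_loglik(x: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood of x ~ N(mu*1, sigma2*C); returns (lnL, mu, sigma2)."""
    n = len(x)
    cf = _chol(C)
    Ci1 = cho_solve(cf, np.ones(n))
    mu = float(x @ Ci1 / Ci1.sum())
    e = x - mu
    Cie = cho_solve(cf, e)
    s2 = float(e @ Cie) / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    lnL = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return lnL, mu, s2


def pagel_lambda(tree: PhyloTree, x, tol: float = 1e-8) -> SignalResult:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs lambda=0."""
    x = _align(tree, x)
    if tree.n_tips < 4:
        raise ValueError("lambda estimation needs at least 4 tips")
    lmax = lambda_max(tree)
    C1 = phylo_covariance(tree, 1.0).C
    D = np.diag(np.diag(C1))
    off = C1 - D

    def nll(lam):
        C = D + lam * off
        try:
            return -_gls_loglik(x, C)[0]
        except np.linalg.LinAlgError:
            return np.inf

    # coarse grid + bounded refinement (profile can be multimodal near 0)
    grid = np.linspace(0.0, lmax, 21)
    vals = [nll(l) for l in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": tol})
    lam_hat, best = (float(res.x), float(res.fun))
    if vals[i] < best:  # keep the grid point if refinement did not help
        lam_hat, best = float(grid[i]), float(vals[i])
    lnL1 = -best
    lnL0 = -nll(0.0)
    lr = max(0.0, 2.0 * (lnL1 - lnL0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult("PagelLambda", lam_hat, p, log_likelihood=lnL1,
                        lr_statistic=lr)


def blomberg_k(tree: PhyloTree, x, n_perm: int = 1000, seed=None) -> SignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K = (MSE0/MSE) / E[MSE0/MSE], with MSE0 the mean squared deviation from
    the GLS grand mean, MSE the GLS error under the tree covariance, and the
    Brownian expectation (tr(C) - n / 1'C^-1 1) / (n - 1). Small GLS error
    relative to the permutation null indicates phylogenetic signal; p is the
    one-tailed proportion of permutations with MSE at most the observed
    (add-one rule).
    """
    x = _align(tree, x)
    n = len(x)
    if n < 4:
        raise ValueError("K needs at least 4 tips")
    C = phylo_covariance(tree, 1.0).C
    cf = _chol(C)
    Ci = cho_solve(cf, np.eye(n))
    w = Ci @ np.ones(n)
    sw = w.sum()
    expected = (np.trace(C) - n / sw) / (n - 1)

    def mses(xmat):
        # columns are candidate tip vectors
        mu = (w @ xmat) / sw
        e = xmat - mu
        mse0 = np.sum(e * e, axis=0) / (n - 1)
        mse = np.sum(e * (Ci @ e), axis=0) / (n - 1)
        return mse0, mse

    mse0, mse = mses(x[:, None])
    k = float((mse0[0] / mse[0]) / expected)

    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(x) for _ in range(n_perm)])
    _, mse_null = mses(perms)
    p = float((np.sum(mse_null <= mse[0]) + 1) / (n_perm + 1))
    return SignalResult("BlombergK", k, p, n_permutations=n_perm)


def _anova_f(x: np.ndarray, gidx: list[np.ndarray]):
    """One-way ANOVA F for columns of x (n x m) over the rows named in gidx."""
    used = np.concatenate(gidx)
    n = len(used)
    k = len(gidx)
    grand = x[used].mean(axis=0)
    ssb = np.zeros(x.shape[1])
    ssw = np.zeros_like(ssb)
    for idx in gidx:
        sub = x[idx]
        m = sub.mean(axis=0)
        ssb += len(idx) * (m - grand) ** 2
        ssw += np.sum((sub - m) ** 2, axis=0)
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    return F, dfb, dfw


def phyl_anova(tree: PhyloTree, x, groups, n_sim: int = 1000, seed=None,
               add_one: bool = False) -> PhylAnovaResult:
    """Phylogenetic ANOVA: ordinary F, Brownian-simulation null.

    The Brownian rate for the null is the GLS estimate sigma^2 from the
    observed data on the tree. Post-hoc pairwise t statistics (pooled MSE)
    use the same simulated null, with Holm correction across pairs. The
    p-value is the plain proportion of simulated statistics at least as
    large as the observed one (``add_one`` switches to the (count+1)/(n+1)
    rule).
    """
    x = _align(tree, x)
    g = pd.Series(groups)
    if set(tree.tip_labels) <= set(g.index):
        g = g.loc[tree.tip_labels]
    else:
        if len(g) != tree.n_tips:
            raise ValueError("groups must be indexed by tip label or match tip count")
        g = pd.Series(g.to_numpy(), index=tree.tip_labels)

    levels = [lv for lv in pd.unique(g) if (g == lv).sum() >= 2]
    dropped = set(pd.unique(g)) - set(levels)
    if dropped:
        import warnings
        warnings.warn(f"dropping groups with < 2 members: {sorted(map(str, dropped))}")
    if len(levels) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    gidx = [np.where(g.to_numpy() == lv)[0] for lv in levels]

    F_obs, dfb, dfw = _anova_f(x[:, None], gidx)
    F_obs = float(F_obs[0])

    C = phylo_covariance(tree, 1.0).C
    _, _, s2 = _gls_loglik(x, C)
    sims = simulate_bm(tree, sigma2=max(s2, 1e-300), n_reps=n_sim, seed=seed)
    F_null, _, _ = _anova_f(sims, gidx)
    exceed = int(np.sum(F_null >= F_obs))
    p = (exceed + 1) / (n_sim + 1) if add_one else exceed / n_sim

    # post-hoc pairwise t with simulation null
    def pair_t(mat):
        ssw = np.zeros(mat.shape[1])
        for idx in gidx:
            sub = mat[idx]
            ssw += np.sum((sub - sub.mean(axis=0)) ** 2, axis=0)
        msw = ssw / dfw
        ts = {}
        for a, b in itertools.combinations(range(len(levels)), 2):
            ia, ib = gidx[a], gidx[b]
            diff = mat[ia].mean(axis=0) - mat[ib].mean(axis=0)
            se = np.sqrt(msw * (1 / len(ia) + 1 / len(ib)))
            ts[(a, b)] = diff / se
        return ts

    t_obs = pair_t(x[:, None])
    t_null = pair_t(sims)
    rows = []
    for (a, b), tv in t_obs.items():
        tv = float(tv[0])
        null = np.abs(t_null[(a, b)])
        exceed = int(np.sum(null >= abs(tv)))
        praw = (exceed + 1) / (n_sim + 1) if add_one else exceed / n_sim
        rows.append({"group_a": levels[a], "group_b": levels[b],
                     "t": tv, "df": dfw, "p_raw": praw})
    posthoc = pd.DataFrame(rows)
    if len(posthoc):
        posthoc["p_holm"] = holm_adjust(posthoc["p_raw"].to_numpy())
    return PhylAnovaResult(F=F_obs, df_between=dfb, df_within=dfw,
                           p_value=float(p), posthoc=posthoc, n_sim=n_sim)


# ---------------------------------------------------------------------------
# Correlation matrices


def holm_adjust(p):
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="holm")[1]


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small n, with ties)."""
    n = len(xr)
    null = []
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(xr, yr[list(perm)])[0, 1]
        null.append(r)
    null = np.abs(np.asarray(null))
    return float(np.mean(null >= abs(rho) - 1e-12))


def spearman_holm(matrix: pd.DataFrame, exact_n_max: int = 7) -> pd.DataFrame:
    """Spearman correlations among trait columns with Holm-adjusted p-values.

    Average ranks for ties; pairwise-complete observations; a trait constant
    within the analyzed set yields an NA cell which is excluded from the
    Holm family. Exact permutation p-values are used for pairs with at most
    ``exact_n_max`` complete observations. Returns a tidy frame
    (trait_a, trait_b, rho, n, p_raw, p_holm, constant).
    """
    traits = list(matrix.columns)
    rows = []
    for a, b in itertools.combinations(traits, 2):
        sub = matrix[[a, b]].dropna()
        n = len(sub)
        xa, xb = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if n < 3 or np.ptp(xa) == 0 or np.ptp(xb) == 0:
            rows.append({"trait_a": a, "trait_b": b, "rho": np.nan, "n": n,
                         "p_raw": np.nan, "constant": True})
            continue
        xr = stats.rankdata(xa)
        yr = stats.rankdata(xb)
        rho = float(np.corrcoef(xr, yr)[0, 1])
        if n <= exact_n_max:
            p = _spearman_exact_p(xr, yr, rho)
        else:
            p = float(stats.spearmanr(xa, xb).pvalue)
        rows.append({"trait_a": a, "trait_b": b, "rho": rho, "n": n,
                     "p_raw": p, "constant": False})
    out = pd.DataFrame(rows)
    mask = ~out["constant"]
    out["p_holm"] = np.nan
    if mask.any():
        out.loc[mask, "p_holm"] = holm_adjust(out.loc[mask, "p_raw"].to_numpy())
    return out
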