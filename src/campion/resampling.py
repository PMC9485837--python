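"""Permutation tests on component scores and trait-range resampling.

Two statistics compare floral-color groups in morphospace: the ratio of
score variances var(A)/var(B) and the difference of score means. The null
distribution relabels the color assignment across all species (preserving
group sizes) and recomputes the statistic for the focal pair; significance
is the one-sided exceedance proportion in the configured direction (the
variance-ratio test for red defaults to "smaller than expected"). When the
number of distinct relabelings is small the null is enumerated exhaustively
instead of sampled.

The range-resampling loop replaces calyx height, calyx width and petal limb
length with independent Uniform(min, max) draws per species, reruns the
phylogenetic PCA per dataset, and aggregates per-color means and variances
of the leading components — a robustness check on using range medians.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from .morphospace import MorphospaceResult, phylogenetic_pca
from .phylo import PhyloTree
from .trait_data import TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationTestResult",
    "ResampleSummary",
    "permute_group_statistic",
    "all_pairwise_color_tests",
    "resample_trait_ranges",
    "resampled_ppca_summary",
    "RESAMPLED_TRAITS",
]

#: Continuous traits whose ranges are resampled; the other three continuous
#: traits and all categorical codes stay at their median/coded values.
RESAMPLED_TRAITS = ("calyx_height", "calyx_width", "petal_limb_length")

EXHAUSTIVE_LIMIT = 20_000


@dataclass
class PermutationTestResult:
    statistic: str               # "variance_ratio" | "mean_difference"
    observed: float
    null_distribution: np.ndarray
    p_value: float
    groups: tuple
    component: str | None
    n_perm: int
    sided: str
    exhaustive: bool
    seed: object = None


def _stat_fn(statistic: str):
    if statistic == "variance_ratio":
        def f(a, b):
            vb = b.var(ddof=1)
            if vb == 0:
                raise ZeroDivisionError("variance of the denominator group is zero")
            return a.var(ddof=1) / vb
    elif statistic == "mean_difference":
        def f(a, b):
            return a.mean() - b.mean()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return f


def _count_relabelings(labels: np.ndarray) -> int:
    total = math.factorial(len(labels))
    for c in np.unique(labels, return_counts=True)[1]:
        total //= math.factorial(int(c))
    return total


def permute_group_statistic(scores, colors, pair, statistic: str,
                            n_perm: int = 1000, sided: str | None = None,
                            seed=None, restrict_to_pair: bool = False,
                            add_one: bool = False,
                            component: str | None = None) -> PermutationTestResult:
    """One-sided permutation test of a two-group statistic on component scores.

    ``pair = (A, B)`` orders the statistic (var(A)/var(B), mean(A)-mean(B)).
    ``sided`` is "less" or "greater" and is never inferred from the data;
    the default is "less" for the variance ratio (testing reduced variance
    in A, the direction of the red-flower hypothesis) and "greater" on the
    absolute value for the mean difference. By default all species' color
    labels are shuffled jointly; ``restrict_to_pair`` shuffles only the two
    focal groups' labels (a documented deviation).
    """
    scores = pd.Series(scores) if not isinstance(scores, pd.Series) else scores
    colors = pd.Series(colors).loc[scores.index]
    a_name, b_name = pair
    for g in pair:
        if not (colors == g).any():
            raise ValueError(f"group {g!r} is empty")
    if statistic == "variance_ratio":
        for g in pair:
            if (colors == g).sum() < 2:
                raise ValueError(f"group {g!r} has < 2 members; variance undefined")
    use_abs = False
    if sided is None:
        if statistic == "variance_ratio":
            sided = "less"
        else:
            sided, use_abs = "greater", True
    if sided not in ("less", "greater"):
        raise ValueError("sided must be 'less' or 'greater'")

    if restrict_to_pair:
        mask = colors.isin(pair).to_numpy()
    else:
        mask = np.ones(len(colors), dtype=bool)
    vals = scores.to_numpy(dtype=float)[mask]
    labs = colors.to_numpy()[mask]

    fn = _stat_fn(statistic)

    def stat(labels, strict=False):
        try:
            s = fn(vals[labels == a_name], vals[labels == b_name])
        except ZeroDivisionError:
            if strict:
                raise
            return np.inf  # degenerate relabeling in the null: ratio blows up
        return abs(s) if use_abs else s

    observed = stat(labs, strict=True)

    n_distinct = _count_relabelings(labs)
    exhaustive = n_distinct <= EXHAUSTIVE_LIMIT
    if exhaustive:
        null = np.array([stat(np.asarray(p))
                         for p in multiset_permutations(list(labs))])
        n_eff = len(null)
    else:
        rng = np.random.default_rng(seed)
        null = np.array([stat(rng.permutation(labs)) for _ in range(n_perm)])
        n_eff = n_perm

    if sided == "greater":
        exceed = int(np.sum(null >= observed))
    else:
        exceed = int(np.sum(null <= observed))
    p = (exceed + 1) / (n_eff + 1) if add_one else exceed / n_eff
    return PermutationTestResult(
        statistic=statistic, observed=float(observed), null_distribution=null,
        p_value=float(p), groups=tuple(pair), component=component,
        n_perm=n_eff, sided=("abs-" if use_abs else "") + sided,
        exhaustive=exhaustive, seed=seed)


def all_pairwise_color_tests(result: MorphospaceResult, colors,
                             components=("pPC1", "pPC2"), n_perm: int = 1000,
                             seed=None, **kw) -> pd.DataFrame:
    """Every unordered color pair x component x statistic.

    Pairs involving red put red first, so the default one-sided variance
    test asks whether red variance is smaller than expected by chance.
    Returns a tidy table; the full null distributions are in
    ``df.attrs['results']`` keyed by (group_a, group_b, component, statistic).
    """
    colors = pd.Series(colors).loc[result.scores.index]
    levels = list(pd.unique(colors))
    for g in levels:
        if (colors == g).sum() < 2:
            raise ValueError(f"color group {g!r} has < 2 species")
    pairs = []
    for a, b in itertools.combinations(levels, 2):
        if b == "red" or (a != "red" and b < a):
            a, b = b, a
        pairs.append((a, b))
    rows, store = [], {}
    seeds = np.random.SeedSequence(seed).spawn(len(pairs) * len(components) * 2)
    si = 0
    for pair in pairs:
        for comp in components:
            for statistic in ("variance_ratio", "mean_difference"):
                res = permute_group_statistic(
                    result.scores[comp], colors, pair, statistic,
                    n_perm=n_perm, seed=seeds[si], component=comp, **kw)
                si += 1
                rows.append({
                    "group_a": pair[0], "group_b": pair[1], "component": comp,
                    "statistic": statistic, "observed": res.observed,
                    "p_value": res.p_value, "sided": res.sided,
                    "n_perm": res.n_perm, "exhaustive": res.exhaustive,
                })
                store[(pair[0], pair[1], comp, statistic)] = res
    out = pd.DataFrame(rows)
    out.attrs["results"] = store
    return out


def resample_trait_ranges(table: TraitTable, traits=RESAMPLED_TRAITS,
                          n_datasets: int = 1000, seed=None):
    """Yield encoded trait matrices with the named traits drawn
    Uniform(min, max) per species; all other columns untouched."""
    rng = np.random.default_rng(seed)
    base = table.encoded_matrix()
    bounds = {t: table.ranges(t) for t in traits}
    for t in traits:
        if bounds[t][["min", "max"]].isna().any().any():
            raise ValueError(f"missing range for trait {t!r}")
    for _ in range(n_datasets):
        X = base.copy()
        for t in traits:
            lo = bounds[t]["min"].to_numpy()
            hi = bounds[t]["max"].to_numpy()
            X[t] = lo + (hi - lo) * rng.random(len(lo))
        yield X


@dataclass
class ResampleSummary:
    """Across-dataset distributions of per-color group mean and variance of
    the leading components over re-sampled phylogenetic PCAs."""

    per_dataset: pd.DataFrame  # dataset, group, component, mean, variance
    summary: pd.DataFrame      # group, component, stat, mean, variance, q05..q95
    n_datasets: int
    n_failed: int


def resampled_ppca_summary(table: TraitTable, tree: PhyloTree, colors=None,
                           components=("pPC1", "pPC2"), n_datasets: int = 1000,
                           seed=None, max_failure_rate: float = 0.05) -> ResampleSummary:
    """Rerun the phylogenetic PCA on range-resampled datasets and aggregate
    per-color group means and variances of the leading components."""
    colors = table.colors if colors is None else pd.Series(colors)
    rows = []
    n_failed = 0
    for d, X in enumerate(resample_trait_ranges(table, n_datasets=n_datasets, seed=seed)):
        try:
            res = phylogenetic_pca(X.loc[tree.tip_labels], tree)
        except Exception as exc:  # individual dataset failure: log and skip
            n_failed += 1
            logger.warning("resampled dataset %d failed: %s", d, exc)
            if n_failed > max_failure_rate * n_datasets:
                raise RuntimeError(
                    f"more than {max_failure_rate:.0%} of resampled pPCA runs failed")
            continue
        cg = colors.loc[res.scores.index]
        for g in pd.unique(cg):
            pts = res.scores.loc[cg == g, list(components)]
            for comp in components:
                rows.append({
                    "dataset": d, "group": g, "component": comp,
                    "mean": float(pts[comp].mean()),
                    "variance": float(pts[comp].var(ddof=1)),
                })
    per_dataset = pd.DataFrame(rows)
    agg = []
    for (g, comp), sub in per_dataset.groupby(["group", "component"]):
        for stat in ("mean", "variance"):
            x = sub[stat].to_numpy()
            agg.append({
                "group": g, "component": comp, "stat": stat,
                "mean": float(x.mean()), "variance": float(x.var(ddof=1)) if len(x) > 1 else 0.0,
                "q05": float(np.quantile(x, 0.05)),
                "q50": float(np.quantile(x, 0.50)),
                "q95": float(np.quantile(x, 0.95)),
            })
    return ResampleSummary(per_dataset=per_dataset, summary=pd.DataFrame(agg),
                           n_datasets=n_datasets, n_failed=n_failed)
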