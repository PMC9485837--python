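"""Discrete floral-color evolution on a phylogeny.

Implements the Mk (continuous-time Markov chain) likelihood by Felsenstein
pruning, a seven-model constraint set over the states white/pink/red —
equal rates (ER), symmetric (SYM), all-rates-different (ARD), and four
stepwise variants on the ordered chain white <-> pink <-> red in which the
direct white <-> red jump is forbidden — AIC-based model comparison,
marginal ancestral-state reconstruction, and stochastic character mapping
with endpoint-conditioned branch paths sampled by uniformization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .phylo import PhyloTree

__all__ = [
    "MkModel",
    "FittedMk",
    "AsrResult",
    "SimmapResult",
    "build_model_set",
    "mk_loglik",
    "fit_mk",
    "compare_models",
    "marginal_asr",
    "stochastic_map",
]

COLOR_STATES = ("white", "pink", "red")


@dataclass(frozen=True)
class MkModel:
    """Rate-constraint scheme for a k-state Mk model.

    ``index`` is a k x k integer matrix: entry (i, j) names the shared rate
    parameter (1-based) governing the i -> j transition, with 0 meaning the
    transition is forbidden (rate exactly zero). Diagonal entries are
    ignored; the generator's diagonal is set to minus the row sum.
    """

    name: str
    index: tuple
    states: tuple = COLOR_STATES
    root_prior: str = "equal"  # "equal" | "stationary"

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def n_free(self) -> int:
        idx = np.asarray(self.index)
        return int(idx[~np.eye(self.k, dtype=bool)].max())

    def Q(self, rates) -> np.ndarray:
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (self.n_free,):
            raise ValueError(f"{self.name}: expected {self.n_free} rates, got {rates.shape}")
        if np.any(rates < 0):
            raise ValueError("rates must be nonnegative")
        idx = np.asarray(self.index)
        Q = np.zeros((self.k, self.k))
        off = ~np.eye(self.k, dtype=bool)
        Q[off & (idx > 0)] = rates[idx[off & (idx > 0)] - 1]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def prior(self, rates=None) -> np.ndarray:
        if self.root_prior == "equal":
            return np.full(self.k, 1.0 / self.k)
        if self.root_prior == "stationary":
            Q = self.Q(rates)
            A = np.vstack([Q.T, np.ones(self.k)])
            b = np.zeros(self.k + 1)
            b[-1] = 1.0
            pi, *_ = np.linalg.lstsq(A, b, rcond=None)
            return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()
        raise ValueError(f"unknown root prior {self.root_prior!r}")


def build_model_set(root_prior: str = "equal") -> list[MkModel]:
    """The seven-model floral-color set (states ordered white, pink, red).

    The four stepwise models share the chain topology (white <-> pink <->
    red, no direct white <-> red): fully reversible (4 free rates);
    pink-red irreversible (red cannot revert to pink, 3); red-white
    irreversible (pink cannot revert to white, so whiteness is unrecoverable
    on the path toward red, 3); and both irreversibilities combined (a
    strictly directional chain white -> pink -> red, 2).
    """
    kw = {"root_prior": root_prior}
    return [
        MkModel("ER", ((0, 1, 1), (1, 0, 1), (1, 1, 0)), **kw),
        MkModel("SYM", ((0, 1, 2), (1, 0, 3), (2, 3, 0)), **kw),
        MkModel("ARD", ((0, 1, 2), (3, 0, 4), (5, 6, 0)), **kw),
        MkModel("stepwise_reversible", ((0, 1, 0), (2, 0, 3), (0, 4, 0)), **kw),
        MkModel("stepwise_pink_red_irrev", ((0, 1, 0), (2, 0, 3), (0, 0, 0)), **kw),
        MkModel("stepwise_red_white_irrev", ((0, 1, 0), (0, 0, 2), (0, 3, 0)), **kw),
        MkModel("stepwise_red_pink_red_white_irrev",
                ((0, 1, 0), (0, 0, 2), (0, 0, 0)), **kw),
    ]


def _transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t) via eigendecomposition with an expm fallback; rows renormalized."""
    if t == 0:
        return np.eye(len(Q))
    try:
        w, U = np.linalg.eig(Q)
        Ui = np.linalg.inv(U)
        if np.linalg.cond(U) < 1e10:
            P = (U * np.exp(w * t)) @ Ui
            P = np.real(P)
        else:
            P = expm(Q * t)
    except np.linalg.LinAlgError:
        P = expm(Q * t)
    P = np.clip(P, 0.0, None)
    rs = P.sum(axis=1, keepdims=True)
    return P / np.where(rs > 0, rs, 1.0)


def _tip_states(tree: PhyloTree, tips, states) -> np.ndarray:
    if isinstance(tips, pd.Series):
        tips = tips.to_dict()
    if isinstance(tips, dict):
        missing = set(tree.tip_labels) - set(tips)
        if missing:
            raise ValueError(f"tip states missing for {sorted(missing)[:5]}")
        seq = [tips[l] for l in tree.tip_labels]
    else:
        seq = list(tips)
        if len(seq) != tree.n_tips:
            raise ValueError("tip state vector length mismatch")
    lookup = {s: i for i, s in enumerate(states)}
    try:
        return np.asarray([lookup[s] for s in seq], dtype=int)
    except KeyError as exc:
        raise ValueError(f"tip state {exc} not in model alphabet {states}") from exc


def _branch_matrices(tree: PhyloTree, Q: np.ndarray) -> list:
    P = [None] * tree.n_nodes
    cache: dict[float, np.ndarray] = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        t = float(tree.edge_length[v])
        if t not in cache:
            cache[t] = _transition_matrix(Q, t)
        P[v] = cache[t]
    return P


def _down_partials(tree: PhyloTree, code: np.ndarray, P: list, k: int):
    """Scaled conditional likelihoods of each subtree; returns (L, log_scale)."""
    L = np.zeros((tree.n_nodes, k))
    log_scale = 0.0
    for v in tree.postorder:
        if not tree.children[v]:
            L[v, code[v]] = 1.0
            continue
        vec = np.ones(k)
        for c in tree.children[v]:
            vec = vec * (P[c] @ L[c])
        s = vec.sum()
        if s <= 0 or not np.isfinite(s):
            raise FloatingPointError(
                f"non-finite Mk likelihood at node {v} (branch lengths "
                f"{[tree.edge_length[c] for c in tree.children[v]]})")
        L[v] = vec / s
        log_scale += np.log(s)
    return L, log_scale


def mk_loglik(tree: PhyloTree, tips, model: MkModel, rates) -> float:
    """Log-likelihood of tip states by Felsenstein pruning."""
    code = _tip_states(tree, tips, model.states)
    Q = model.Q(rates)
    P = _branch_matrices(tree, Q)
    L, log_scale = _down_partials(tree, code, P, model.k)
    prior = model.prior(rates)
    return float(np.log(prior @ L[tree.root]) + log_scale)


@dataclass
class FittedMk:
    model: MkModel
    rates: np.ndarray
    log_likelihood: float
    aic: float

    @property
    def k(self) -> int:
        return self.model.n_free


def fit_mk(tree: PhyloTree, tips, model: MkModel,
           n_starts: int = 4, rate_floor: float = 1e-8) -> FittedMk:
    """Maximize the Mk likelihood over log-parameterized rates (multi-start)."""
    code = _tip_states(tree, tips, model.states)
    height = float(tree.tip_depths().max())
    m = model.n_free

    def nll(log_rates):
        try:
            return -mk_loglik(tree, tips, model, np.exp(log_rates))
        except FloatingPointError:
            return np.inf

    scales = np.geomspace(0.05, 20.0, n_starts) / max(height, 1e-12)
    best = None
    # ceiling of 100 expected changes per tree height: beyond this the
    # likelihood is flat (tips are effectively iid draws from the prior)
    bounds = [(np.log(rate_floor), np.log(1e2 / max(height, 1e-12)))] * m
    for s in scales:
        x0 = np.full(m, np.log(s))
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"Mk optimization failed for model {model.name}")
    rates = np.exp(best.x)
    lnL = -float(best.fun)
    return FittedMk(model=model, rates=rates, log_likelihood=lnL,
                    aic=2.0 * m - 2.0 * lnL)


def compare_models(tree: PhyloTree, tips, models=None, **kw) -> pd.DataFrame:
    """Fit a model set and tabulate lnL / k / AIC / dAIC, best first.

    Models within two AIC units of the best are flagged ``retained``.
    """
    if models is None:
        models = build_model_set()
    fits = [fit_mk(tree, tips, m, **kw) for m in models]
    df = pd.DataFrame({
        "model": [f.model.name for f in fits],
        "k": [f.k for f in fits],
        "log_likelihood": [f.log_likelihood for f in fits],
        "aic": [f.aic for f in fits],
    })
    df = df.sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["retained"] = df["delta_aic"] < 2.0
    df.attrs["fits"] = {f.model.name: f for f in fits}
    return df


@dataclass
class AsrResult:
    """Marginal state probabilities at every internal node."""

    node_probs: pd.DataFrame  # index: node id, columns: states
    log_likelihood: float
    aic: float
    states: tuple


def marginal_asr(tree: PhyloTree, tips, fit: FittedMk) -> AsrResult:
    """Marginal ancestral states by the up-down (rerooting-equivalent) pass.

    For each node the subtree-conditional likelihoods are combined with the
    likelihood of the rest of the tree given the node's state; each node
    vector is normalized to sum to one.
    """
    model = fit.model
    code = _tip_states(tree, tips, model.states)
    Q = model.Q(fit.rates)
    P = _branch_matrices(tree, Q)
    L, log_scale = _down_partials(tree, code, P, model.k)
    prior = model.prior(fit.rates)

    U = np.zeros((tree.n_nodes, model.k))
    U[tree.root] = prior
    for v in tree.preorder:
        kids = tree.children[v]
        if not kids:
            continue
        msgs = {c: P[c] @ L[c] for c in kids}
        for c in kids:
            rest = U[v].copy()
            for s in kids:
                if s != c:
                    rest = rest * msgs[s]
            u = rest @ P[c]
            tot = u.sum()
            U[c] = u / tot if tot > 0 else u
    post = L * U
    post /= post.sum(axis=1, keepdims=True)
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    probs = pd.DataFrame(post[internal], index=internal, columns=list(model.states))
    return AsrResult(node_probs=probs, log_likelihood=fit.log_likelihood,
                     aic=fit.aic, states=model.states)


# ---------------------------------------------------------------------------
# Stochastic character mapping


@dataclass
class SimmapResult:
    node_frequencies: pd.DataFrame   # internal node id x states
    transition_counts: pd.DataFrame  # one row per simulation, ordered-pair columns
    n_sims: int
    states: tuple
    histories: list | None = None    # per sim: {node: [(state, duration), ...]}

    def mean_counts(self) -> pd.Series:
        return self.transition_counts.mean(axis=0)


def _sample_path(rng, Q, mu, R, Rpow, P_t, i, j, t, max_n=500):
    """Endpoint-conditioned CTMC path on one branch via uniformization.

    Returns the piecewise history [(state, duration), ...] from the parent
    (state i) to the child (state j) over total time t.
    """
    if P_t[i, j] <= 0:
        raise RuntimeError("impossible endpoint pair in stochastic map")
    # weights w_n ∝ Poisson(mu t; n) * [R^n]_{ij}. Normalizing by the
    # accumulated series (not the matrix exponential) keeps the sampler
    # exact under truncation; dropping the constant e^{-mu t} and rescaling
    # the running term dodges under/overflow at large mu*t.
    term = 1.0            # (mu t)^n / n!, up to the running scale
    scale_shift = 0       # number of 1e100 rescalings applied to `term`
    weights, scales = [1.0 if i == j else 0.0], [0]
    n = 0
    tail_target = mu * t + 10.0 * np.sqrt(mu * t) + 20.0
    while n < max_n:
        n += 1
        if len(Rpow) <= n:
            Rpow.append(Rpow[-1] @ R)
        term *= mu * t / n
        if term > 1e100:
            term *= 1e-100
            scale_shift += 1
        weights.append(term * Rpow[n][i, j])
        scales.append(scale_shift)
        if n > tail_target:
            break
    top = max(scales)
    w = np.asarray([wv * (1e-100 ** (top - s)) for wv, s in zip(weights, scales)])
    total = w.sum()
    if total <= 0:
        raise RuntimeError("endpoint-conditioned path has no support; "
                           "branch/rate combination is numerically degenerate")
    n = int(rng.choice(len(w), p=w / total))
    if n == 0:
        return [(i, t)]
    # intermediate states, backward-filtered forward sampling
    states = [i]
    for step in range(1, n):
        prev = states[-1]
        w = R[prev, :] * Rpow[n - step][:, j]
        w = np.clip(w, 0, None)
        s = w.sum()
        states.append(int(rng.choice(len(w), p=w / s)))
    states.append(j)
    times = np.sort(rng.random(n) * t)
    # collapse virtual (self) jumps into dwell segments
    segs = []
    cur, t0 = states[0], 0.0
    for st, tt in zip(states[1:], times):
        if st != cur:
            segs.append((cur, tt - t0))
            cur, t0 = st, tt
    segs.append((cur, t - t0))
    return segs


def stochastic_map(tree: PhyloTree, tips, fit: FittedMk, n_sims: int = 1000,
                   seed=None, root_prior=None, keep_histories: bool = False) -> SimmapResult:
    """Sample complete character histories conditioned on the tip states.

    The root state is drawn from (prior x root conditional likelihood),
    node states descend conditioned on the parent state and each subtree's
    partial likelihoods, and each branch path is simulated by uniformization
    conditioned on its endpoint states. Summaries report per-node state
    frequencies across simulations and the posterior distribution of
    transition counts for every ordered state pair.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    model = fit.model
    k = model.k
    code = _tip_states(tree, tips, model.states)
    Q = model.Q(fit.rates)
    P = _branch_matrices(tree, Q)
    L, _ = _down_partials(tree, code, P, k)
    prior = np.asarray(root_prior, dtype=float) if root_prior is not None \
        else model.prior(fit.rates)
    prior = prior / prior.sum()

    rng = np.random.default_rng(seed)
    mu = 1.05 * max(np.max(-np.diag(Q)), 0.0) + 1e-12
    R = np.eye(k) + Q / mu
    Rpow = [np.eye(k)]

    pairs = [(a, b) for a, b in itertools.product(range(k), repeat=2) if a != b]
    pair_idx = {ab: i for i, ab in enumerate(pairs)}
    pair_names = [f"{model.states[a]}->{model.states[b]}" for a, b in pairs]
    counts = np.zeros((n_sims, len(pairs)), dtype=int)
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    freq = np.zeros((tree.n_nodes, k))
    histories = [] if keep_histories else None

    root_w = prior * L[tree.root]
    root_w = root_w / root_w.sum()

    for s in range(n_sims):
        node_state = np.empty(tree.n_nodes, dtype=int)
        node_state[tree.root] = rng.choice(k, p=root_w)
        hist = {} if keep_histories else None
        for v in tree.preorder:
            for c in tree.children[v]:
                w = P[c][node_state[v], :] * L[c]
                tot = w.sum()
                node_state[c] = rng.choice(k, p=w / tot)
                segs = _sample_path(rng, Q, mu, R, Rpow, P[c],
                                    node_state[v], node_state[c],
                                    float(tree.edge_length[c]))
                for (a, _), (b, _2) in zip(segs[:-1], segs[1:]):
                    counts[s, pair_idx[(a, b)]] += 1
                if keep_histories:
                    hist[c] = segs
        for v in internal:
            freq[v, node_state[v]] += 1
        if keep_histories:
            histories.append(hist)

    node_freq = pd.DataFrame(freq[internal] / n_sims, index=internal,
                             columns=list(model.states))
    count_df = pd.DataFrame(counts, columns=pair_names)
    return SimmapResult(node_frequencies=node_freq, transition_counts=count_df,
                        n_sims=n_sims, states=model.states, histories=histories)


def history_to_simmap_newick(tree: PhyloTree, history: dict, states) -> str:
    """Serialize one sampled history in the simmap-annotated newick dialect
    ({state,time:state,time:...} per branch, child-to-parent order reversed
    to the conventional tipward listing)."""

    def seg_string(v):
        segs = history[v]
        inner = ":".join(f"{states[s]},{d:.8g}" for s, d in segs)
        return "{" + inner + "}"

    def rec(v):
        if not tree.children[v]:
            s = tree.tip_labels[v]
        else:
            s = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        if v != tree.root:
            s += ":" + seg_string(v)
        return s

    return rec(tree.root) + ";"
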