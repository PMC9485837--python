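"""Synthetic study generator: trees, trait tables, colors, occurrence clouds.

Emulates the structure of the empirical study — about 47 species scored for
six continuous trait ranges, three ordinal traits, a three-state floral
color (20 white / 18 pink / 9 red) and ploidy; a 43-tip ultrametric
gene-tree (a handful of species lack sequences); and per-species occurrence
point clouds whose pairwise range overlap is planted — with known ground
truth so every pipeline stage can be tested without downloads.

Continuous trait medians evolve by correlated Brownian motion on the tree
under a chosen Pagel's lambda; ordinal traits threshold latent Brownian
variables so their phylogenetic signal is controllable; the red-group
variance contrast pulls red species' traits toward the red centroid by a
shrink factor (1 = null, smaller = stronger convergence). Occurrence clouds
are truncated Gaussian scatters around cluster-anchored range centers:
members of one geographic cluster are guaranteed sympatric after buffering,
members of different clusters guaranteed allopatric.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import OccurrenceSet
from .phylo import PhyloTree
from .trait_data import (CATEGORICAL_TRAITS, CONTINUOUS_TRAITS, SpeciesRecord,
                         TraitRange, TraitTable)

__all__ = [
    "SyntheticScenario",
    "simulate_tree",
    "simulate_traits",
    "simulate_colors_mk",
    "simulate_occurrences",
    "simulate_study",
]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study; every generator is a pure function
    of (scenario, seed offsets derived from scenario.seed)."""

    seed: int = 0
    n_species: int = 47
    n_tree_tips: int = 43
    birth_rate: float = 1.0          # Yule speciation rate (1/Myr)
    root_age: float = 20.0           # Myr, matches the calibrated-root scale
    lam: float = 1.0                 # Pagel's lambda of the trait model
    half_width: float = 0.25         # trait range half-width as fraction of |median|
    red_shrink: float = 0.3          # red-group contrast (1 = no effect)
    color_counts: tuple = (20, 18, 9)   # white, pink, red
    # occurrence model
    n_clusters: int = 6
    points_per_species: int = 40
    spread_km: float = 80.0          # scatter SD, truncated at 3 SD
    cluster_separation_km: float = 2500.0
    within_cluster_offset_km: float = 8.0

    #: per-trait (mean, among-species SD) targets on the study's scale
    trait_scale: dict = field(default_factory=lambda: {
        "stem_length": (250.0, 200.0),
        "leaves_per_node": (2.1, 1.3),
        "leaf_length": (42.0, 28.0),
        "calyx_height": (14.0, 6.0),
        "calyx_width": (5.4, 2.2),
        "petal_limb_length": (7.0, 7.0),
    })

    def species_ids(self) -> list[str]:
        return [f"sp{i:02d}" for i in range(1, self.n_species + 1)]

    def subseed(self, k: int) -> int:
        return int(np.random.SeedSequence([self.seed, k]).generate_state(1)[0] % (2**31))


def simulate_tree(scenario: SyntheticScenario, rescale: bool = True) -> PhyloTree:
    """Forward Yule (pure-birth) tree conditioned on the tip count.

    Lineages split at rate ``birth_rate`` each; the simulation runs until
    the target tip count and then one further exponential waiting time, so
    every pendant branch has positive length. The tree is ultrametric by
    construction and, with ``rescale``, scaled so the root sits at
    ``root_age``. Tips are labeled with ``n_tree_tips`` species ids after a
    seeded shuffle — the remaining species emulate taxa without sequences.
    """
    if scenario.n_species < 3 or scenario.n_tree_tips < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(scenario.subseed(1))
    b = scenario.birth_rate
    birth_time = {0: 0.0}
    children: dict[int, list[int]] = {}
    active = [0]
    nxt = 1
    t = 0.0
    while len(active) < scenario.n_tree_tips:
        t += rng.exponential(1.0 / (len(active) * b))
        i = active.pop(int(rng.integers(len(active))))
        kids = [nxt, nxt + 1]
        nxt += 2
        children[i] = kids
        for c in kids:
            birth_time[c] = t
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / (len(active) * b))

    tips = sorted(active)
    internals = sorted(children)
    index = {v: i for i, v in enumerate(tips)}
    index.update({v: len(tips) + j for j, v in enumerate(internals)})
    n = len(tips) + len(internals)
    parent = np.full(n, -1, dtype=int)
    elen = np.zeros(n)
    split_time = {v: birth_time[children[v][0]] for v in internals}
    for v, kids in children.items():
        for c in kids:
            parent[index[c]] = index[v]
            end = split_time[c] if c in children else t_end
            elen[index[c]] = end - birth_time[c]

    ids = scenario.species_ids()
    shuffler = random.Random(scenario.subseed(2))
    shuffled = ids.copy()
    shuffler.shuffle(shuffled)
    labels = sorted(shuffled[: scenario.n_tree_tips])
    tree = PhyloTree(parent, elen, labels)
    if rescale:
        depth = tree.tip_depths().max()
        tree = tree.copy(edge_length=tree.edge_length * (scenario.root_age / depth))
    return tree


#: ordinal level frequencies the latent thresholds aim for (all-species rates)
_LEVEL_FREQS = {
    "inflorescence_class": (0.23, 0.55, 0.22),
    "tube_extension": (0.17, 0.57, 0.26),
    "organ_exsertion": (0.11, 0.26, 0.19, 0.44),
}

#: modest positive correlation among the flower-size traits
_SIZE_TRAITS = ("calyx_height", "calyx_width", "petal_limb_length")


def _trait_correlation() -> np.ndarray:
    traits = list(CONTINUOUS_TRAITS)
    R = np.eye(len(traits))
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if i != j and a in _SIZE_TRAITS and b in _SIZE_TRAITS:
                R[i, j] = 0.4
    return R


def simulate_traits(scenario: SyntheticScenario, tree: PhyloTree,
                    colors: pd.Series | None = None) -> TraitTable:
    """Trait table with correlated-BM continuous medians, latent-threshold
    ordinals, planted colors, and the red-group variance contrast."""
    from .phylo import phylo_covariance

    rng = np.random.default_rng(scenario.subseed(3))
    ids = scenario.species_ids()
    on_tree = [s for s in ids if s in tree.tip_labels]
    off_tree = [s for s in ids if s not in tree.tip_labels]

    traits = list(CONTINUOUS_TRAITS)
    p = len(traits)
    R = _trait_correlation()
    LR = np.linalg.cholesky(R)

    # unit-variance phylogenetic deviations for tree species, iid for the rest
    C = phylo_covariance(tree, scenario.lam).C
    Cn = C / tree.tip_depths().max()
    LC = np.linalg.cholesky(Cn + 1e-10 * np.eye(len(Cn)))
    n_latent = p + len(CATEGORICAL_TRAITS)
    Z_tree = LC @ rng.standard_normal((len(on_tree), n_latent))
    Z_off = rng.standard_normal((len(off_tree), n_latent))
    order = on_tree + off_tree
    Z = np.vstack([Z_tree, Z_off])

    # continuous block gets the among-trait correlation
    Zc = Z[:, :p] @ LR.T
    means = np.array([scenario.trait_scale[t][0] for t in traits])
    sds = np.array([scenario.trait_scale[t][1] for t in traits])
    X = means + Zc * sds

    if colors is None:
        nw, npk, nr = scenario.color_counts
        if nw + npk + nr != scenario.n_species:
            raise ValueError("color counts must sum to n_species")
        pool = ["white"] * nw + ["pink"] * npk + ["red"] * nr
        shuffler = random.Random(scenario.subseed(4))
        shuffler.shuffle(pool)
        colors = pd.Series(pool, index=ids)
    colors = colors.loc[ids]

    # red-group convergence: shrink toward the red centroid
    latents = Z[:, p:]
    red_mask = (colors.loc[order] == "red").to_numpy()
    if red_mask.sum() >= 2 and scenario.red_shrink != 1.0:
        cx = X[red_mask].mean(axis=0)
        X[red_mask] = cx + scenario.red_shrink * (X[red_mask] - cx)
        cl = latents[red_mask].mean(axis=0)
        latents[red_mask] = cl + scenario.red_shrink * (latents[red_mask] - cl)

    # floor continuous traits away from zero (traits are physical sizes)
    X = np.maximum(X, 0.05 * means)

    # ordinal traits by empirical-quantile thresholding of the latents
    cat_levels = {}
    for k, (trait, levels) in enumerate(CATEGORICAL_TRAITS.items()):
        freqs = np.asarray(_LEVEL_FREQS[trait])
        cuts = np.quantile(latents[:, k], np.cumsum(freqs)[:-1])
        idx = np.searchsorted(cuts, latents[:, k], side="right")
        cat_levels[trait] = [levels[i] for i in idx]

    ploidy_rng = random.Random(scenario.subseed(5))
    records = []
    hw = scenario.half_width
    for i, sid in enumerate(order):
        tr = {}
        for j, t in enumerate(traits):
            med = float(X[i, j])
            lo = max(0.0, med - hw * abs(med))
            hi = med + hw * abs(med)
            tr[t] = TraitRange(lo, med, hi)
        color = colors[sid]
        if color == "red":
            ploidy = "polyploid"  # every red species in the study is polyploid
        else:
            u = ploidy_rng.random()
            ploidy = "diploid" if u < 0.10 else ("diploid/polyploid" if u < 0.15 else "polyploid")
        records.append(SpeciesRecord(
            species_id=sid, traits=tr,
            inflorescence_class=cat_levels["inflorescence_class"][i],
            tube_extension=cat_levels["tube_extension"][i],
            organ_exsertion=cat_levels["organ_exsertion"][i],
            color=color, ploidy=ploidy,
        ))
    records.sort(key=lambda r: r.species_id)
    return TraitTable(records=records)


def simulate_colors_mk(tree: PhyloTree, Q: np.ndarray, seed=None,
                       states=("white", "pink", "red"), root_state=None):
    """Simulate the color CTMC down the tree; returns (tips, truth).

    ``truth`` holds the true node states and the true per-type transition
    counts of the full history.
    """
    rng = np.random.default_rng(seed)
    Q = np.asarray(Q, dtype=float)
    k = len(states)
    node_state = np.empty(tree.n_nodes, dtype=int)
    node_state[tree.root] = (rng.integers(k) if root_state is None
                             else list(states).index(root_state))
    counts = {f"{a}->{b}": 0 for a in states for b in states if a != b}
    dwell = dict.fromkeys(states, 0.0)
    for v in tree.preorder:
        for c in tree.children[v]:
            s = node_state[v]
            t_remain = float(tree.edge_length[c])
            while True:
                out = -Q[s, s]
                if out <= 0:
                    break
                wait = rng.exponential(1.0 / out)
                if wait >= t_remain:
                    break
                t_remain -= wait
                dwell[states[s]] += wait
                probs = np.clip(Q[s], 0, None)
                probs[s] = 0.0
                nxt = int(rng.choice(k, p=probs / probs.sum()))
                counts[f"{states[s]}->{states[nxt]}"] += 1
                s = nxt
            dwell[states[s]] += t_remain
            node_state[c] = s
    tips = pd.Series([states[node_state[i]] for i in range(tree.n_tips)],
                     index=tree.tip_labels)
    truth = {"node_states": node_state, "transition_counts": counts,
             "dwell_times": dwell}
    return tips, truth


def simulate_occurrences(scenario: SyntheticScenario, species_ids=None):
    """Clustered occurrence clouds with planted sympatry classes.

    Species are dealt round-robin into geographic clusters. Cluster anchors
    sit on a widely spaced grid; each member's range center is offset from
    its anchor by at most ``within_cluster_offset_km`` and every cloud
    contains its own range-center point plus a truncated (3 SD) Gaussian
    scatter. Buffered ranges of same-cluster species therefore always
    overlap, and different-cluster ranges never do. Returns
    (dict species -> OccurrenceSet, truth) where truth records the cluster
    assignment and the planted sympatric pairs.
    """
    ids = list(species_ids) if species_ids is not None else scenario.species_ids()
    rng = np.random.default_rng(scenario.subseed(6))
    ncl = scenario.n_clusters
    sep = scenario.cluster_separation_km
    # anchor grid centred near (-100E, 38N)
    cols = int(np.ceil(np.sqrt(ncl)))
    lat0, lon0 = 38.0, -100.0
    km_per_deg_lat = 110.574
    km_per_deg_lon = 111.320 * np.cos(np.radians(lat0))
    anchors = []
    for i in range(ncl):
        r, c = divmod(i, cols)
        anchors.append((lon0 + (c - cols / 2) * sep / km_per_deg_lon,
                        lat0 + (r - 1) * sep / km_per_deg_lat))
    cluster = {sid: i % ncl for i, sid in enumerate(ids)}

    occurrences = {}
    for sid in ids:
        alon, alat = anchors[cluster[sid]]
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, scenario.within_cluster_offset_km)
        clon = alon + rad * np.cos(ang) / km_per_deg_lon
        clat = alat + rad * np.sin(ang) / km_per_deg_lat
        n = scenario.points_per_species
        dx = np.clip(rng.standard_normal(n), -3, 3) * scenario.spread_km
        dy = np.clip(rng.standard_normal(n), -3, 3) * scenario.spread_km
        lon = clon + dx / km_per_deg_lon
        lat = clat + dy / km_per_deg_lat
        pts = np.column_stack([np.append(lon, clon), np.append(lat, clat)])
        occurrences[sid] = OccurrenceSet(sid, pts)

    symp = {tuple(sorted((a, b))): cluster[a] == cluster[b]
            for i, a in enumerate(ids) for b in ids[i + 1:]}
    truth = {"cluster": cluster, "sympatric": symp}
    return occurrences, truth


def simulate_study(scenario: SyntheticScenario):
    """Tree + traits + occurrences + ground truth for one scenario."""
    tree = simulate_tree(scenario)
    table = simulate_traits(scenario, tree)
    occurrences, geo_truth = simulate_occurrences(scenario)
    truth = {
        "scenario": scenario,
        "colors": table.colors,
        "red_shrink": scenario.red_shrink,
        **geo_truth,
    }
    return tree, table, occurrences, truth
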