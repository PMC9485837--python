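"""Species ranges from occurrence points, overlap/sympatry, and
disparity-by-geography statistics.

Occurrence clouds are cleaned (bad coordinates, duplicates) and thinned,
projected with an Albers equal-area conic fit to the data's latitude span
(closed form on the authalic sphere, so areas are exact), buffered by a
10 km radius, and unioned into range polygons. The pairwise overlap index is

    area(A n B) / [(area(A) - overlap) + (area(B) - overlap)],

with a pair called sympatric exactly when the overlap area is positive.
Phenotypic disparity between two species is the absolute difference of
their component scores; group contrasts use Kruskal-Wallis, an aligned-rank
two-way ANOVA (color-pair x sympatry), and a rank-based ANCOVA with
phylogenetic distance as the covariate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point
from shapely.ops import unary_union

__all__ = [
    "OccurrenceSet",
    "RangePolygon",
    "AlbersEqualArea",
    "fit_albers",
    "clean_and_thin",
    "build_range",
    "overlap_index",
    "pairwise_disparity",
    "build_pairwise_table",
    "kruskal_wallis",
    "art_two_way",
    "rank_ancova",
    "overlap_disparity_correlation",
]

EARTH_RADIUS_KM = 6371.0072  # authalic sphere


@dataclass
class OccurrenceSet:
    species_id: str
    points: np.ndarray  # (n, 2) of (longitude, latitude), WGS84 degrees

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 2:
            raise ValueError("points must be (lon, lat) pairs")
        if self.points.size:
            lon, lat = self.points[:, 0], self.points[:, 1]
            if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
                raise ValueError(f"{self.species_id}: coordinates out of WGS84 bounds")

    def __len__(self):
        return len(self.points)


@dataclass(frozen=True)
class AlbersEqualArea:
    """Albers equal-area conic projection on the authalic sphere (km units)."""

    lon0: float
    lat0: float
    lat1: float
    lat2: float

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lon = np.radians(np.asarray(lon, float))
        lat = np.radians(np.asarray(lat, float))
        p1, p2 = np.radians(self.lat1), np.radians(self.lat2)
        l0, f0 = np.radians(self.lon0), np.radians(self.lat0)
        n = 0.5 * (np.sin(p1) + np.sin(p2))
        if abs(n) < 1e-12:
            raise ValueError("degenerate Albers projection: standard parallels "
                             "symmetric about the equator")
        C = np.cos(p1) ** 2 + 2 * n * np.sin(p1)
        R = EARTH_RADIUS_KM
        rho = R * np.sqrt(np.clip(C - 2 * n * np.sin(lat), 0, None)) / n
        rho0 = R * np.sqrt(max(C - 2 * n * np.sin(f0), 0.0)) / n
        theta = n * (lon - l0)
        return rho * np.sin(theta), rho0 - rho * np.cos(theta)


def fit_albers(points: np.ndarray) -> AlbersEqualArea:
    """Standard parallels at 1/6 in from the latitude extremes (the usual
    rule of thumb), origin at the centroid."""
    pts = np.atleast_2d(np.asarray(points, float))
    lat_min, lat_max = pts[:, 1].min(), pts[:, 1].max()
    span = lat_max - lat_min
    if span < 1e-6:
        lat1, lat2 = lat_min - 1.0, lat_max + 1.0
    else:
        lat1, lat2 = lat_min + span / 6.0, lat_max - span / 6.0
    return AlbersEqualArea(lon0=float(pts[:, 0].mean()), lat0=float(pts[:, 1].mean()),
                           lat1=float(lat1), lat2=float(lat2))


def _haversine_km(p, q) -> float:
    lon1, lat1, lon2, lat2 = map(np.radians, (p[0], p[1], q[0], q[1]))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def clean_and_thin(raw: OccurrenceSet, bounds: tuple | None = None,
                   min_distance_km: float = 1.0) -> OccurrenceSet:
    """Drop (0, 0), out-of-bounds and duplicate points, then greedily thin so
    no two retained points are closer than ``min_distance_km``.

    ``bounds`` is (lon_min, lat_min, lon_max, lat_max). The greedy pass
    visits points sorted by latitude then longitude, so thinning is
    deterministic.
    """
    pts = raw.points
    if len(pts) == 0:
        warnings.warn(f"{raw.species_id}: no occurrence points")
        return OccurrenceSet(raw.species_id, np.empty((0, 2)))
    keep = ~np.all(pts == 0.0, axis=1)
    if bounds is not None:
        lon_min, lat_min, lon_max, lat_max = bounds
        keep &= ((pts[:, 0] >= lon_min) & (pts[:, 0] <= lon_max)
                 & (pts[:, 1] >= lat_min) & (pts[:, 1] <= lat_max))
    pts = np.unique(pts[keep], axis=0)
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    pts = pts[order]
    kept: list = []
    for p in pts:
        if all(_haversine_km(p, q) >= min_distance_km for q in kept):
            kept.append(p)
    if not kept:
        warnings.warn(f"{raw.species_id}: empty after cleaning; "
                      "species will be excluded downstream")
    return OccurrenceSet(raw.species_id, np.asarray(kept).reshape(-1, 2))


@dataclass
class RangePolygon:
    species_id: str
    geometry: object  # shapely (multi)polygon in projected km coordinates
    area_km2: float
    projection: AlbersEqualArea
    degenerate: bool = False


def build_range(occ: OccurrenceSet, buffer_km: float = 10.0,
                projection: AlbersEqualArea | None = None) -> RangePolygon:
    """Project, buffer each point by ``buffer_km``, union, and measure area.

    All species being compared must share one projection; pass the one
    returned by :func:`fit_albers` on the pooled occurrence points.
    """
    if len(occ) == 0:
        raise ValueError(f"{occ.species_id}: cannot build a range from no points")
    proj = projection if projection is not None else fit_albers(occ.points)
    x, y = proj.forward(occ.points[:, 0], occ.points[:, 1])
    geoms = [Point(xi, yi).buffer(buffer_km, quad_segs=64) for xi, yi in zip(x, y)]
    geom = unary_union(geoms)
    if not geom.is_valid:
        geom = geom.buffer(0)
    degenerate = buffer_km <= 0
    if degenerate:
        warnings.warn(f"{occ.species_id}: zero buffer produces a zero-area range")
    return RangePolygon(occ.species_id, geom, float(geom.area), proj,
                        degenerate=degenerate)


def overlap_index(a: RangePolygon, b: RangePolygon):
    """(overlap_area, index, sympatric) for one species pair.

    Identical ranges make the denominator zero; the index is then reported
    as +inf (sympatric, flagged by the caller as a sentinel).
    """
    inter = a.geometry.intersection(b.geometry)
    ov = float(inter.area)
    denom = (a.area_km2 - ov) + (b.area_km2 - ov)
    if ov > 0 and denom <= 0:
        idx = np.inf
    elif ov == 0:
        idx = 0.0
    else:
        idx = ov / denom
    return ov, idx, ov > 0


def ranges_to_geojson(ranges: dict, path) -> None:
    """Write range polygons as a GeoJSON FeatureCollection.

    Coordinates are in the shared projected plane (km, Albers equal-area),
    recorded in each feature's properties rather than a CRS member.
    """
    import json
    from shapely.geometry import mapping

    features = []
    for sid, rp in sorted(ranges.items()):
        props = {"species_id": sid, "area_km2": rp.area_km2,
                 "units": "km (projected, Albers equal-area)"}
        features.append({"type": "Feature", "properties": props,
                         "geometry": mapping(rp.geometry)})
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def pairwise_disparity(scores: pd.DataFrame, components=("pPC1", "pPC2")) -> pd.DataFrame:
    """|score_A - score_B| per component over all unordered species pairs."""
    rows = []
    ids = list(scores.index)
    for a, b in itertools.combinations(ids, 2):
        key = tuple(sorted((a, b)))
        row = {"species_a": key[0], "species_b": key[1]}
        for comp in components:
            row[f"{comp}_disparity"] = abs(float(scores.at[a, comp]) - float(scores.at[b, comp]))
        rows.append(row)
    return pd.DataFrame(rows)


def _color_pair_label(ca: str, cb: str) -> str:
    order = {"red": 0, "pink": 1, "white": 2}
    a, b = sorted((ca, cb), key=lambda c: order.get(c, 99))
    return f"{a}-{b}"


def build_pairwise_table(ranges: dict, scores: pd.DataFrame, colors: pd.Series,
                         phylo_distances: pd.DataFrame | None = None,
                         components=("pPC1", "pPC2")) -> pd.DataFrame:
    """Join geography, disparity, color pair, and phylogenetic distance per pair.

    Only species present in all inputs enter; the pair key is the sorted id
    pair, so the table is stable under species reordering.
    """
    ids = [s for s in scores.index if s in ranges]
    if phylo_distances is not None:
        ids = [s for s in ids if s in phylo_distances.index]
    rows = []
    for a, b in itertools.combinations(sorted(ids), 2):
        ov, idx, symp = overlap_index(ranges[a], ranges[b])
        row = {
            "species_a": a, "species_b": b,
            "overlap_area": ov, "overlap_index": idx, "sympatric": symp,
            "color_pair": _color_pair_label(colors[a], colors[b]),
        }
        for comp in components:
            row[f"{comp}_disparity"] = abs(float(scores.at[a, comp]) - float(scores.at[b, comp]))
        if phylo_distances is not None:
            row["phylo_distance"] = float(phylo_distances.at[a, b])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nonparametric statistics on pairwise disparities


def kruskal_wallis(values, groups):
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2 or len(values) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups and >= 2 observations")
    samples = [values[groups == g] for g in levels]
    if np.ptp(values) == 0:
        return 0.0, len(levels) - 1, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), len(levels) - 1, float(p)


def _effects_dummies(labels: np.ndarray) -> np.ndarray:
    """Sum-to-zero (effects) coding, one column per non-reference level."""
    levels = list(pd.unique(labels))
    X = np.zeros((len(labels), len(levels) - 1))
    for j, lv in enumerate(levels[1:]):
        X[labels == lv, j] = 1.0
    X[labels == levels[0], :] = -1.0
    return X


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def art_two_way(values, factor_a, factor_b) -> pd.DataFrame:
    """Aligned-rank-transform two-way ANOVA.

    For each effect (A, B, A x B) the responses are aligned by stripping the
    estimated other effects via the cell-mean decomposition, ranked with
    average ties, and a factorial ANOVA (effects coding, marginal
    drop-one-term sums of squares) is run on the ranks; only that effect's
    F and p are kept. Returns a table indexed by effect.
    """
    y = np.asarray(values, float)
    A = np.asarray(factor_a).astype(str)
    B = np.asarray(factor_b).astype(str)
    df = pd.DataFrame({"y": y, "A": A, "B": B})
    cells = df.groupby(["A", "B"])["y"].count()
    full = pd.MultiIndex.from_product([df["A"].unique(), df["B"].unique()])
    empty = [c for c in full if c not in cells.index]
    if empty:
        raise ValueError(f"empty design cell(s): {empty}")

    grand = y.mean()
    mean_a = df.groupby("A")["y"].transform("mean").to_numpy()
    mean_b = df.groupby("B")["y"].transform("mean").to_numpy()
    mean_ab = df.groupby(["A", "B"])["y"].transform("mean").to_numpy()
    resid = y - mean_ab
    aligned = {
        "A": resid + (mean_a - grand),
        "B": resid + (mean_b - grand),
        "A:B": resid + (mean_ab - mean_a - mean_b + grand),
    }

    XA = _effects_dummies(A)
    XB = _effects_dummies(B)
    XAB = np.column_stack([XA[:, i] * XB[:, j]
                           for i in range(XA.shape[1]) for j in range(XB.shape[1])])
    one = np.ones((len(y), 1))
    blocks = {"A": XA, "B": XB, "A:B": XAB}
    n = len(y)
    df_resid = n - (1 + XA.shape[1] + XB.shape[1] + XAB.shape[1])
    rows = []
    for effect, al in aligned.items():
        r = stats.rankdata(al)
        X_full = np.hstack([one, XA, XB, XAB])
        X_red = np.hstack([one] + [v for k, v in blocks.items() if k != effect])
        sse_full = _sse(r, X_full)
        sse_red = _sse(r, X_red)
        df_num = blocks[effect].shape[1]
        F = ((sse_red - sse_full) / df_num) / (sse_full / df_resid)
        rows.append({
            "effect": effect, "F": float(F), "df_num": df_num,
            "df_den": df_resid, "p": float(stats.f.sf(F, df_num, df_resid)),
        })
    return pd.DataFrame(rows).set_index("effect")


def rank_ancova(response, group, covariate):
    """Rank-based ANCOVA under homogeneous slopes.

    Both the response and the covariate are rank-transformed (average ties);
    the response ranks are regressed on the covariate ranks by least
    squares, and the group effect is tested by a one-way ANOVA on the
    residuals (a drop-in-dispersion F on the residual ranks). Ranking the
    covariate makes the test invariant to any monotone rescaling of its
    units. A constant covariate reduces the procedure to a one-way test on
    the response ranks, with a warning.
    """
    y = np.asarray(response, float)
    g = np.asarray(group)
    x = np.asarray(covariate, float)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need both groups present")
    ry = stats.rankdata(y)
    if np.ptp(x) == 0:
        warnings.warn("constant covariate: rank ANCOVA reduces to a one-way "
                      "rank test (Kruskal-Wallis-like)")
        resid = ry
        df_used = 0
    else:
        rx = stats.rankdata(x)
        rxc = rx - rx.mean()
        beta = float(rxc @ (ry - ry.mean()) / (rxc @ rxc))
        resid = ry - beta * rxc
        df_used = 1
    n = len(y)
    k = len(levels)
    grand = resid.mean()
    ssb = sum(len(resid[g == lv]) * (resid[g == lv].mean() - grand) ** 2 for lv in levels)
    ssw = sum(((resid[g == lv] - resid[g == lv].mean()) ** 2).sum() for lv in levels)
    df1, df2 = k - 1, n - k - df_used
    if ssw <= 0:  # residuals fully explained by the covariate ranks
        F = 0.0 if ssb <= 1e-12 else np.inf
    else:
        F = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p


def overlap_disparity_correlation(pairs: pd.DataFrame,
                                  components=("pPC1", "pPC2")) -> pd.DataFrame:
    """Spearman correlation of overlap (index and area) with per-component
    disparity among sympatric pairs."""
    symp = pairs[pairs["sympatric"]]
    finite = np.isfinite(symp["overlap_index"])
    rows = []
    for comp in components:
        for measure in ("overlap_index", "overlap_area"):
            sub = symp if measure == "overlap_area" else symp[finite]
            if len(sub) < 3:
                raise ValueError("need >= 3 sympatric pairs")
            rho, p = stats.spearmanr(sub[measure], sub[f"{comp}_disparity"])
            rows.append({"component": comp, "measure": measure,
                         "rho": float(rho), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)
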