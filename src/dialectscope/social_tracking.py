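"""Proximity-network analysis of tracking fixes.

Daily dyadic mean distances (computed only over ticks where both birds are
detected), nearest opposite-sex assignment, weighted categorical networks,
Newman assortativity with permutation inference, and temporal assortment
series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data.types import BirdRecord


@dataclass
class ProximityNetwork:
    """Weighted undirected network over birds with categorical attributes."""

    nodes: list[str]
    node_attrs: dict[str, dict[str, str]]  # attribute name -> {bird_id: level}
    edges_u: np.ndarray  # int indices into nodes
    edges_v: np.ndarray
    weights: np.ndarray
    scope: str = "all"  # between_sex | same_sex | all

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("edge weights must be non-negative")
        if np.any(self.edges_u == self.edges_v):
            raise ValueError("self-edges are not allowed")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, node in enumerate(self.nodes):
            g.add_node(node, **{attr: vals[node] for attr, vals in self.node_attrs.items()})
        for u, v, w in zip(self.edges_u, self.edges_v, self.weights):
            g.add_edge(self.nodes[u], self.nodes[v], weight=float(w))
        return g


@dataclass
class AssortativityResult:
    r: float
    attribute: str
    n_permutations: int
    p_perm: float  # literal rule: #{r_perm > r_obs} / n_perm
    p_conservative: float  # (1 + #{r_perm >= r_obs}) / (1 + n_perm)
    seed: int
    perm_r: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# dyadic distances


def dyad_daily_distances(fixes: pd.DataFrame, birds: list[BirdRecord]) -> pd.DataFrame:
    """Daily mean Euclidean distance for every dyad, restricted to ticks
    where both members were detected.

    Returns one row per (dyad, day) with columns bird_a, bird_b, day_index,
    mean_distance_mm, ln_distance, n_simultaneous_fixes, dyad_type (MF/MM/FF).
    For MF dyads ``bird_a`` is the female.  Dyads never co-detected on a day
    are absent (missing, not zero).
    """
    if fixes.duplicated(subset=["day_index", "timestamp", "bird_id"]).any():
        raise ValueError("duplicate fix for a bird at one timestamp")
    sex = {b.bird_id: b.sex for b in birds}
    ids = sorted({b.bird_id for b in birds} & set(fixes["bird_id"].unique()))
    idx = {bid: i for i, bid in enumerate(ids)}
    n = len(ids)
    rows = []
    for day, sub in fixes.groupby("day_index"):
        ticks = np.sort(sub["timestamp"].unique())
        tpos = {t: k for k, t in enumerate(ticks)}
        T = len(ticks)
        X = np.full((T, n), np.nan)
        Y = np.full((T, n), np.nan)
        ti = sub["timestamp"].map(tpos).to_numpy()
        bi = sub["bird_id"].map(idx).to_numpy()
        X[ti, bi] = sub["x_mm"].to_numpy()
        Y[ti, bi] = sub["y_mm"].to_numpy()
        valid = np.isfinite(X)
        S = np.zeros((n, n))
        C = np.zeros((n, n))
        for lo in range(0, T, 256):  # chunked to bound memory
            xs, ys, vs = X[lo : lo + 256], Y[lo : lo + 256], valid[lo : lo + 256]
            dx = xs[:, :, None] - xs[:, None, :]
            dy = ys[:, :, None] - ys[:, None, :]
            d = np.sqrt(dx**2 + dy**2)
            both = vs[:, :, None] & vs[:, None, :]
            d = np.where(both, d, 0.0)
            S += d.sum(axis=0)
            C += both.sum(axis=0)
        iu, ju = np.triu_indices(n, k=1)
        co = C[iu, ju]
        keep = co > 0
        for a, b, s, c in zip(iu[keep], ju[keep], S[iu, ju][keep], co[keep]):
            id_a, id_b = ids[a], ids[b]
            sa, sb = sex[id_a], sex[id_b]
            if sa != sb:
                dtype = "MF"
                if sa == "M":  # female first
                    id_a, id_b = id_b, id_a
            else:
                dtype = sa * 2
            mean = s / c
            rows.append((id_a, id_b, int(day), mean, np.log(mean), int(c), dtype))
    return pd.DataFrame(
        rows,
        columns=[
            "bird_a", "bird_b", "day_index", "mean_distance_mm",
            "ln_distance", "n_simultaneous_fixes", "dyad_type",
        ],
    )


def aggregate_dyads(daily: pd.DataFrame) -> pd.DataFrame:
    """Period-level dyad means (weighted by simultaneous-fix counts)."""
    def _agg(g: pd.DataFrame) -> pd.Series:
        w = g["n_simultaneous_fixes"].to_numpy()
        d = g["mean_distance_mm"].to_numpy()
        return pd.Series(
            {
                "mean_distance_mm": float((d * w).sum() / w.sum()),
                "n_simultaneous_fixes": int(w.sum()),
                "dyad_type": g["dyad_type"].iloc[0],
            }
        )

    out = (
        daily.groupby(["bird_a", "bird_b"])[
            ["mean_distance_mm", "n_simultaneous_fixes", "dyad_type"]
        ]
        .apply(_agg)
        .reset_index()
    )
    out["ln_distance"] = np.log(out["mean_distance_mm"])
    return out


def nearest_opposite_sex(period: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-bird nearest opposite-sex partner by period-mean distance.

    Input is an aggregated dyad table restricted to (or containing) MF rows.
    Ties are broken by higher co-detection count, then lexicographic id,
    with a warning.  Returns (assignments, reciprocity fraction).
    """
    mf = period[period["dyad_type"] == "MF"]
    if mf.empty:
        raise ValueError("no opposite-sex dyads with data")
    best: dict[str, tuple[float, int, str]] = {}
    for row in mf.itertuples(index=False):
        for focal, partner in ((row.bird_a, row.bird_b), (row.bird_b, row.bird_a)):
            cand = (row.mean_distance_mm, -row.n_simultaneous_fixes, partner)
            cur = best.get(focal)
            if cur is None or cand < cur:
                if cur is not None and cand[0] == cur[0]:
                    warnings.warn(f"nearest-neighbour tie for {focal}", stacklevel=2)
                best[focal] = cand
    rows = [
        {"bird_id": focal, "nearest": partner, "mean_distance_mm": dist,
         "n_simultaneous_fixes": -negn}
        for focal, (dist, negn, partner) in sorted(best.items())
    ]
    out = pd.DataFrame(rows)
    nearest_of = dict(zip(out["bird_id"], out["nearest"]))
    recip = float(np.mean([nearest_of.get(p) == b for b, p in nearest_of.items()]))
    return out, recip


def concordance_with_pairs(
    nearest: pd.DataFrame,
    pairs: list[tuple[str, str]],
    *,
    focal_sex_ids: set[str] | None = None,
    n_distance_bins: int = 0,
) -> dict:
    """Fraction of focal birds whose nearest opposite-sex bird is a called
    partner; percentage rounded to the nearest integer.

    ``focal_sex_ids`` restricts the focal set (e.g. females only).  With
    ``n_distance_bins > 0`` a distance-binned breakdown is included.
    """
    if nearest.empty:
        raise ValueError("empty nearest-neighbour table")
    bonded = {frozenset(p) for p in pairs}
    sub = nearest
    if focal_sex_ids is not None:
        sub = nearest[nearest["bird_id"].isin(focal_sex_ids)]
    if sub.empty:
        raise ValueError("no focal birds left after filtering")
    hits = np.array(
        [frozenset((b, p)) in bonded for b, p in zip(sub["bird_id"], sub["nearest"])]
    )
    out = {
        "n": int(len(sub)),
        "n_concordant": int(hits.sum()),
        "proportion": float(hits.mean()),
        "percentage": int(round(100 * hits.mean())),
    }
    if n_distance_bins > 0:
        binned = sub.assign(hit=hits)
        binned["bin"] = pd.qcut(binned["mean_distance_mm"], n_distance_bins, duplicates="drop")
        out["by_distance"] = (
            binned.groupby("bin", observed=True)["hit"].agg(["mean", "size"]).reset_index()
        )
    return out


# ---------------------------------------------------------------------------
# networks and assortativity


def build_network(
    dyads: pd.DataFrame,
    birds: list[BirdRecord],
    *,
    scope: str = "between_sex",
    weight: str = "inverse",
    max_distance_mm: float | None = None,
) -> ProximityNetwork:
    """Weighted network from a dyad table.

    ``weight='inverse'`` uses w = 1/mean_distance_mm (declared convention);
    ``weight='max_minus'`` uses w = max_d - d (requires ``max_distance_mm``
    or uses the observed maximum).
    """
    if scope == "between_sex":
        sub = dyads[dyads["dyad_type"] == "MF"]
    elif scope == "same_sex":
        sub = dyads[dyads["dyad_type"].isin(["MM", "FF"])]
    elif scope == "all":
        sub = dyads
    else:
        raise ValueError(f"unknown scope {scope!r}")
    by_id = {b.bird_id: b for b in birds}
    nodes = sorted(set(sub["bird_a"]) | set(sub["bird_b"]))
    idx = {n: i for i, n in enumerate(nodes)}
    d = sub["mean_distance_mm"].to_numpy()
    if weight == "inverse":
        w = 1.0 / d
    elif weight == "max_minus":
        top = max_distance_mm if max_distance_mm is not None else float(d.max())
        w = np.maximum(top - d, 0.0)
    elif weight == "count":
        w = sub["n_simultaneous_fixes"].to_numpy().astype(float)
    else:
        raise ValueError(f"unknown weight scheme {weight!r}")
    attrs = {
        attr: {n: getattr(by_id[n], attr) for n in nodes}
        for attr in ("rearing_pop", "genetic_pop", "sex")
    }
    attrs["rearing_type"] = {n: by_id[n].rearing_type for n in nodes}
    attrs["genetic_type"] = {n: by_id[n].genetic_type for n in nodes}
    return ProximityNetwork(
        nodes=nodes,
        node_attrs=attrs,
        edges_u=sub["bird_a"].map(idx).to_numpy(),
        edges_v=sub["bird_b"].map(idx).to_numpy(),
        weights=w,
        scope=scope,
    )


def network_from_counts(counts: pd.DataFrame, birds: list[BirdRecord]) -> ProximityNetwork:
    """Interaction-count network (female_id, male_id, count)."""
    by_id = {b.bird_id: b for b in birds}
    nodes = sorted(set(counts["female_id"]) | set(counts["male_id"]))
    idx = {n: i for i, n in enumerate(nodes)}
    attrs = {
        attr: {n: getattr(by_id[n], attr) for n in nodes}
        for attr in ("rearing_pop", "genetic_pop", "sex")
    }
    attrs["rearing_type"] = {n: by_id[n].rearing_type for n in nodes}
    attrs["genetic_type"] = {n: by_id[n].genetic_type for n in nodes}
    return ProximityNetwork(
        nodes=nodes,
        node_attrs=attrs,
        edges_u=counts["female_id"].map(idx).to_numpy(),
        edges_v=counts["male_id"].map(idx).to_numpy(),
        weights=counts["count"].to_numpy().astype(float),
        scope="between_sex",
    )


def _mixing_r(cat_u: np.ndarray, cat_v: np.ndarray, w: np.ndarray, k: int) -> float:
    e = np.zeros((k, k))
    np.add.at(e, (cat_u, cat_v), w)
    np.add.at(e, (cat_v, cat_u), w)
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    ab = float(a @ b)
    tr = float(np.trace(e))
    if abs(1.0 - ab) < 1e-12:
        if abs(tr - 1.0) < 1e-12:
            return 1.0
        raise ValueError("degenerate mixing: sum(a_i b_i) = 1 with imperfect mixing")
    return (tr - ab) / (1.0 - ab)


def assortativity(network: ProximityNetwork, attribute: str) -> float:
    """Newman categorical assortativity on the edge-weight mixing matrix."""
    if attribute not in network.node_attrs:
        raise KeyError(f"attribute {attribute!r} missing from network")
    if network.weights.sum() <= 0:
        raise ValueError("total edge weight must be positive")
    vals = network.node_attrs[attribute]
    levels = sorted(set(vals.values()))
    if len(levels) < 2:
        raise ValueError(f"attribute {attribute!r} has a single level; r undefined")
    lev = {v: i for i, v in enumerate(levels)}
    cats = np.array([lev[vals[n]] for n in network.nodes])
    return _mixing_r(cats[network.edges_u], cats[network.edges_v], network.weights, len(levels))


def permutation_test(
    network: ProximityNetwork,
    attribute: str,
    n_perm: int = 10000,
    seed: int = 0,
    keep_null: bool = False,
) -> AssortativityResult:
    """Node-label permutation test for categorical assortativity.

    p follows the literal rule #{r_perm > r_obs}/n_perm; the add-one
    conservative variant is co-reported.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is very small; p is unreliable", stacklevel=2)
    r_obs = assortativity(network, attribute)
    vals = network.node_attrs[attribute]
    levels = sorted(set(vals.values()))
    lev = {v: i for i, v in enumerate(levels)}
    cats = np.array([lev[vals[n]] for n in network.nodes])
    rng = np.random.default_rng(seed)
    u, v, w, k = network.edges_u, network.edges_v, network.weights, len(levels)
    perm_r = np.empty(n_perm)
    for i in range(n_perm):
        c = rng.permutation(cats)
        perm_r[i] = _mixing_r(c[u], c[v], w, k)
    p = float((perm_r > r_obs).sum() / n_perm)
    p_cons = float((1 + (perm_r >= r_obs).sum()) / (1 + n_perm))
    return AssortativityResult(
        r=r_obs,
        attribute=attribute,
        n_permutations=n_perm,
        p_perm=p,
        p_conservative=p_cons,
        seed=seed,
        perm_r=perm_r if keep_null else None,
    )


def daily_assortment_series(
    daily: pd.DataFrame,
    birds: list[BirdRecord],
    attribute: str,
    scope: str = "between_sex",
    *,
    weight: str = "inverse",
) -> tuple[pd.DataFrame, dict]:
    """Per-day assortativity series plus a fitted linear trend.

    Days with fewer than 2 dyads are skipped with a warning.  Returns
    (series with columns day_index/r, {'slope', 'intercept', 'p'}).
    """
    days = sorted(daily["day_index"].unique())
    if len(days) < 2:
        raise ValueError("need at least 2 days of data")
    rows = []
    for day in days:
        sub = daily[daily["day_index"] == day]
        if len(sub) < 2:
            warnings.warn(f"day {day} has < 2 dyads; skipped", stacklevel=2)
            continue
        net = build_network(sub, birds, scope=scope, weight=weight)
        try:
            rows.append({"day_index": int(day), "r": assortativity(net, attribute)})
        except ValueError:
            warnings.warn(f"day {day}: assortativity undefined; skipped", stacklevel=2)
    series = pd.DataFrame(rows)
    fit = stats.linregress(series["day_index"], series["r"])
    trend = {"slope": float(fit.slope), "intercept": float(fit.intercept),
             "p": float(fit.pvalue), "slope_se": float(fit.stderr)}
    return series, trend


# ---------------------------------------------------------------------------
# serialisation


def write_network(network: ProximityNetwork, graphml_path: str | Path,
                  edges_csv_path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), str(graphml_path))
    pd.DataFrame(
        {
            "bird_a": [network.nodes[u] for u in network.edges_u],
            "bird_b": [network.nodes[v] for v in network.edges_v],
            "weight": network.weights,
        }
    ).to_csv(edges_csv_path, index=False)


def write_assortativity_report(result: AssortativityResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "r": result.r,
                "attribute": result.attribute,
                "n_permutations": result.n_permutations,
                "p_perm": result.p_perm,
                "p_conservative": result.p_conservative,
                "seed": result.seed,
            },
            fh,
            indent=2,
        )
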