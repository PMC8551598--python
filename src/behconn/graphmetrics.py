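"""Weighted graph metrics, degree/weight-preserving nulls, normalisation.

All metrics operate on thresholded positive-weight undirected connectomes.
Path-based metrics map weights to lengths as 1/w; disconnected pairs are
excluded from the characteristic path length and contribute zero to
efficiency. Clustering uses the Onnela geometric-mean form with weights
scaled by the network maximum. Six global metrics (clustering, path length,
global/local efficiency, small-worldness, assortativity) are normalised by
the mean of an ensemble of rewired null networks that preserve the degree
sequence and the multiset of edge weights exactly; strength and modularity
are reported raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from . import community

__all__ = ["nodal_metrics", "global_metrics", "null_ensemble",
           "normalise_metrics", "auc_over_costs", "NullEnsemble",
           "NORMALISED_METRICS"]

NORMALISED_METRICS = ["clustering", "path_length", "global_efficiency",
                      "local_efficiency", "small_worldness", "assortativity"]


def _check_positive(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("metrics expect a thresholded non-negative matrix")
    if not np.allclose(w, w.T):
        raise ValueError("matrix must be symmetric")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def inverse_length(w: np.ndarray) -> np.ndarray:
    """Default weight-to-length map: length = 1/weight (0 = no edge)."""
    with np.errstate(divide="ignore"):
        return np.where(w > 0, 1.0 / w, 0.0)


def _distances(w: np.ndarray, to_length=inverse_length) -> np.ndarray:
    """All-pairs shortest path lengths under the configured length map."""
    return shortest_path(to_length(w), method="D", directed=False)


def _onnela_clustering(w: np.ndarray) -> np.ndarray:
    mx = w.max()
    if mx == 0:
        return np.zeros(w.shape[0])
    wh = np.cbrt(w / mx)
    cyc = np.diag(wh @ wh @ wh)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, cyc / denom, 0.0)
    return c


def _efficiency_from_dist(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def _local_efficiency(w: np.ndarray, to_length=inverse_length) -> np.ndarray:
    """Per-node efficiency of the subgraph induced on its neighbours."""
    n = w.shape[0]
    eloc = np.zeros(n)
    adj = w > 0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        eloc[i] = _efficiency_from_dist(_distances(sub, to_length))
    return eloc


def _betweenness(w: np.ndarray, to_length=inverse_length) -> np.ndarray:
    lengths = to_length(w)
    g = nx.from_numpy_array(w)
    for i, j, dat in g.edges(data=True):
        dat["length"] = lengths[i, j]
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(w.shape[0])])


def _module_strengths(w: np.ndarray, modules: np.ndarray) -> np.ndarray:
    """node x module matrix of strengths into each module."""
    labels = pd.unique(modules)
    return np.stack([w[:, modules == m].sum(axis=1) for m in labels], axis=1)


def participation_coefficient(w: np.ndarray, modules: np.ndarray) -> np.ndarray:
    """P_i = 1 - sum_s (k_is / k_i)^2 with weighted strengths; 0 if isolated."""
    k = w.sum(axis=1)
    ks = _module_strengths(w, modules)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 1.0 - ((ks / k[:, None]) ** 2).sum(axis=1)
    p[k == 0] = 0.0
    return p


def within_module_z(w: np.ndarray, modules: np.ndarray) -> np.ndarray:
    """z-score of each node's strength to its own module, within that module."""
    z = np.zeros(w.shape[0])
    for m in pd.unique(modules):
        idx = np.flatnonzero(modules == m)
        k_in = w[np.ix_(idx, idx)].sum(axis=1)
        sd = k_in.std()
        z[idx] = (k_in - k_in.mean()) / sd if sd > 0 else 0.0
    return z


def nodal_metrics(w: np.ndarray, modules: np.ndarray,
                  region_ids: list[str] | None = None,
                  to_length=inverse_length) -> pd.DataFrame:
    """Per-region strength, betweenness, participation, within-module z,
    clustering and local efficiency."""
    w = _check_positive(w)
    modules = np.asarray(modules)
    if modules.shape[0] != w.shape[0]:
        raise ValueError("module partition must assign every region")
    df = pd.DataFrame({
        "strength": w.sum(axis=1),
        "betweenness": _betweenness(w, to_length),
        "participation": participation_coefficient(w, modules),
        "within_module_z": within_module_z(w, modules),
        "clustering": _onnela_clustering(w),
        "local_efficiency": _local_efficiency(w, to_length),
    })
    if region_ids is not None:
        df.index = pd.Index(region_ids, name="region_id")
    return df


def modularity_louvain(w: np.ndarray, seed: int = 0, n_restart: int = 4) -> float:
    """Best-of-restarts Louvain Q on the (positive) connectome."""
    best = -np.inf
    for r in range(n_restart):
        best = max(best, community.louvain(w, seed=seed + r).q)
    return best


def assortativity(w: np.ndarray) -> float:
    """Pearson correlation of endpoint strengths over edges (both directions)."""
    i, j = np.nonzero(np.triu(w, k=1) > 0)
    if len(i) < 2:
        return float("nan")
    s = w.sum(axis=1)
    x = np.concatenate([s[i], s[j]])
    y = np.concatenate([s[j], s[i]])
    if x.std() == 0 or y.std() == 0:
        warnings.warn("strength-regular graph: assortativity undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def global_metrics(w: np.ndarray, seed: int = 0,
                   to_length=inverse_length) -> dict[str, float]:
    """Raw global metrics of one connectome (dict keyed by metric name)."""
    w = _check_positive(w)
    n = w.shape[0]
    d = _distances(w, to_length)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("graph has no edges")
    cpl = float(d[finite].mean())
    clustering = float(_onnela_clustering(w).mean())
    geff = _efficiency_from_dist(d)
    leff = float(_local_efficiency(w, to_length).mean())
    return {
        "strength": float(w.sum(axis=1).mean()),
        "modularity": modularity_louvain(w, seed=seed),
        "path_length": cpl,
        "global_efficiency": geff,
        "local_efficiency": leff,
        "clustering": clustering,
        "small_worldness": clustering / cpl,
        "assortativity": assortativity(w),
        "disconnected_pairs": int((~np.isfinite(d[off])).sum() // 2),
    }


@dataclass
class NullEnsemble:
    n_nulls: int
    swaps_per_edge: int
    seed: int
    metrics: pd.DataFrame          # null x metric
    means: pd.Series

    def mean(self, name: str) -> float:
        return float(self.means[name])


def rewire_preserving(w: np.ndarray, swaps_per_edge: int = 10,
                      seed: int | None = None) -> np.ndarray:
    """Maslov-Sneppen double-edge swaps carrying weights.

    Each accepted swap replaces edges (a,b),(c,d) with (a,d),(c,b), moving the
    original weights with the rewired stubs: the degree sequence and the
    multiset of edge weights are both preserved exactly.
    """
    w = _check_positive(w)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    sel = w[iu, ju] > 0
    edges = list(zip(iu[sel].tolist(), ju[sel].tolist()))
    weights = {e: w[e] for e in edges}
    adj = {e: True for e in edges}
    rng = np.random.default_rng(seed)
    m = len(edges)
    target = swaps_per_edge * m
    attempts = 0
    done = 0
    max_attempts = 50 * target
    while done < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        ab, cd = edges[e1], edges[e2]
        a, b = ab
        c, d = cd
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in adj or new2 in adj:
            continue
        del adj[ab], adj[cd]
        adj[new1] = adj[new2] = True
        w1, w2 = weights.pop(ab), weights.pop(cd)
        weights[new1], weights[new2] = w1, w2
        edges[e1], edges[e2] = new1, new2
        done += 1
    out = np.zeros_like(w)
    for (i, j), wt in weights.items():
        out[i, j] = out[j, i] = wt
    return out


def _reassign_weights_by_strength(w_rewired: np.ndarray,
                                  strengths: np.ndarray) -> np.ndarray:
    """Reassign the weight multiset to approximately preserve node strengths.

    Edges of the rewired topology are ranked by the product of their
    endpoints' original strengths and receive the sorted original weights in
    matching order — the standard rank-matching construction for
    strength-preserving nulls. Degree sequence and weight multiset stay exact;
    strengths are preserved approximately.
    """
    iu, ju = np.triu_indices(w_rewired.shape[0], k=1)
    on = w_rewired[iu, ju] > 0
    ei, ej = iu[on], ju[on]
    rank = np.argsort(-(strengths[ei] * strengths[ej]), kind="stable")
    weights = np.sort(w_rewired[iu, ju][on])[::-1]
    out = np.zeros_like(w_rewired)
    out[ei[rank], ej[rank]] = weights
    return out + out.T


def null_ensemble(w: np.ndarray, n_nulls: int = 100, swaps_per_edge: int = 10,
                  seed: int | None = None,
                  preserve: str = "degree") -> NullEnsemble:
    """Global metrics over ``n_nulls`` rewired null networks.

    ``preserve="degree"`` (default) keeps the degree sequence and weight
    multiset exactly; ``preserve="strength"`` additionally rank-matches
    weights to endpoint strengths so node strengths are approximately kept.
    """
    if preserve not in ("degree", "strength"):
        raise ValueError("preserve must be 'degree' or 'strength'")
    s_orig = np.asarray(w, dtype=float).sum(axis=1)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_nulls):
        wn = rewire_preserving(w, swaps_per_edge=swaps_per_edge,
                               seed=int(rng.integers(2**31 - 1)))
        if preserve == "strength":
            wn = _reassign_weights_by_strength(wn, s_orig)
        rows.append(global_metrics(wn, seed=int(rng.integers(2**31 - 1))))
    metrics = pd.DataFrame(rows)
    return NullEnsemble(n_nulls=n_nulls, swaps_per_edge=swaps_per_edge,
                        seed=-1 if seed is None else int(seed),
                        metrics=metrics, means=metrics.mean())


def normalise_metrics(raw: dict[str, float], nulls: NullEnsemble
                      ) -> dict[str, float]:
    """Divide the six normalisable metrics by their null-ensemble means.

    Strength and modularity stay raw. Small-worldness is the ratio of
    normalised clustering to normalised path length (so the raw clustering /
    path ratio self-normalises consistently); raw values are retained
    alongside under ``raw_*`` keys, and assortativity is additionally reported
    raw because null assortativity is typically near zero.
    """
    out = {}
    for k, v in raw.items():
        out[f"raw_{k}"] = v
    out["strength"] = raw["strength"]
    out["modularity"] = raw["modularity"]
    for name in ["clustering", "path_length", "global_efficiency",
                 "local_efficiency", "assortativity"]:
        out[name] = raw[name] / nulls.mean(name)
    out["small_worldness"] = out["clustering"] / out["path_length"]
    return out


def auc_over_costs(values: np.ndarray, costs: np.ndarray) -> float:
    """Trapezoidal area under a metric-versus-cost curve.

    Costs are proportions (e.g. 0.05 ... 0.30) and must be ascending; with at
    least two points the integral has the units of metric x cost.
    """
    values = np.asarray(values, dtype=float)
    costs = np.asarray(costs, dtype=float)
    if len(costs) < 2 or np.any(np.diff(costs) <= 0):
        raise ValueError("need >= 2 strictly ascending cost points")
    if values.shape[-1] != costs.shape[0]:
        raise ValueError("values and costs length mismatch")
    return float(np.trapezoid(values, costs))
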