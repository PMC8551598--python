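"""Independent brute-force oracles for the test suite.

Everything here is written deliberately naively (explicit loops,
Floyd-Warshall, exhaustive enumeration) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

TOL = 1e-12


# ---------------------------------------------------------------- paths

def floyd_warshall(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths with lengths = 1/weight, triple loop."""
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def char_path_length(w: np.ndarray) -> float:
    d = floyd_warshall(w)
    vals = [d[i, j] for i in range(len(w)) for j in range(len(w))
            if i != j and math.isfinite(d[i, j])]
    return sum(vals) / len(vals)


def global_efficiency(w: np.ndarray) -> float:
    d = floyd_warshall(w)
    n = len(w)
    vals = [1.0 / d[i, j] if math.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
            for i in range(n) for j in range(n) if i != j]
    return sum(vals) / len(vals)


def local_efficiency_nodal(w: np.ndarray) -> np.ndarray:
    n = len(w)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(sub)
    return out


def betweenness(w: np.ndarray) -> np.ndarray:
    """Unnormalised betweenness by explicit shortest-path counting."""
    n = len(w)
    d = floyd_warshall(w)
    # sigma[s][t]: number of shortest s-t paths, by DP over increasing distance
    sigma = np.zeros((n, n))
    for s in range(n):
        order = sorted(range(n), key=lambda t: d[s, t])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or not math.isfinite(d[s, t]):
                continue
            for v in range(n):
                if v != t and w[v, t] > 0 and \
                        abs(d[s, v] + 1.0 / w[v, t] - d[s, t]) < TOL:
                    sigma[s, t] += sigma[s, v]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not math.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) < TOL:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


# ---------------------------------------------------------------- local metrics

def onnela_clustering(w: np.ndarray) -> np.ndarray:
    n = len(w)
    mx = w.max()
    out = np.zeros(n)
    if mx == 0:
        return out
    for i in range(n):
        k = sum(1 for j in range(n) if w[i, j] > 0)
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h and \
                        w[i, j] > 0 and w[i, h] > 0 and w[j, h] > 0:
                    s += ((w[i, j] / mx) * (w[i, h] / mx) * (w[j, h] / mx)) ** (1 / 3)
        out[i] = s / (k * (k - 1))
    return out


def strength(w: np.ndarray) -> np.ndarray:
    return np.array([sum(w[i]) for i in range(len(w))])


def participation(w: np.ndarray, modules: np.ndarray) -> np.ndarray:
    n = len(w)
    out = np.zeros(n)
    for i in range(n):
        k = sum(w[i])
        if k == 0:
            continue
        acc = 0.0
        for m in set(modules.tolist()):
            k_m = sum(w[i, j] for j in range(n) if modules[j] == m)
            acc += (k_m / k) ** 2
        out[i] = 1.0 - acc
    return out


def within_module_z(w: np.ndarray, modules: np.ndarray) -> np.ndarray:
    n = len(w)
    out = np.zeros(n)
    for m in set(modules.tolist()):
        idx = [i for i in range(n) if modules[i] == m]
        kin = [sum(w[i, j] for j in idx) for i in idx]
        mu = sum(kin) / len(kin)
        var = sum((x - mu) ** 2 for x in kin) / len(kin)
        sd = math.sqrt(var)
        for i, x in zip(idx, kin):
            out[i] = (x - mu) / sd if sd > 0 else 0.0
    return out


def assortativity(w: np.ndarray) -> float:
    n = len(w)
    s = strength(w)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                xs.append(s[i])
                ys.append(s[j])
    xs, ys = np.array(xs), np.array(ys)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (xs.std() * ys.std()))


# ---------------------------------------------------------------- modularity

def signed_q(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Signed symmetric modularity by explicit double loop (diagonal included)."""
    n = len(w)
    wp = np.maximum(w, 0.0)
    wn = np.maximum(-w, 0.0)
    vp, vn = wp.sum(), wn.sum()
    sp, sn = wp.sum(1), wn.sum(1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            if vp > 0:
                q += wp[i, j] - gamma * sp[i] * sp[j] / vp
            if vn > 0:
                q -= wn[i, j] - gamma * sn[i] * sn[j] / vn
    return q / (vp + vn)


def set_partitions(n: int):
    """All partitions of range(n) as restricted-growth label arrays."""
    def rec(i, labels, k):
        if i == n:
            yield np.array(labels)
            return
        for c in range(k + 1):
            labels.append(c)
            yield from rec(i + 1, labels, max(k, c + 1))
            labels.pop()
    yield from rec(0, [], 0)


def best_partition_exhaustive(w: np.ndarray, gamma: float = 1.0
                              ) -> tuple[np.ndarray, float]:
    """Global modularity optimum by scanning every partition (n <= 10)."""
    wp = np.maximum(w, 0.0)
    wn = np.maximum(-w, 0.0)
    vp, vn = wp.sum(), wn.sum()
    b = np.zeros_like(w, dtype=float)
    if vp > 0:
        sp = wp.sum(1)
        b += wp - gamma * np.outer(sp, sp) / vp
    if vn > 0:
        sn = wn.sum(1)
        b -= wn - gamma * np.outer(sn, sn) / vn
    b /= (vp + vn)
    best_q, best_lab = -np.inf, None
    for lab in set_partitions(len(w)):
        q = b[lab[:, None] == lab[None, :]].sum()
        if q > best_q:
            best_q, best_lab = q, lab.copy()
    return best_lab, float(best_q)


# ---------------------------------------------------------------- misc

def trapezoid(y: np.ndarray, x: np.ndarray) -> float:
    total = 0.0
    for i in range(1, len(x)):
        total += 0.5 * (y[i] + y[i - 1]) * (x[i] - x[i - 1])
    return total


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac, bc = a - a.mean(), b - b.mean()
    return float((ac * bc).sum() / math.sqrt((ac ** 2).sum() * (bc ** 2).sum()))


def random_connected_graph(n: int, rng: np.random.Generator,
                           density: float = 0.6) -> np.ndarray:
    """Random connected weighted graph (spanning tree + extra edges)."""
    w = np.zeros((n, n))
    perm = rng.permutation(n)
    for a, b_ in zip(perm[:-1], perm[1:]):
        w[a, b_] = w[b_, a] = rng.uniform(0.2, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] == 0 and rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.2, 1.0)
    return w
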