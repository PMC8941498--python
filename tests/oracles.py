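"""Independent brute-force oracles used to check the fast implementations.

Everything here is written for clarity over speed and deliberately avoids the
code paths it is used to verify.
"""

from __future__ import annotations

import numpy as np


def path_distance(tree, label_a: str, label_b: str) -> float:
    """Patristic distance by walking node paths to the root and back."""
    nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    a, b = nodes[label_a], nodes[label_b]

    def ancestors(nd):
        out = [nd]
        while nd.parent_node is not None:
            nd = nd.parent_node
            out.append(nd)
        return out

    anc_a = ancestors(a)
    anc_b = set(id(n) for n in ancestors(b))
    mrca = next(n for n in anc_a if id(n) in anc_b)

    def climb(nd, stop):
        total = 0.0
        while nd is not stop:
            total += nd.edge.length
            nd = nd.parent_node
        return total

    return climb(a, mrca) + climb(b, mrca)


def mpd_double_loop(labels, dist) -> float:
    """Mean pairwise distance by explicit double loop over a DistanceMatrix."""
    labels = sorted(set(labels))
    n = len(labels)
    if n < 2:
        return float("nan")
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += dist.matrix[dist.index([labels[i]])[0], dist.index([labels[j]])[0]]
            count += 1
    return total / count


def mntd_double_loop(labels, dist) -> float:
    labels = sorted(set(labels))
    n = len(labels)
    if n < 2:
        return float("nan")
    total = 0.0
    for i in range(n):
        best = np.inf
        for j in range(n):
            if i == j:
                continue
            d = dist.matrix[dist.index([labels[i]])[0], dist.index([labels[j]])[0]]
            best = min(best, d)
        total += best
    return total / n


def faith_pd_edge_union(labels, tree) -> float:
    """Faith's PD as the union of per-pair path edge sets (no root stem)."""
    labels = sorted(set(labels))
    if not labels:
        return float("nan")
    if len(labels) == 1:
        return 0.0
    nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

    def path_edges(a, b):
        def ancestors(nd):
            out = [nd]
            while nd.parent_node is not None:
                nd = nd.parent_node
                out.append(nd)
            return out

        anc_a = ancestors(a)
        anc_b = set(id(n) for n in ancestors(b))
        mrca = next(n for n in anc_a if id(n) in anc_b)
        edges = set()
        for start in (a, b):
            nd = start
            while nd is not mrca:
                edges.add(id(nd))  # the edge above nd
                nd = nd.parent_node
        return edges

    union: set[int] = set()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            union |= path_edges(nodes[labels[i]], nodes[labels[j]])
    length_of = {
        id(nd): nd.edge.length
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
    }
    return sum(length_of[e] for e in union)


def ols_normal_equations(x, y):
    """Closed-form simple OLS: slope, intercept, residual mean square, adj R2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    s2 = (resid**2).sum() / (n - 2)
    ss_tot = ((y - ybar) ** 2).sum()
    r2 = 1 - (resid**2).sum() / ss_tot
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return slope, intercept, s2, adj


def welch_formula(x, y):
    """Textbook Welch statistic and Welch-Satterthwaite df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def pearson_chi2(table):
    """Sum (O - E)^2 / E over a contingency table with positive marginals."""
    table = np.asarray(table, float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def overlap_direct(pa, pb):
    """Schoener's D and Hellinger I straight from their definitions."""
    pa = np.asarray(pa, float)
    pb = np.asarray(pb, float)
    d = 1.0 - 0.5 * sum(abs(a - b) for a, b in zip(pa, pb))
    i = 1.0 - 0.5 * sum((np.sqrt(a) - np.sqrt(b)) ** 2 for a, b in zip(pa, pb))
    return d, i


def yule_attainment_time(n_tips, lam, rng):
    """Monte-Carlo draw of the time for a pure-birth process to reach n tips,
    extended by the waiting time to the next event (count-level simulation)."""
    t = 0.0
    for k in range(1, n_tips):
        t += rng.exponential(1.0 / (lam * k))
    return t + rng.exponential(1.0 / (lam * n_tips))
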