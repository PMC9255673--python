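"""Independent reference implementations used only for cross-checking.

These deliberately avoid the package's code paths (scipy linkage/cut_tree,
the QR-SVD CCA): naive O(V^3) average-linkage agglomeration with an explicit
leaf-pair distance average, partition replay for catalog enumeration, and a
refined angle-grid search for the two-dimensional canonical correlation.
"""
from __future__ import annotations

import numpy as np


def pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def correlation_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    n = profiles.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - pearson(profiles[i], profiles[j])
    return D


def naive_average_linkage(D: np.ndarray) -> list[tuple[frozenset, frozenset]]:
    """UPGMA merge sequence: average of original leaf-pair distances."""
    n = D.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        merges.append((clusters[a], clusters[b]))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def naive_unique_modules(profiles: np.ndarray, levels) -> dict[frozenset, set[int]]:
    """Catalog by replaying the naive merge sequence and hashing every
    non-singleton part of the partition at each requested level."""
    n = profiles.shape[0]
    merges = naive_average_linkage(correlation_distance_matrix(profiles))
    partitions = {n: [frozenset([i]) for i in range(n)]}
    parts = list(partitions[n])
    for k, (a, b) in enumerate(merges):
        parts = [c for c in parts if c not in (a, b)] + [a | b]
        partitions[n - k - 1] = list(parts)
    catalog: dict[frozenset, set[int]] = {}
    for m in levels:
        for part in partitions[m]:
            if len(part) >= 2:
                catalog.setdefault(part, set()).add(m)
    return catalog


def cca_first_r_gridsearch(X: np.ndarray, Y: np.ndarray,
                           n_grid: int = 720, n_refine: int = 3) -> float:
    """Max |corr(X a(theta), Y b(phi))| over unit directions in 2-D, by a
    coarse angle grid with local refinement."""
    assert X.shape[1] == 2 and Y.shape[1] == 2

    def scan(th_lo, th_hi, ph_lo, ph_hi, k):
        thetas = np.linspace(th_lo, th_hi, k)
        phis = np.linspace(ph_lo, ph_hi, k)
        U = X @ np.stack([np.cos(thetas), np.sin(thetas)])
        V = Y @ np.stack([np.cos(phis), np.sin(phis)])
        U = (U - U.mean(0)) / U.std(0)
        V = (V - V.mean(0)) / V.std(0)
        C = np.abs(U.T @ V) / X.shape[0]
        i, j = np.unravel_index(np.argmax(C), C.shape)
        return float(C[i, j]), thetas[i], phis[j]

    r, th, ph = scan(0.0, np.pi, 0.0, np.pi, n_grid)
    width = np.pi / n_grid
    for _ in range(n_refine):
        r, th, ph = scan(th - width, th + width, ph - width, ph + width, 81)
        width /= 40
    return r
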