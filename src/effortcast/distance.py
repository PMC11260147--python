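"""Land-avoiding distances on the ocean pixel graph.

Ocean pixels form an 8-connected graph (diagonals allowed, longitude wraps
when the grid spans 360 degrees); edge weights are great-circle distances
between pixel centroids. Land pixels carry no edges, so shortest paths route
around land. Distances are computed with multi-source Dijkstra; pixels not
reachable from any source receive ``inf`` and a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import haversine_m


def build_ocean_graph(lats: np.ndarray, lons: np.ndarray, is_ocean: np.ndarray,
                      n_lat: int, n_lon: int, wrap: bool) -> csr_matrix:
    """Sparse symmetric adjacency over all pixels; edges join ocean pixels only."""
    rows_i, cols_j, weights = [], [], []
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    for p in np.flatnonzero(is_ocean):
        r, c = divmod(int(p), n_lon)
        for dr, dc in steps:
            rr, cc = r + dr, c + dc
            if rr < 0 or rr >= n_lat:
                continue
            if wrap:
                cc %= n_lon
            elif cc < 0 or cc >= n_lon:
                continue
            q = rr * n_lon + cc
            if q <= p or not is_ocean[q]:
                continue
            w = float(haversine_m(lats[p], lons[p], lats[q], lons[q]))
            rows_i.append(p)
            cols_j.append(q)
            weights.append(w)
    n = n_lat * n_lon
    m = csr_matrix((weights, (rows_i, cols_j)), shape=(n, n))
    return m + m.T


def multi_source_distance(graph: csr_matrix, sources, n_pix: int,
                          warn_unreachable: bool = True) -> np.ndarray:
    """Shortest-path distance (m) from the nearest source to every pixel."""
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    if sources.size == 0:
        raise ValueError("at least one source pixel is required")
    d = dijkstra(graph, directed=False, indices=sources, min_only=True)
    if warn_unreachable and np.isinf(d[_finite_mask_targets(graph, n_pix)]).any():
        warnings.warn("some ocean pixels are unreachable from every source; "
                      "their distance is +inf", stacklevel=2)
    return d


def _finite_mask_targets(graph: csr_matrix, n_pix: int) -> np.ndarray:
    """Pixels that participate in the ocean graph (have at least one edge)."""
    deg = np.asarray((graph != 0).sum(axis=1)).ravel()
    return deg > 0


def nearest_source_distance(graph: csr_matrix, source_groups: dict, n_pix: int):
    """Per-pixel distance to the nearest source and the label of its group.

    ``source_groups`` maps a label to an array of source pixel ids. Returns
    ``(distance, label)`` arrays; pixels unreachable from every group get
    ``inf`` and label ``None``. Ties go to the lexicographically first label.
    """
    labels = sorted(source_groups)
    dist = np.full(n_pix, np.inf)
    who = np.array([None] * n_pix, dtype=object)
    for lab in labels:
        src = np.asarray(source_groups[lab], dtype=int)
        if src.size == 0:
            continue
        d = dijkstra(graph, directed=False, indices=src, min_only=True)
        better = d < dist - 1e-9
        dist[better] = d[better]
        who[better] = lab
    return dist, who
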