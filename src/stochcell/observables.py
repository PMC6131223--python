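"""Spatial and temporal statistics of lattice co-culture states.

Mirrors the readouts used to compare the lattice model with co-culture
micrographs: per-type population curves and their Gompertz fits,
nearest-neighbor graph-distance histograms, melanoma cluster morphology
(area, exposed-edge perimeter, principal-axis ratio, convex hull), and the
decay of normal-cell density with distance from the melanoma interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .cell_lattice import EMPTY, MELANOMA, NORMAL, LatticeState

__all__ = [
    "ClusterReport",
    "GompertzFit",
    "nn_distance_hist",
    "label_clusters",
    "density_vs_interface",
    "fit_gompertz",
    "gompertz",
]


@dataclass(frozen=True)
class GompertzFit:
    """Parameters of N(t) = A exp(-exp(-b (t - c))) plus fit diagnostics."""

    asymptote: float
    rate: float
    inflection_time: float
    residual: float
    degenerate: bool = False


def _coords(state: LatticeState, ctype: int) -> np.ndarray:
    return np.argwhere(state.occupancy == ctype).astype(float)


def _kdtree(state: LatticeState, pts: np.ndarray) -> cKDTree:
    if state.boundary == "periodic":
        return cKDTree(pts, boxsize=state.L)
    return cKDTree(pts)


def nn_distance_hist(state: LatticeState, i: int, j: int) -> pd.Series:
    """Histogram of each type-i cell's graph distance to its nearest type-j.

    Distances are Manhattan (p = 1) on the grid, toroidal when the boundary
    is periodic; for i == j the cell itself is excluded.  The returned
    Series is indexed by integer distance and its mass equals the number of
    type-i cells.
    """
    pi = _coords(state, i)
    pj = _coords(state, j)
    need = 2 if i == j else 1
    if len(pi) == 0 or len(pj) < need or (i == j and len(pi) < 2):
        raise ValueError(
            f"need at least one type-{i} cell and {need} type-{j} cell(s)"
        )
    tree = _kdtree(state, pj)
    k = 2 if i == j else 1
    d, _ = tree.query(pi, k=k, p=1)
    d = d[:, -1] if k == 2 else d
    d = np.rint(d).astype(int)
    counts = pd.Series(d).value_counts().sort_index()
    counts.index.name = "distance"
    counts.name = "count"
    return counts


def _adjacency_pairs(
    state: LatticeState, pts: np.ndarray, link_dist: int
) -> np.ndarray:
    tree = _kdtree(state, pts)
    pairs = tree.query_pairs(r=link_dist + 1e-9, p=1, output_type="ndarray")
    return pairs


def _unwrap(
    pts: np.ndarray, members: np.ndarray, adj: dict[int, list[int]], L: int, periodic: bool
) -> np.ndarray:
    """Assign wrap-consistent coordinates to one cluster via BFS from a seed."""
    coords = {int(members[0]): pts[members[0]].copy()}
    queue = [int(members[0])]
    while queue:
        a = queue.pop()
        for b in adj.get(a, ()):
            if b in coords:
                continue
            d = pts[b] - pts[a]
            if periodic:
                d = d - L * np.rint(d / L)
            coords[b] = coords[a] + d
            queue.append(b)
    return np.array([coords[int(m)] for m in members])


def label_clusters(
    state: LatticeState, ctype: int, link_dist: int = 1
) -> pd.DataFrame:
    """Connected components of one cell type under distance <= link_dist.

    Per cluster: ``size``/``area`` (cell count), ``perimeter`` (unit lattice
    edges from a member cell to a vertex outside the cluster), ``axis_ratio``
    (sqrt of the eigenvalue ratio of the member-coordinate covariance; 1 for
    a single cell, inf for a perfect line), and ``hull_area`` (planar convex
    hull of cell centers, 0 when degenerate).  ``link_dist`` should normally
    be the self-exclusion diameter of the type so that lattice-adjacent
    *admissible* cells link.
    """
    if link_dist < 1:
        raise ValueError("link_dist must be >= 1")
    pts = _coords(state, ctype)
    cols = ["size", "area", "perimeter", "axis_ratio", "hull_area"]
    if len(pts) == 0:
        return pd.DataFrame(columns=cols)
    pairs = _adjacency_pairs(state, pts, link_dist)
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    n = len(pts)
    if len(pairs):
        g = sp.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        g = sp.coo_matrix((n, n))
    n_comp, labels = connected_components(g, directed=False)
    adj: dict[int, list[int]] = {}
    for a, b in pairs:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    periodic = state.boundary == "periodic"
    member_set = {tuple(map(int, p)) for p in pts}
    label_of = {tuple(map(int, pts[q])): labels[q] for q in range(n)}
    rows = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        size = len(members)
        # exposed unit edges: 4-neighbor vertices not in the same cluster
        perim = 0
        for m in members:
            mi, mj = int(pts[m][0]), int(pts[m][1])
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = mi + di, mj + dj
                if periodic:
                    ni %= state.L
                    nj %= state.L
                elif not (0 <= ni < state.L and 0 <= nj < state.L):
                    perim += 1
                    continue
                if (ni, nj) not in member_set or label_of.get((ni, nj)) != c:
                    perim += 1
        coords = _unwrap(pts, members, adj, state.L, periodic)
        if size == 1:
            axis_ratio = 1.0
            hull_area = 0.0
        else:
            cov = np.cov(coords.T)
            ev = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
            ev = np.clip(ev, 0.0, None)
            if ev[0] <= 0:
                axis_ratio = 1.0
            elif ev[-1] <= 1e-12 * ev[0]:
                axis_ratio = float("inf")
            else:
                axis_ratio = float(np.sqrt(ev[0] / ev[-1]))
            try:
                hull_area = float(ConvexHull(coords).volume)
            except QhullError:
                hull_area = 0.0
        rows.append(
            {
                "size": size,
                "area": size,
                "perimeter": perim,
                "axis_ratio": axis_ratio,
                "hull_area": hull_area,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def _distance_to_type(state: LatticeState, ctype: int) -> np.ndarray:
    """Graph distance of every vertex to the nearest type-``ctype`` cell.

    Multi-source breadth-first search on the 4-neighbor lattice.
    """
    L = state.L
    periodic = state.boundary == "periodic"
    dist = np.full((L, L), -1, dtype=np.int64)
    srcs = np.argwhere(state.occupancy == ctype)
    if len(srcs) == 0:
        raise ValueError(f"no type-{ctype} cells on the grid")
    from collections import deque

    q: deque[tuple[int, int]] = deque()
    for i, j in srcs:
        dist[i, j] = 0
        q.append((int(i), int(j)))
    while q:
        i, j = q.popleft()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if periodic:
                ni %= L
                nj %= L
            elif not (0 <= ni < L and 0 <= nj < L):
                continue
            if dist[ni, nj] < 0:
                dist[ni, nj] = dist[i, j] + 1
                q.append((ni, nj))
    return dist


def density_vs_interface(
    state: LatticeState, window: int = 5, fit: bool = True
) -> tuple[pd.DataFrame, dict | None]:
    """Normal-cell count per window versus distance from the melanoma front.

    The grid is tiled with ``window`` x ``window`` squares; each window is
    binned by its mean graph distance to the nearest melanoma cell (bands of
    width ``window``).  Returns the per-band table (band, band_distance,
    mean_normal_count, n_windows) and, when ``fit`` is true and at least two
    bands have positive means, a log-linear least-squares exponential-decay
    fit {rate, amplitude, r_squared, excluded_bands}.
    """
    if window < 1 or window > state.L:
        raise ValueError("window must be in [1, L]")
    if not (state.occupancy == NORMAL).any():
        return pd.DataFrame(
            columns=["band", "band_distance", "mean_normal_count", "n_windows"]
        ), None
    dist = _distance_to_type(state, MELANOMA)
    L = state.L
    is_norm = state.occupancy == NORMAL
    recs = []
    for bi in range(0, L - window + 1, window):
        for bj in range(0, L - window + 1, window):
            sl = (slice(bi, bi + window), slice(bj, bj + window))
            recs.append((float(dist[sl].mean()), int(is_norm[sl].sum())))
    recs = np.array(recs)
    bands = np.floor(recs[:, 0] / window).astype(int)
    table = (
        pd.DataFrame(
            {"band": bands, "count": recs[:, 1]}
        )
        .groupby("band")
        .agg(mean_normal_count=("count", "mean"), n_windows=("count", "size"))
        .reset_index()
        .sort_values("band", ignore_index=True)
    )
    table.insert(1, "band_distance", (table["band"] + 0.5) * window)
    fit_result = None
    if fit:
        pos = table[table["mean_normal_count"] > 0]
        excluded = int(len(table) - len(pos))
        if len(pos) >= 2:
            x = pos["band_distance"].to_numpy()
            y = np.log(pos["mean_normal_count"].to_numpy())
            slope, intercept = np.polyfit(x, y, 1)
            yhat = slope * x + intercept
            ss_res = float(((y - yhat) ** 2).sum())
            ss_tot = float(((y - y.mean()) ** 2).sum())
            fit_result = {
                "rate": -float(slope),
                "amplitude": float(np.exp(intercept)),
                "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
                "excluded_bands": excluded,
            }
    return table, fit_result


def gompertz(t: np.ndarray, A: float, b: float, c: float) -> np.ndarray:
    """Gompertz growth curve N(t) = A exp(-exp(-b (t - c)))."""
    return A * np.exp(-np.exp(-b * (np.asarray(t, dtype=float) - c)))


def fit_gompertz(
    table: pd.DataFrame, ctype: int = MELANOMA, time_col: str = "sweep"
) -> GompertzFit:
    """Least-squares Gompertz fit of one population curve.

    ``table`` is an observable table from :func:`stochcell.cell_lattice.run`
    (or any frame with a time column and a ``count_melanoma`` /
    ``count_normal`` column).  At least 6 samples spanning actual growth are
    required.  A flat series is fitted but flagged ``degenerate`` (rate
    indistinguishable from 0).
    """
    col = {MELANOMA: "count_melanoma", NORMAL: "count_normal"}[ctype]
    t = table[time_col].to_numpy(dtype=float)
    y = table[col].to_numpy(dtype=float)
    if len(t) < 6:
        raise ValueError("need at least 6 samples to fit a Gompertz curve")
    if np.ptp(y) < 1e-12 or y.max() <= 0:
        return GompertzFit(float(y.mean()), 0.0, float(t.mean()), 0.0, degenerate=True)
    A0 = float(y.max()) * 1.05
    # inflection where N = A/e
    c0 = float(t[np.argmin(np.abs(y - A0 / np.e))])
    span = max(float(t[-1] - t[0]), 1e-9)
    b0 = 4.0 / span
    try:
        popt, _ = curve_fit(
            gompertz,
            t,
            y,
            p0=(A0, b0, c0),
            maxfev=20000,
            bounds=((0, 0, -np.inf), (np.inf, np.inf, np.inf)),
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gompertz fit did not converge (initial guess A={A0:.3g}, "
            f"b={b0:.3g}, c={c0:.3g}): {exc}"
        ) from exc
    resid = float(np.sqrt(np.mean((gompertz(t, *popt) - y) ** 2)))
    degenerate = popt[1] * span < 1e-6
    return GompertzFit(
        float(popt[0]), float(popt[1]), float(popt[2]), resid, degenerate
    )
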