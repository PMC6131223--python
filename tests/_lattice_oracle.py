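"""Independent pure-Python oracle for the lattice Monte-Carlo update rule.

Re-derives the single-vertex transition law from first principles (brute
force over vertices and event branches) without touching the package's
compiled kernel, so it can serve as an exact reference for one-step
transition probabilities on tiny grids.
"""

from __future__ import annotations

import itertools

import numpy as np


def toroidal_dist(L, a, b, periodic=True):
    di = abs(a[0] - b[0])
    dj = abs(a[1] - b[1])
    if periodic:
        di = min(di, L - di)
        dj = min(dj, L - dj)
    return di + dj


def brute_admissible(grid, x, t, D, periodic=True, exclude=None):
    L = grid.shape[0]
    for v in itertools.product(range(L), repeat=2):
        occ = grid[v]
        if occ == 0 or v == exclude:
            continue
        if toroidal_dist(L, x, v, periodic) < D[t][occ]:
            return False
    return True


def _ring(L, x, d, periodic=True):
    return [
        v
        for v in itertools.product(range(L), repeat=2)
        if toroidal_dist(L, x, v, periodic) == d
    ]


def _within(L, x, r, periodic=True):
    return [
        v
        for v in itertools.product(range(L), repeat=2)
        if 1 <= toroidal_dist(L, x, v, periodic) <= r
    ]


def step_distribution(grid, x, weights, D, r_mig=1, periodic=True):
    """Exact outcome distribution of one update at vertex x.

    ``weights[t] = (alpha, sigma, rho, delta)`` for t in {1, 2}.  Returns a
    dict mapping grid bytes -> probability.
    """
    L = grid.shape[0]
    out: dict[bytes, float] = {}

    def add(g, p):
        if p > 0:
            out[g.tobytes()] = out.get(g.tobytes(), 0.0) + p

    t = int(grid[x])
    if t != 0:
        a, s, r, dl = weights[t]
        Q = a + s + r + dl
        add(grid, s / Q)  # quiescence
        g = grid.copy()
        g[x] = 0
        add(g, r / Q)  # death
        # migration
        dests = [
            v
            for v in _within(L, x, r_mig, periodic)
            if grid[v] == 0 and brute_admissible(grid, v, t, D, periodic, exclude=x)
        ]
        if dests:
            for v in dests:
                g = grid.copy()
                g[x] = 0
                g[v] = t
                add(g, dl / Q / len(dests))
        else:
            add(grid, dl / Q)
        # division on the nearest admissible ring
        cands = []
        for d in range(1, D[t][t] + 1):
            cands = [
                v
                for v in _ring(L, x, d, periodic)
                if grid[v] == 0 and brute_admissible(grid, v, t, D, periodic)
            ]
            if cands:
                break
        if cands:
            for v in cands:
                g = grid.copy()
                g[v] = t
                add(g, a / Q / len(cands))
        else:
            add(grid, a / Q)
        return out

    # empty vertex
    R = weights[1][2] + weights[2][2]
    chans = []  # (weight, outcomes: list of (grid, frac))
    for i in (1, 2):
        a, s, r, dl = weights[i]
        if not brute_admissible(grid, x, i, D, periodic):
            continue
        # division parents on the nearest occupied ring
        n_par = 0
        for d in range(1, D[i][i] + 1):
            n_par = sum(1 for v in _ring(L, x, d, periodic) if grid[v] == i)
            if n_par:
                break
        if n_par:
            g = grid.copy()
            g[x] = i
            chans.append((a * n_par, [(g, 1.0)]))
        # migrants within range
        migrants = [v for v in _within(L, x, r_mig, periodic) if grid[v] == i]
        if migrants:
            outs = []
            for v in migrants:
                g = grid.copy()
                g[v] = 0
                g[x] = i
                outs.append((g, 1.0 / len(migrants)))
            chans.append((dl * len(migrants), outs))
    Z = R + sum(w for w, _ in chans)
    if Z <= 0:
        add(grid, 1.0)
        return out
    add(grid, R / Z)
    for w, outs in chans:
        for g, frac in outs:
            add(g, w / Z * frac)
    return out


def full_step_distribution(grid, weights, D, r_mig=1, periodic=True):
    """Outcome distribution of one full update (vertex chosen uniformly)."""
    L = grid.shape[0]
    out: dict[bytes, float] = {}
    for x in itertools.product(range(L), repeat=2):
        for key, p in step_distribution(grid, x, weights, D, r_mig, periodic).items():
            out[key] = out.get(key, 0.0) + p / L**2
    return out
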