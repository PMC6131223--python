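"""Lattice Markov-chain Monte Carlo model of contact-inhibited co-culture.

Two cell populations — melanoma (type 1) and normal keratinocytes (type 2)
— live on the vertices of an L x L square grid (4-neighbor graph distance,
periodic by default).  Contact inhibition is purely geometric: a pair of
cells of types i and j may never sit closer than the exclusion diameter
``D(i, j)`` edges.  Melanoma cells tolerate distance-1 neighbors
(D = 1) while normal cells keep two edges between themselves (D = 2), so
the same update rules produce dense melanoma clusters inside a sparser
normal monolayer.

One Monte-Carlo time unit (a *sweep*) is L^2 single-vertex updates.  A
uniformly chosen vertex is updated as follows.

Occupied by type i (event weights normalized by Q_i = a_i+s_i+r_i+d_i):
  quiescence  s_i / Q_i   stay put
  death       r_i / Q_i   vertex becomes empty
  migration   d_i / Q_i   move to a uniform admissible empty vertex within
                          graph distance <= r_mig (stay if none)
  division    a_i / Q_i   place a daughter on a uniform admissible empty
                          vertex of the nearest non-empty admissible ring
                          (d = 1 .. D(i,i); stay if none)

Empty vertex x (weights normalized by their sum):
  stay empty      R = r_1 + r_2
  division by i   Pi(i) * a_i * n_i(x),  n_i(x) = parents on the nearest
                                          ring holding type-i cells
  migration by i  Pi(i) * d_i * m_i(x),  m_i(x) = type-i cells within
                                          r_mig; the chosen source vacates

``Pi(i)`` is the admissibility indicator: 1 iff placing a type-i cell at x
violates no exclusion diameter against any current occupant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "EMPTY",
    "MELANOMA",
    "NORMAL",
    "CellTypeParams",
    "ExclusionMatrix",
    "LatticeState",
    "SimConfig",
    "PlacementError",
    "admissible",
    "update_vertex",
    "initialize",
    "run",
    "seed_kernel",
    "check_invariants",
    "graph_distance",
]

EMPTY, MELANOMA, NORMAL = 0, 1, 2
_MAX_RANGE = 5  # largest supported exclusion diameter / migration range
_BUF = 4 * _MAX_RANGE * (_MAX_RANGE + 1)


class PlacementError(RuntimeError):
    """Raised when an initial configuration cannot be placed admissibly."""


@dataclass(frozen=True)
class CellTypeParams:
    """Dimensionless per-update event weights of one cell type."""

    alpha: float  # division
    sigma: float  # quiescence
    rho: float  # death
    delta: float  # migration

    def __post_init__(self) -> None:
        for name in ("alpha", "sigma", "rho", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name!r} must be non-negative")
        if self.Q <= 0:
            raise ValueError("total event weight Q must be positive")

    @property
    def Q(self) -> float:
        return self.alpha + self.sigma + self.rho + self.delta


@dataclass(frozen=True)
class ExclusionMatrix:
    """Reciprocal minimal graph distances D(i, j) between cell types.

    The defaults encode the co-culture geometry: melanoma-melanoma pairs may
    be one edge apart, normal-normal pairs two, and cross pairs the larger
    of the two self-diameters.
    """

    d_mel_mel: int = 1
    d_norm_norm: int = 2
    d_cross: int | None = None

    def __post_init__(self) -> None:
        if self.d_cross is None:
            object.__setattr__(
                self, "d_cross", max(self.d_mel_mel, self.d_norm_norm)
            )
        for v in (self.d_mel_mel, self.d_norm_norm, self.d_cross):
            if not (1 <= v <= _MAX_RANGE):
                raise ValueError(f"exclusion diameters must be in [1, {_MAX_RANGE}]")

    def D(self, i: int, j: int) -> int:
        return int(self.as_array()[i, j])

    def as_array(self) -> np.ndarray:
        D = np.ones((3, 3), dtype=np.int64)
        D[MELANOMA, MELANOMA] = self.d_mel_mel
        D[NORMAL, NORMAL] = self.d_norm_norm
        D[MELANOMA, NORMAL] = D[NORMAL, MELANOMA] = self.d_cross
        return D


@dataclass
class LatticeState:
    """Occupancy grid with exclusion bookkeeping metadata."""

    L: int
    occupancy: np.ndarray
    boundary: str = "periodic"
    sweep_count: float = 0.0

    def __post_init__(self) -> None:
        self.occupancy = np.ascontiguousarray(self.occupancy, dtype=np.int8)
        if self.occupancy.shape != (self.L, self.L):
            raise ValueError("occupancy must be an L x L grid")
        if self.boundary not in ("periodic", "bounded"):
            raise ValueError("boundary must be 'periodic' or 'bounded'")
        if not np.isin(self.occupancy, (EMPTY, MELANOMA, NORMAL)).all():
            raise ValueError("occupancy values must be in {0, 1, 2}")

    @classmethod
    def empty(cls, L: int, boundary: str = "periodic") -> "LatticeState":
        return cls(L, np.zeros((L, L), dtype=np.int8), boundary)

    def counts(self) -> dict[int, int]:
        return {
            t: int((self.occupancy == t).sum()) for t in (MELANOMA, NORMAL)
        }


@dataclass(frozen=True)
class SimConfig:
    """Run controls: grid, duration, seeding and sampling."""

    L: int
    sweeps: int
    n_melanoma: int
    n_normal: int
    seed: int
    boundary: str = "periodic"
    sample_period: int = 1
    r_mig: int = 1
    placement: str = "well_mixed"

    def __post_init__(self) -> None:
        if self.L < 3:
            raise ValueError("L must be >= 3")
        if self.sweeps < 0 or self.sample_period < 1:
            raise ValueError("sweeps >= 0 and sample_period >= 1 required")
        if self.n_melanoma < 0 or self.n_normal < 0:
            raise ValueError("initial counts must be non-negative")
        if not (1 <= self.r_mig <= _MAX_RANGE):
            raise ValueError(f"r_mig must be in [1, {_MAX_RANGE}]")
        if self.placement != "well_mixed":
            raise ValueError("only 'well_mixed' placement is implemented")


# ---------------------------------------------------------------------------
# numba kernels (the same code path backs update_vertex and run)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _dist(L, periodic, i1, j1, i2, j2):
    di = abs(i1 - i2)
    dj = abs(j1 - j2)
    if periodic:
        if L - di < di:
            di = L - di
        if L - dj < dj:
            dj = L - dj
    return di + dj


@njit(cache=True)
def _admissible(grid, L, periodic, D, t, xi, xj, exi, exj):
    """True iff a type-t cell may occupy (xi, xj); (exi, exj) is ignored."""
    maxr = max(D[t, 1], D[t, 2]) - 1
    for di in range(-maxr, maxr + 1):
        rem = maxr - abs(di)
        for dj in range(-rem, rem + 1):
            i2 = xi + di
            j2 = xj + dj
            if periodic:
                i2 %= L
                j2 %= L
            elif i2 < 0 or i2 >= L or j2 < 0 or j2 >= L:
                continue
            occ = grid[i2, j2]
            if occ == 0 or (i2 == exi and j2 == exj):
                continue
            if _dist(L, periodic, xi, xj, i2, j2) < D[t, occ]:
                return False
    return True


@njit(cache=True)
def _collect_ring(grid, L, periodic, d, xi, xj, buf_i, buf_j):
    """Deduplicated vertices at true graph distance exactly d from x."""
    cnt = 0
    for di in range(-d, d + 1):
        rem = d - abs(di)
        for sgn in range(2):
            dj = rem if sgn == 0 else -rem
            if rem == 0 and sgn == 1:
                continue
            i2 = xi + di
            j2 = xj + dj
            if periodic:
                i2 %= L
                j2 %= L
            elif i2 < 0 or i2 >= L or j2 < 0 or j2 >= L:
                continue
            if _dist(L, periodic, xi, xj, i2, j2) != d:
                continue  # wraps closer on a small torus
            dup = False
            for q in range(cnt):
                if buf_i[q] == i2 and buf_j[q] == j2:
                    dup = True
                    break
            if not dup:
                buf_i[cnt] = i2
                buf_j[cnt] = j2
                cnt += 1
    return cnt


@njit(cache=True)
def _division_candidates(grid, L, periodic, D, t, xi, xj, buf_i, buf_j):
    """Empty admissible vertices on the nearest admissible ring (d<=D(t,t))."""
    ri = np.empty(_BUF, dtype=np.int64)
    rj = np.empty(_BUF, dtype=np.int64)
    for d in range(1, D[t, t] + 1):
        n_ring = _collect_ring(grid, L, periodic, d, xi, xj, ri, rj)
        cnt = 0
        for q in range(n_ring):
            if grid[ri[q], rj[q]] == 0 and _admissible(
                grid, L, periodic, D, t, ri[q], rj[q], -1, -1
            ):
                buf_i[cnt] = ri[q]
                buf_j[cnt] = rj[q]
                cnt += 1
        if cnt > 0:
            return cnt
    return 0


@njit(cache=True)
def _migration_candidates(grid, L, periodic, D, t, xi, xj, r_mig, buf_i, buf_j):
    """Empty vertices within r_mig admissible for t once (xi,xj) is vacated."""
    ri = np.empty(_BUF, dtype=np.int64)
    rj = np.empty(_BUF, dtype=np.int64)
    cnt = 0
    for d in range(1, r_mig + 1):
        n_ring = _collect_ring(grid, L, periodic, d, xi, xj, ri, rj)
        for q in range(n_ring):
            if grid[ri[q], rj[q]] == 0 and _admissible(
                grid, L, periodic, D, t, ri[q], rj[q], xi, xj
            ):
                buf_i[cnt] = ri[q]
                buf_j[cnt] = rj[q]
                cnt += 1
    return cnt


@njit(cache=True)
def _parents_on_nearest_ring(grid, L, periodic, t, xi, xj, r_div, buf_i, buf_j):
    """Type-t cells on the nearest ring (d<=r_div) that holds any of them."""
    ri = np.empty(_BUF, dtype=np.int64)
    rj = np.empty(_BUF, dtype=np.int64)
    for d in range(1, r_div + 1):
        n_ring = _collect_ring(grid, L, periodic, d, xi, xj, ri, rj)
        cnt = 0
        for q in range(n_ring):
            if grid[ri[q], rj[q]] == t:
                buf_i[cnt] = ri[q]
                buf_j[cnt] = rj[q]
                cnt += 1
        if cnt > 0:
            return cnt
    return 0


@njit(cache=True)
def _migrants_within(grid, L, periodic, t, xi, xj, r_mig, buf_i, buf_j):
    """Type-t cells within graph distance r_mig of x (potential migrants)."""
    ri = np.empty(_BUF, dtype=np.int64)
    rj = np.empty(_BUF, dtype=np.int64)
    cnt = 0
    for d in range(1, r_mig + 1):
        n_ring = _collect_ring(grid, L, periodic, d, xi, xj, ri, rj)
        for q in range(n_ring):
            if grid[ri[q], rj[q]] == t:
                buf_i[cnt] = ri[q]
                buf_j[cnt] = rj[q]
                cnt += 1
    return cnt


@njit(cache=True)
def _update_at(grid, L, periodic, alpha, sigma, rho, delta, D, r_mig, xi, xj):
    ci = np.empty(_BUF, dtype=np.int64)
    cj = np.empty(_BUF, dtype=np.int64)
    t = grid[xi, xj]
    if t != 0:
        Q = alpha[t] + sigma[t] + rho[t] + delta[t]
        u = np.random.random() * Q
        if u < sigma[t]:
            return  # quiescence
        if u < sigma[t] + rho[t]:
            grid[xi, xj] = 0  # death
            return
        if u < sigma[t] + rho[t] + delta[t]:
            cnt = _migration_candidates(grid, L, periodic, D, t, xi, xj, r_mig, ci, cj)
            if cnt > 0:
                q = np.random.randint(0, cnt)
                grid[xi, xj] = 0
                grid[ci[q], cj[q]] = t
            return
        # division
        cnt = _division_candidates(grid, L, periodic, D, t, xi, xj, ci, cj)
        if cnt > 0:
            q = np.random.randint(0, cnt)
            grid[ci[q], cj[q]] = t
        return
    # empty vertex: compete birth channels against the stay weight R
    R = rho[1] + rho[2]
    w = np.zeros(5)
    w[0] = R
    n_par = np.zeros(2, dtype=np.int64)
    for t2 in range(1, 3):
        if not _admissible(grid, L, periodic, D, t2, xi, xj, -1, -1):
            continue
        n_par[t2 - 1] = _parents_on_nearest_ring(
            grid, L, periodic, t2, xi, xj, D[t2, t2], ci, cj
        )
        w[2 * t2 - 1] = alpha[t2] * n_par[t2 - 1]
        w[2 * t2] = delta[t2] * _migrants_within(
            grid, L, periodic, t2, xi, xj, r_mig, ci, cj
        )
    Z = w[0] + w[1] + w[2] + w[3] + w[4]
    if Z <= 0.0:
        return
    u = np.random.random() * Z
    acc = w[0]
    if u < acc:
        return  # stays empty
    for t2 in range(1, 3):
        acc += w[2 * t2 - 1]
        if u < acc:
            grid[xi, xj] = t2  # colonized by division
            return
        acc += w[2 * t2]
        if u < acc:
            cnt = _migrants_within(grid, L, periodic, t2, xi, xj, r_mig, ci, cj)
            q = np.random.randint(0, cnt)
            grid[ci[q], cj[q]] = 0  # source vacated
            grid[xi, xj] = t2
            return


@njit(cache=True)
def _run_updates(grid, L, periodic, alpha, sigma, rho, delta, D, r_mig, n_updates):
    for _ in range(n_updates):
        xi = np.random.randint(0, L)
        xj = np.random.randint(0, L)
        _update_at(grid, L, periodic, alpha, sigma, rho, delta, D, r_mig, xi, xj)


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


def seed_kernel(seed: int) -> None:
    """Seed the Monte-Carlo kernel's RNG stream (deterministic thereafter)."""
    _seed_numba(np.uint32(seed))


# ---------------------------------------------------------------------------
# python surface
# ---------------------------------------------------------------------------


def _weight_arrays(
    types: tuple[CellTypeParams, CellTypeParams]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mel, norm = types
    alpha = np.array([0.0, mel.alpha, norm.alpha])
    sigma = np.array([0.0, mel.sigma, norm.sigma])
    rho = np.array([0.0, mel.rho, norm.rho])
    delta = np.array([0.0, mel.delta, norm.delta])
    return alpha, sigma, rho, delta


def admissible(
    state: LatticeState,
    x: tuple[int, int],
    ctype: int,
    excl: ExclusionMatrix,
    exclude: tuple[int, int] | None = None,
) -> bool:
    """Admissibility indicator Pi: may vertex ``x`` receive a type-``ctype`` cell?

    ``exclude`` ignores one occupant (the mover itself when checking a
    migration destination).
    """
    if ctype not in (MELANOMA, NORMAL):
        raise ValueError("ctype must be MELANOMA (1) or NORMAL (2)")
    exi, exj = exclude if exclude is not None else (-1, -1)
    return bool(
        _admissible(
            state.occupancy,
            state.L,
            state.boundary == "periodic",
            excl.as_array(),
            ctype,
            int(x[0]),
            int(x[1]),
            int(exi),
            int(exj),
        )
    )


def update_vertex(
    state: LatticeState,
    x: tuple[int, int],
    types: tuple[CellTypeParams, CellTypeParams],
    excl: ExclusionMatrix,
    r_mig: int = 1,
    seed: int | None = None,
) -> LatticeState:
    """Apply one single-vertex Monte-Carlo update in place and return state.

    Randomness comes from the kernel RNG stream; pass ``seed`` (or call
    :func:`seed_kernel`) to make a sequence of updates reproducible.
    """
    if seed is not None:
        seed_kernel(seed)
    alpha, sigma, rho, delta = _weight_arrays(types)
    _update_at(
        state.occupancy,
        state.L,
        state.boundary == "periodic",
        alpha,
        sigma,
        rho,
        delta,
        excl.as_array(),
        int(r_mig),
        int(x[0]),
        int(x[1]),
    )
    return state


def initialize(
    config: SimConfig,
    excl: ExclusionMatrix,
    rng: np.random.Generator | None = None,
) -> LatticeState:
    """Well-mixed random initial placement honoring all exclusion diameters.

    Cells are placed sequentially at uniformly drawn vertices, rejecting
    inadmissible draws; the type order is shuffled so the two populations
    interleave.  Deterministic for a given generator state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = LatticeState.empty(config.L, config.boundary)
    labels = [MELANOMA] * config.n_melanoma + [NORMAL] * config.n_normal
    order = rng.permutation(len(labels))
    max_tries = 200
    for idx in order:
        t = labels[idx]
        for _ in range(max_tries):
            xi = int(rng.integers(0, config.L))
            xj = int(rng.integers(0, config.L))
            if state.occupancy[xi, xj] == EMPTY and admissible(
                state, (xi, xj), t, excl
            ):
                state.occupancy[xi, xj] = t
                break
        else:
            placed = state.counts()
            raise PlacementError(
                f"could not place a type-{t} cell after {max_tries} tries "
                f"(placed so far: {placed}); lower the requested density"
            )
    return state


def run(
    config: SimConfig,
    types: tuple[CellTypeParams, CellTypeParams],
    excl: ExclusionMatrix,
    initial: LatticeState | None = None,
) -> tuple[LatticeState, pd.DataFrame]:
    """Simulate ``config.sweeps`` sweeps (one sweep = L^2 vertex updates).

    Returns the final state and an observable table sampled every
    ``sample_period`` sweeps with per-type counts, densities and the
    normal:melanoma ratio (NaN once melanoma dies out).  Identical seeds
    give identical trajectories.
    """
    ss = np.random.SeedSequence(config.seed)
    init_ss, kernel_ss = ss.spawn(2)
    if initial is None:
        state = initialize(config, excl, np.random.default_rng(init_ss))
    else:
        state = LatticeState(
            initial.L, initial.occupancy.copy(), initial.boundary, initial.sweep_count
        )
        if state.L != config.L:
            raise ValueError("initial state size does not match config.L")
    if not check_invariants(state, excl):
        raise PlacementError("initial configuration violates an exclusion diameter")
    seed_kernel(int(kernel_ss.generate_state(1, dtype=np.uint32)[0]))
    alpha, sigma, rho, delta = _weight_arrays(types)
    D = excl.as_array()
    periodic = state.boundary == "periodic"

    rows = []

    def sample(sweep: int) -> None:
        c = state.counts()
        area = config.L**2
        ratio = c[NORMAL] / c[MELANOMA] if c[MELANOMA] > 0 else np.nan
        rows.append(
            {
                "sweep": sweep,
                "count_melanoma": c[MELANOMA],
                "count_normal": c[NORMAL],
                "density_melanoma": c[MELANOMA] / area,
                "density_normal": c[NORMAL] / area,
                "ratio_normal_to_melanoma": ratio,
            }
        )

    sample(0)
    done = 0
    while done < config.sweeps:
        chunk = min(config.sample_period, config.sweeps - done)
        _run_updates(
            state.occupancy,
            state.L,
            periodic,
            alpha,
            sigma,
            rho,
            delta,
            D,
            int(config.r_mig),
            chunk * config.L**2,
        )
        done += chunk
        state.sweep_count += chunk
        sample(done)
    return state, pd.DataFrame(rows)


def check_invariants(state: LatticeState, excl: ExclusionMatrix) -> bool:
    """Exhaustive check that no occupied pair violates its exclusion diameter.

    O(N^2) over occupied vertices — intended for tests and debugging on
    small grids, not for the hot loop.
    """
    D = excl.as_array()
    periodic = state.boundary == "periodic"
    occ = np.argwhere(state.occupancy != EMPTY)
    for a in range(len(occ)):
        for b in range(a + 1, len(occ)):
            ti = state.occupancy[occ[a][0], occ[a][1]]
            tj = state.occupancy[occ[b][0], occ[b][1]]
            d = _dist(
                state.L, periodic, occ[a][0], occ[a][1], occ[b][0], occ[b][1]
            )
            if d < D[ti, tj]:
                return False
    return True


def graph_distance(
    state: LatticeState, a: tuple[int, int], b: tuple[int, int]
) -> int:
    """Manhattan graph distance between two vertices (wraps if periodic)."""
    return int(
        _dist(
            state.L,
            state.boundary == "periodic",
            int(a[0]),
            int(a[1]),
            int(b[0]),
            int(b[1]),
        )
    )
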