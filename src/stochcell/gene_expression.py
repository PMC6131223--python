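"""Binary-promoter (telegraph) model of gene expression.

A single gene switches between a transcribing ON state and a silent OFF
state.  While ON, products are synthesized at rate ``k``; products degrade
at rate ``rho`` regardless of the promoter state.  The OFF -> ON switch
occurs at rate ``f``.  The ON -> OFF switch is either

* self-repression (SRG): one of the ``n`` products binds the regulatory
  region, so the propensity is ``h1 * n``; or
* external regulation (ERG): an external repressor of fixed abundance
  drives the switch at the effective rate ``h2eff``; or
* absent (CONSTITUTIVE): the promoter is always ON and the product count
  relaxes to a Poisson distribution with mean ``k / rho``.

The joint law of (promoter state, product count) is described by the pair
of probability vectors ``alpha_n = P(ON, n)`` and ``beta_n = P(OFF, n)``
whose master equation is solved here on a truncated count range, and
cross-checked by an exact stochastic simulation (Gillespie) sampler.

Noise is summarized by the Fano factor ``F = var(n)/<n>`` and by the
promoter-product covariance ``xi = cov(g, n)`` where ``g`` takes the value
``k/rho`` in the ON state and 0 in the OFF state; the two are linked by the
decomposition ``F = 1 + xi/<n>``, so sub-Poissonian output (F < 1) requires
a negative promoter-product covariance.
"""

from __future__ import annotations

import dataclasses
import enum
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply, splu

__all__ = [
    "Mode",
    "PromoterParams",
    "JointDistribution",
    "SummaryStats",
    "SSATrajectory",
    "SolverError",
    "steady_state",
    "transient_solve",
    "simulate_ssa",
    "ssa_sample_states",
    "fano_factor",
    "covariance_xi",
    "summary_stats",
    "sweep_fano",
]

_NORM_TOL = 1e-9
_TAIL_TOL = 1e-8
_RESIDUAL_TOL = 1e-10
_MAX_NMAX = 1 << 20


class SolverError(RuntimeError):
    """Raised when the truncated master-equation solve cannot be completed."""


class Mode(str, enum.Enum):
    SRG = "SRG"
    ERG = "ERG"
    CONSTITUTIVE = "CONSTITUTIVE"


@dataclass(frozen=True)
class PromoterParams:
    """Rate constants for one binary gene.

    Parameters
    ----------
    k : float
        Product synthesis rate while ON (products / time).
    rho : float
        Per-molecule degradation rate (1 / time).
    f : float
        OFF -> ON switching rate (1 / time).  Ignored for CONSTITUTIVE.
    h1 : float
        ON -> OFF binding rate per product molecule (SRG only).
    h2eff : float
        ON -> OFF rate with the external-regulator abundance already folded
        in (ERG only).
    mode : Mode
        Regulatory scheme; selects which switching propensity is active.
    sequestering : bool
        SRG variant in which the binding product is removed from the pool
        (n -> n-1 on ON->OFF, n -> n+1 on OFF->ON).  The default keeps the
        product count unchanged across switching events.
    """

    k: float
    rho: float
    f: float = 0.0
    h1: float = 0.0
    h2eff: float = 0.0
    mode: Mode = Mode.SRG
    sequestering: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        for name in ("k", "rho", "f", "h1", "h2eff"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name!r} must be non-negative")
        if self.mode is Mode.SRG and self.h2eff != 0:
            raise ValueError("SRG requires h2eff = 0")
        if self.mode is Mode.ERG and self.h1 != 0:
            raise ValueError("ERG requires h1 = 0")
        if self.mode is Mode.CONSTITUTIVE and (self.h1 != 0 or self.h2eff != 0):
            raise ValueError("CONSTITUTIVE requires h1 = h2eff = 0")
        if self.sequestering and self.mode is not Mode.SRG:
            raise ValueError("sequestering switching only applies to SRG")

    @property
    def a(self) -> float:
        """Mean count of the matching always-ON gene, a = k / rho."""
        if self.rho == 0:
            raise ValueError("a = k/rho undefined for rho = 0")
        return self.k / self.rho


@dataclass
class JointDistribution:
    """Truncated joint law of (promoter state, product count).

    ``alpha[n]`` is the probability of (ON, n) and ``beta[n]`` of (OFF, n)
    for n = 0..n_max.  A valid distribution is normalized to 1 within 1e-9
    and carries negligible mass (< 1e-8) at the truncation boundary.
    """

    n_max: int
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != (self.n_max + 1,) or self.beta.shape != (self.n_max + 1,):
            raise ValueError("alpha/beta must have length n_max + 1")
        if (self.alpha < -1e-12).any() or (self.beta < -1e-12).any():
            raise ValueError("probabilities must be non-negative")

    @property
    def pn(self) -> np.ndarray:
        """Marginal distribution of the product count."""
        return self.alpha + self.beta

    @property
    def mean_n(self) -> float:
        n = np.arange(self.n_max + 1)
        return float(self.pn @ n)

    @property
    def var_n(self) -> float:
        n = np.arange(self.n_max + 1)
        p = self.pn
        m = float(p @ n)
        return max(float(p @ (n * n)) - m * m, 0.0)

    @property
    def p_on(self) -> float:
        return float(self.alpha.sum())

    @property
    def total(self) -> float:
        return float(self.alpha.sum() + self.beta.sum())

    def is_normalized(self, tol: float = _NORM_TOL) -> bool:
        return abs(self.total - 1.0) <= tol

    def tail_mass(self) -> float:
        return float(self.alpha[-1] + self.beta[-1])


@dataclass(frozen=True)
class SummaryStats:
    """First two moments of n, Fano factor, promoter-product covariance."""

    mean_n: float
    var_n: float
    fano: float
    xi: float
    p_on: float


@dataclass
class SSATrajectory:
    """Event list of one exact stochastic simulation run.

    ``times`` are the strictly increasing event times; ``n_values`` and
    ``promoter_states`` (1 = ON, 0 = OFF) give the state *after* each event.
    Index 0 holds the initial condition at time 0.
    """

    times: np.ndarray
    n_values: np.ndarray
    promoter_states: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_values = np.asarray(self.n_values, dtype=np.int64)
        self.promoter_states = np.asarray(self.promoter_states, dtype=np.int8)


# ---------------------------------------------------------------------------
# master-equation generator
# ---------------------------------------------------------------------------

def _generator(params: PromoterParams, n_max: int) -> sp.csc_matrix:
    """Sparse rate matrix Q with dp/dt = Q p over the truncated state space.

    State layout: index n is (ON, n), index n_max+1+n is (OFF, n).  For the
    CONSTITUTIVE mode the OFF block is unreachable and drains into ON so the
    stationary solution puts all mass on the ON block.
    """
    N = n_max
    on = np.arange(N + 1)
    off = on + N + 1
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r: np.ndarray, c: np.ndarray, v: np.ndarray) -> None:
        rows.append(np.asarray(r))
        cols.append(np.asarray(c))
        vals.append(np.asarray(v, dtype=float))

    # synthesis (ON, n) -> (ON, n+1), reflected at the truncation boundary
    if params.k > 0:
        add(on[1:], on[:-1], np.full(N, params.k))
    # degradation in both promoter states
    if params.rho > 0:
        rate = params.rho * on[1:]
        add(on[:-1], on[1:], rate)
        add(off[:-1], off[1:], rate)

    if params.mode is Mode.CONSTITUTIVE:
        f_eff = params.f if params.f > 0 else 1.0  # any positive rate drains OFF
        add(on, off, np.full(N + 1, f_eff))
    else:
        h_on_off = params.h1 * on + params.h2eff  # ON->OFF propensity per n
        if params.sequestering:
            # binding removes the bound product, release returns it
            add(off[:-1], on[1:], h_on_off[1:])
            add(on[1:], off[:-1], np.full(N, params.f))
            # boundary: release from (OFF, n_max) reflected (stays OFF)
        else:
            add(off, on, h_on_off)
            add(on, off, np.full(N + 1, params.f))

    r = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    c = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    v = np.concatenate(vals) if vals else np.empty(0)
    dim = 2 * (N + 1)
    Q = sp.coo_matrix((v, (r, c)), shape=(dim, dim)).tocsc()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=0)).ravel())
    return Q.tocsc()


def _initial_n_max(params: PromoterParams, requested: int | None) -> int:
    if requested is not None:
        if requested < 2:
            raise ValueError("n_max must be >= 2")
        return requested
    # constitutive Poisson(k/rho) envelope: mean + 12 sd, floor of 8
    if params.rho > 0 and params.k > 0:
        a = params.k / params.rho
        return max(8, math.ceil(a + 12.0 * math.sqrt(a)))
    return 8


def steady_state(params: PromoterParams, n_max: int | None = None) -> JointDistribution:
    """Stationary joint distribution of the truncated master equation.

    The truncated generator is solved as an augmented sparse linear system
    (one balance row replaced by the normalization constraint, sparse LU).
    If the mass at the truncation boundary exceeds 1e-8 the range is doubled
    and the solve repeated.

    Raises
    ------
    SolverError
        If the tail mass does not fall below tolerance before ``n_max``
        exceeds ~1e6 states, or the residual check fails.
    """
    nm = _initial_n_max(params, n_max)
    while True:
        Q = _generator(params, nm)
        dim = Q.shape[0]
        A = Q.tolil()
        A[0, :] = 1.0  # normalization row
        b = np.zeros(dim)
        b[0] = 1.0
        try:
            lu = splu(A.tocsc())
            p = lu.solve(b)
        except RuntimeError as exc:  # singular factorization
            raise SolverError(f"stationary solve failed for {params}: {exc}") from exc
        # one step of iterative refinement on the augmented system
        Ac = A.tocsc()
        p = p + lu.solve(b - Ac @ p)
        p = np.where(np.abs(p) < 1e-300, 0.0, p)
        if (p < -1e-9).any():
            raise SolverError(f"negative stationary probabilities for {params}")
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        residual = float(np.abs(Q @ p).max())
        scale = max(1.0, float(np.abs(Q.diagonal()).max()))
        if residual > _RESIDUAL_TOL * scale:
            raise SolverError(
                f"stationary residual {residual:.3e} exceeds tolerance for {params}"
            )
        dist = JointDistribution(nm, p[: nm + 1], p[nm + 1 :])
        if dist.tail_mass() < _TAIL_TOL:
            return dist
        if nm >= _MAX_NMAX:
            raise SolverError(
                f"tail mass {dist.tail_mass():.3e} still above {_TAIL_TOL} "
                f"at n_max={nm} for {params}"
            )
        nm *= 2


def transient_solve(
    params: PromoterParams, init: JointDistribution, t: float
) -> JointDistribution:
    """Propagate a joint distribution for a duration ``t``.

    Uses Krylov evaluation of the matrix exponential of the truncated
    generator (`scipy.sparse.linalg.expm_multiply`), which is robust for the
    stiff switching-dominated regimes.  ``t = 0`` returns the input.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return JointDistribution(init.n_max, init.alpha.copy(), init.beta.copy())
    nm = max(init.n_max, _initial_n_max(params, None))
    while True:
        p0 = np.zeros(2 * (nm + 1))
        p0[: init.n_max + 1] = init.alpha
        p0[nm + 1 : nm + 1 + init.n_max + 1] = init.beta
        Q = _generator(params, nm)
        p = expm_multiply(Q * t, p0)
        if abs(p.sum() - 1.0) > 1e-8:
            raise SolverError(
                f"probability leaked to {p.sum():.12f} during transient solve; "
                f"try a larger n_max than {nm} or a shorter time step"
            )
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        dist = JointDistribution(nm, p[: nm + 1], p[nm + 1 :])
        if dist.tail_mass() < _TAIL_TOL:
            return dist
        if nm >= _MAX_NMAX:
            raise SolverError(f"transient tail mass not resolved at n_max={nm}")
        nm *= 2


# ---------------------------------------------------------------------------
# exact stochastic simulation
# ---------------------------------------------------------------------------

def _propensities(params: PromoterParams, n: int, on: int) -> tuple[float, float, float, float]:
    """(synthesis, degradation, ON->OFF, OFF->ON) propensities of one state."""
    syn = params.k if on else 0.0
    deg = params.rho * n
    if params.mode is Mode.CONSTITUTIVE:
        sw_off, sw_on = 0.0, (0.0 if on else max(params.f, 1.0))
    else:
        sw_off = (params.h1 * n + params.h2eff) if on else 0.0
        sw_on = params.f if not on else 0.0
    return syn, deg, sw_off, sw_on


def simulate_ssa(
    params: PromoterParams,
    t_end: float,
    seed: int,
    n0: int = 0,
    s0: int | bool = True,
    max_events: int | None = None,
) -> SSATrajectory:
    """Exact stochastic simulation (Gillespie direct method).

    Waiting times are exponential with total propensity
    ``k*[ON] + rho*n + f*[OFF] + (h1*n or h2eff)*[ON]``; identical seeds
    produce identical trajectories (counter-based Philox stream).

    Parameters
    ----------
    t_end : float
        Simulated time horizon (> 0).
    n0, s0 : initial product count and promoter state (truthy = ON).
    max_events : optional hard cap on the number of events recorded.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    if params.mode is Mode.CONSTITUTIVE:
        s0 = True
    rng = np.random.Generator(np.random.Philox(seed))
    t = 0.0
    n = int(n0)
    on = 1 if s0 else 0
    times = [0.0]
    ns = [n]
    states = [on]
    cap = max_events if max_events is not None else np.inf
    while len(times) - 1 < cap:
        syn, deg, sw_off, sw_on = _propensities(params, n, on)
        total = syn + deg + sw_off + sw_on
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        u = rng.random() * total
        if u < syn:
            n += 1
        elif u < syn + deg:
            n -= 1
        elif u < syn + deg + sw_off:
            on = 0
            if params.sequestering:
                n -= 1
        else:
            on = 1
            if params.sequestering:
                n += 1
        times.append(t)
        ns.append(n)
        states.append(on)
    return SSATrajectory(np.array(times), np.array(ns), np.array(states), seed)


def ssa_sample_states(
    params: PromoterParams,
    seed: int,
    n_samples: int,
    spacing: float | None = None,
    burn_in: float | None = None,
    n0: int = 0,
    s0: int | bool = True,
) -> np.ndarray:
    """Sample (promoter, n) states of the SSA at widely spaced times.

    Returns an (n_samples, 2) int array of (on, n) pairs collected every
    ``spacing`` time units after ``burn_in``.  The default spacing is five
    relaxation times (max of 1/rho and the switching timescale) so that
    consecutive samples are close to independent, which makes multinomial
    sampling error a valid yardstick when the samples are compared with the
    stationary solver distribution.
    """
    if params.mode is Mode.CONSTITUTIVE:
        s0 = True
    relax = []
    if params.rho > 0:
        relax.append(1.0 / params.rho)
    sw = params.f + params.h2eff + params.h1  # h1 per molecule: conservative
    if sw > 0:
        relax.append(1.0 / sw)
    tau = max(relax) if relax else 1.0
    if spacing is None:
        spacing = 5.0 * tau
    if burn_in is None:
        burn_in = 20.0 * tau
    rng = np.random.Generator(np.random.Philox(seed))
    t = 0.0
    n = int(n0)
    on = 1 if s0 else 0
    next_sample = burn_in
    out = np.empty((n_samples, 2), dtype=np.int64)
    k = 0
    while k < n_samples:
        syn, deg, sw_off, sw_on = _propensities(params, n, on)
        total = syn + deg + sw_off + sw_on
        if total <= 0.0:
            while k < n_samples:
                out[k, 0], out[k, 1] = on, n
                k += 1
            break
        t_next = t + rng.exponential(1.0 / total)
        while k < n_samples and next_sample < t_next:
            out[k, 0], out[k, 1] = on, n
            k += 1
            next_sample += spacing
        t = t_next
        u = rng.random() * total
        if u < syn:
            n += 1
        elif u < syn + deg:
            n -= 1
        elif u < syn + deg + sw_off:
            on = 0
            if params.sequestering:
                n -= 1
        else:
            on = 1
            if params.sequestering:
                n += 1
    return out


# ---------------------------------------------------------------------------
# noise statistics
# ---------------------------------------------------------------------------

def fano_factor(dist: JointDistribution) -> float:
    """Fano factor F = var(n) / <n> of the product-count marginal."""
    mean = dist.mean_n
    if mean <= 0:
        raise ValueError("Fano factor undefined: mean product count is zero")
    return dist.var_n / mean


def covariance_xi(dist: JointDistribution, params: PromoterParams) -> float:
    """Promoter-product covariance xi = cov(g, n), g = k/rho * [promoter ON].

    The promoter indicator is valued at the stationary mean of the matching
    always-ON gene (k/rho when ON, 0 when OFF), which puts xi on the same
    scale as n and yields the decomposition F = 1 + xi / <n>.
    """
    g = params.a
    n = np.arange(dist.n_max + 1)
    e_gn = g * float(dist.alpha @ n)
    return e_gn - g * dist.p_on * dist.mean_n


def summary_stats(dist: JointDistribution, params: PromoterParams) -> SummaryStats:
    """Mean, variance, Fano factor and xi of a solved joint distribution."""
    return SummaryStats(
        mean_n=dist.mean_n,
        var_n=dist.var_n,
        fano=fano_factor(dist),
        xi=covariance_xi(dist, params),
        p_on=dist.p_on,
    )


def sweep_fano(
    base: PromoterParams,
    grid: dict[str, list] | list[dict],
) -> pd.DataFrame:
    """Solve the stationary model over a parameter grid and tabulate noise.

    ``grid`` is either a mapping field -> list of values (expanded as a
    cartesian product) or an explicit list of per-point override dicts.
    Each row records the overrides plus ``mean_n``, ``fano``, ``xi`` and
    ``p_on``; per-point solver failures are captured in an ``error`` column
    instead of aborting the sweep.
    """
    if isinstance(grid, dict):
        if not grid:
            raise ValueError("grid must be non-empty")
        keys = list(grid)
        points = [dict(zip(keys, combo)) for combo in itertools.product(*grid.values())]
    else:
        points = [dict(p) for p in grid]
    if not points:
        raise ValueError("grid must be non-empty")
    rows = []
    for overrides in points:
        row = dict(overrides)
        try:
            params = dataclasses.replace(base, **overrides)
            stats = summary_stats(steady_state(params), params)
            row.update(
                mean_n=stats.mean_n,
                fano=stats.fano,
                xi=stats.xi,
                p_on=stats.p_on,
                error=None,
            )
        except (SolverError, ValueError) as exc:
            row.update(mean_n=np.nan, fano=np.nan, xi=np.nan, p_on=np.nan, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
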