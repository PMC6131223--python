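"""Expression profiles of independent binary genes along a 1-D embryo axis.

Each node of a one-dimensional lattice spanning the anterior-posterior (AP)
axis carries a single copy of a binary gene (see
:mod:`stochcell.gene_expression`).  Position enters only through the local
switching rates — an activator-like profile modulates the OFF->ON rate
``f(x)`` and/or a repressor-like profile the ON->OFF rate ``h2eff(x)`` —
so nodes are statistically independent and the spatial pattern is the
family of per-node stationary (or finite-time) laws.

The expression domain is delimited by the positions where the mean profile
crosses half of its maximum; the positional imprecision of each border is
the interval swept by the crossings of the mean +/- one standard deviation
envelopes with the same half-max level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .gene_expression import (
    JointDistribution,
    Mode,
    PromoterParams,
    SolverError,
    steady_state,
    transient_solve,
)

__all__ = [
    "AxisLattice",
    "ExpressionProfile",
    "Border",
    "BorderBand",
    "profile",
    "border_positions",
    "border_noise",
    "gaussian_activation_lattice",
]


@dataclass
class AxisLattice:
    """Per-position promoter parameters along the AP axis.

    ``positions`` are strictly increasing fractional coordinates in [0, 1];
    ``params_at[i]`` is the full parameter set of the gene at node i.  If
    ``t_snapshot`` is set, profiles are evaluated at that time starting from
    (OFF, n=0) at every node; otherwise the stationary law is used.
    """

    positions: np.ndarray
    params_at: Sequence[PromoterParams]
    t_snapshot: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1 or self.positions.size < 3:
            raise ValueError("need at least 3 axis positions")
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if len(self.params_at) != self.positions.size:
            raise ValueError("one PromoterParams per position required")


@dataclass
class ExpressionProfile:
    """Mean and standard deviation of the product count per axis node."""

    positions: np.ndarray
    mean_n: np.ndarray
    sd_n: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.mean_n = np.asarray(self.mean_n, dtype=float)
        self.sd_n = np.asarray(self.sd_n, dtype=float)
        if not (self.positions.shape == self.mean_n.shape == self.sd_n.shape):
            raise ValueError("positions/mean_n/sd_n lengths must match")
        if (self.sd_n < 0).any():
            raise ValueError("sd_n must be non-negative")


@dataclass(frozen=True)
class Border:
    """Half-max crossing on one side of the expression peak (or None)."""

    anterior: float | None
    posterior: float | None


@dataclass(frozen=True)
class BorderBand:
    """Positional-uncertainty interval (lo, hi) of one border, or None."""

    anterior: tuple[float, float] | None
    posterior: tuple[float, float] | None


def _zero_off_init(n_max: int = 2) -> JointDistribution:
    beta = np.zeros(n_max + 1)
    beta[0] = 1.0
    return JointDistribution(n_max, np.zeros(n_max + 1), beta)


def profile(lattice: AxisLattice) -> ExpressionProfile:
    """Per-node <n> and sd(n), from the stationary or finite-time law.

    A per-node solver failure aborts with a message naming the node so a
    misconfigured parameter curve is easy to locate.
    """
    means = np.empty(lattice.positions.size)
    sds = np.empty(lattice.positions.size)
    for i, params in enumerate(lattice.params_at):
        try:
            if lattice.t_snapshot is None:
                dist = steady_state(params)
            else:
                init = _zero_off_init()
                if params.mode is Mode.CONSTITUTIVE:
                    init = JointDistribution(
                        2, np.array([1.0, 0.0, 0.0]), np.zeros(3)
                    )
                dist = transient_solve(params, init, lattice.t_snapshot)
        except SolverError as exc:
            raise SolverError(
                f"profile solve failed at node {i} (x={lattice.positions[i]:.4f}): {exc}"
            ) from exc
        means[i] = dist.mean_n
        sds[i] = np.sqrt(dist.var_n)
    return ExpressionProfile(lattice.positions.copy(), means, sds)


def _crossings(x: np.ndarray, y: np.ndarray, level: float) -> list[float]:
    """All positions where the piecewise-linear curve y(x) crosses ``level``."""
    out: list[float] = []
    for i in range(len(x) - 1):
        y0, y1 = y[i] - level, y[i + 1] - level
        if y0 == 0.0:
            out.append(float(x[i]))
        if y0 * y1 < 0:
            out.append(float(x[i] + (x[i + 1] - x[i]) * y0 / (y0 - y1)))
    if y[-1] == level:
        out.append(float(x[-1]))
    return out


def _half_max_side_crossings(
    prof_x: np.ndarray, curve: np.ndarray, level: float, i_peak: int
) -> tuple[list[float], list[float]]:
    left = [c for c in _crossings(prof_x[: i_peak + 1], curve[: i_peak + 1], level)]
    right = [c for c in _crossings(prof_x[i_peak:], curve[i_peak:], level)]
    return left, right


def border_positions(prof: ExpressionProfile) -> Border:
    """Anterior/posterior positions where <n> falls to half its maximum.

    The half-max level is taken from the node-wise maximum of the mean
    profile (leftmost node on ties); crossings are linearly interpolated
    between adjacent nodes.  A side with no crossing is reported as None.
    """
    if prof.mean_n.max() <= 0:
        return Border(None, None)
    i_peak = int(np.argmax(prof.mean_n))  # argmax is leftmost on ties
    level = prof.mean_n[i_peak] / 2.0
    left, right = _half_max_side_crossings(prof.positions, prof.mean_n, level, i_peak)
    anterior = max(left) if left else None  # crossing nearest the peak
    posterior = min(right) if right else None
    return Border(anterior, posterior)


def border_noise(prof: ExpressionProfile) -> BorderBand:
    """Positional-uncertainty band of each half-max border.

    For each side of the peak, the band spans the crossings of the
    ``mean - sd`` and ``mean + sd`` envelopes with the half-max level of the
    mean profile; wider product-count fluctuations therefore translate
    directly into wider positional bands.
    """
    if prof.mean_n.max() <= 0:
        return BorderBand(None, None)
    i_peak = int(np.argmax(prof.mean_n))
    level = prof.mean_n[i_peak] / 2.0
    lo_curve = prof.mean_n - prof.sd_n
    hi_curve = prof.mean_n + prof.sd_n
    base = border_positions(prof)

    def band(side: str) -> tuple[float, float] | None:
        center = getattr(base, side)
        if center is None:
            return None
        pts = [center]
        for curve in (lo_curve, hi_curve):
            left, right = _half_max_side_crossings(
                prof.positions, curve, level, i_peak
            )
            cands = left if side == "anterior" else right
            if cands:
                # crossing nearest the mean border on that side
                pts.append(min(cands, key=lambda c: abs(c - center)))
        return (min(pts), max(pts))

    return BorderBand(band("anterior"), band("posterior"))


def gaussian_activation_lattice(
    base: PromoterParams,
    n_nodes: int = 51,
    center: float = 0.415,
    width: float = 0.08,
    f_peak: float | None = None,
    f_floor: float = 1e-3,
    t_snapshot: float | None = None,
) -> AxisLattice:
    """Axis lattice whose OFF->ON rate follows a Gaussian bump along x.

    This is the default positional input: an activator-like profile
    ``f(x) = f_floor + (f_peak - f_floor) * exp(-(x-center)^2 / 2 width^2)``
    peaked by default at 41.5% embryo length, the position of the modeled
    mRNA stripe.  Other rates are uniform and taken from ``base``.
    """
    if f_peak is None:
        f_peak = base.f if base.f > 0 else 1.0
    x = np.linspace(0.0, 1.0, n_nodes)
    fx = f_floor + (f_peak - f_floor) * np.exp(-((x - center) ** 2) / (2 * width**2))
    params = [dataclasses.replace(base, f=float(fi)) for fi in fx]
    return AxisLattice(x, params, t_snapshot)
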