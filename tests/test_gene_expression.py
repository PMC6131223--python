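"""Unit and property tests for the binary-promoter gene model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as scistats

from stochcell.gene_expression import (
    JointDistribution,
    Mode,
    PromoterParams,
    SolverError,
    covariance_xi,
    fano_factor,
    simulate_ssa,
    ssa_sample_states,
    steady_state,
    summary_stats,
    sweep_fano,
    transient_solve,
)


def poisson_marginal_dist(lam: float, n_max: int) -> JointDistribution:
    """All mass ON with a Poisson(lam) product marginal (test helper)."""
    p = scistats.poisson(lam).pmf(np.arange(n_max + 1))
    p /= p.sum()
    return JointDistribution(n_max, p, np.zeros(n_max + 1))


class TestParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            PromoterParams(k=-1, rho=1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mode=Mode.SRG, h2eff=1.0),
            dict(mode=Mode.ERG, h1=1.0),
            dict(mode=Mode.CONSTITUTIVE, h1=1.0),
        ],
    )
    def test_mode_rate_consistency(self, kwargs):
        with pytest.raises(ValueError):
            PromoterParams(k=1, rho=1, f=1, **kwargs)


class TestSteadyState:
    def test_no_synthesis_all_mass_at_zero(self):
        """k=0: the product count is 0; the promoter still partitions ON/OFF."""
        params = PromoterParams(k=0, rho=1, f=0.3, h2eff=0.7, mode=Mode.ERG)
        dist = steady_state(params)
        assert dist.pn[0] == pytest.approx(1.0, abs=1e-12)
        # promoter marginal is the two-state balance f / (f + h2eff)
        assert dist.p_on == pytest.approx(0.3 / (0.3 + 0.7), abs=1e-10)

    def test_constitutive_is_poisson(self):
        """An always-ON gene has Poisson(k/rho) products and F = 1."""
        params = PromoterParams(k=10, rho=1, mode=Mode.CONSTITUTIVE)
        dist = steady_state(params)
        expected = scistats.poisson(10).pmf(np.arange(dist.n_max + 1))
        tv = 0.5 * np.abs(dist.pn - expected).sum()
        assert tv < 1e-9
        assert fano_factor(dist) == pytest.approx(1.0, abs=1e-8)

    def test_erg_matches_literature_closed_form(self):
        """Slow-switching ERG Fano = 1 + k*h/((f+h)(f+h+rho))."""
        k, rho, f, h = 50.0, 1.0, 0.1, 0.1
        params = PromoterParams(k=k, rho=rho, f=f, h2eff=h, mode=Mode.ERG)
        dist = steady_state(params)
        closed = 1.0 + k * h / ((f + h) * (f + h + rho))
        assert fano_factor(dist) == pytest.approx(closed, rel=1e-8)
        # mean follows the two-state occupancy
        assert dist.mean_n == pytest.approx(k / rho * f / (f + h), rel=1e-8)

    def test_normalized_and_tail_controlled(self):
        params = PromoterParams(k=80, rho=1, f=2, h1=0.5, mode=Mode.SRG)
        dist = steady_state(params)
        assert dist.is_normalized()
        assert dist.tail_mass() < 1e-8

    def test_explicit_small_nmax_is_enlarged(self):
        params = PromoterParams(k=30, rho=1, mode=Mode.CONSTITUTIVE)
        dist = steady_state(params, n_max=4)
        assert dist.n_max > 4
        assert dist.mean_n == pytest.approx(30.0, rel=1e-8)

    def test_invalid_nmax(self):
        with pytest.raises(ValueError):
            steady_state(PromoterParams(k=1, rho=1, f=1), n_max=1)


class TestTransient:
    def test_t_zero_returns_init(self):
        params = PromoterParams(k=5, rho=1, f=1, h2eff=1, mode=Mode.ERG)
        init = steady_state(params)
        out = transient_solve(params, init, 0.0)
        np.testing.assert_array_equal(out.alpha, init.alpha)
        np.testing.assert_array_equal(out.beta, init.beta)

    def test_long_time_reaches_steady_state(self):
        params = PromoterParams(k=8, rho=1, f=2, h2eff=1, mode=Mode.ERG)
        init = JointDistribution(2, np.zeros(3), np.array([1.0, 0, 0]))
        out = transient_solve(params, init, 60.0)
        ss = steady_state(params)
        nm = max(out.n_max, ss.n_max)
        pa = np.zeros(nm + 1)
        pb = np.zeros(nm + 1)
        pa[: out.n_max + 1] = out.pn
        pb[: ss.n_max + 1] = ss.pn
        assert 0.5 * np.abs(pa - pb).sum() < 1e-6

    def test_constitutive_mean_relaxation_closed_form(self):
        """<n>(t) = (k/rho)(1 - e^{-rho t}) starting from n = 0."""
        params = PromoterParams(k=10, rho=1, mode=Mode.CONSTITUTIVE)
        init = JointDistribution(2, np.array([1.0, 0, 0]), np.zeros(3))
        for t in (0.25, 1.0, 3.0):
            out = transient_solve(params, init, t)
            assert out.mean_n == pytest.approx(10 * (1 - np.exp(-t)), rel=1e-7)

    def test_negative_time_rejected(self):
        params = PromoterParams(k=1, rho=1, f=1)
        init = JointDistribution(2, np.array([1.0, 0, 0]), np.zeros(3))
        with pytest.raises(ValueError):
            transient_solve(params, init, -1.0)


class TestSSA:
    def test_no_synthesis_count_frozen(self):
        params = PromoterParams(k=0, rho=1, f=2, h2eff=3, mode=Mode.ERG)
        traj = simulate_ssa(params, t_end=50.0, seed=7, n0=0)
        assert (traj.n_values == 0).all()
        assert len(traj.times) > 2  # promoter keeps toggling

    def test_same_seed_identical_trajectory(self):
        params = PromoterParams(k=5, rho=1, f=1, h1=0.2, mode=Mode.SRG)
        a = simulate_ssa(params, t_end=30.0, seed=123)
        b = simulate_ssa(params, t_end=30.0, seed=123)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.n_values, b.n_values)
        np.testing.assert_array_equal(a.promoter_states, b.promoter_states)

    def test_trajectory_invariants(self):
        params = PromoterParams(k=5, rho=1, f=1, h2eff=1, mode=Mode.ERG)
        traj = simulate_ssa(params, t_end=40.0, seed=5)
        assert (traj.n_values >= 0).all()
        assert (np.diff(traj.times) > 0).all()
        assert np.isin(np.diff(traj.n_values), (-1, 0, 1)).all()

    def test_empirical_histogram_approaches_solver(self):
        """TV(SSA, solver) shrinks as the sample grows (solver oracle)."""
        params = PromoterParams(k=10, rho=1, f=2, h2eff=2, mode=Mode.ERG)
        dist = steady_state(params)
        tvs = []
        for n_samples in (300, 6000):
            s = ssa_sample_states(params, seed=11, n_samples=n_samples)
            emp = np.bincount(s[:, 1], minlength=dist.n_max + 1)
            emp = emp[: dist.n_max + 1] / n_samples
            tvs.append(0.5 * np.abs(emp - dist.pn).sum())
        assert tvs[1] < tvs[0]
        assert tvs[1] < 0.05


class TestNoiseStatistics:
    def test_poisson_marginal_fano_one(self):
        dist = poisson_marginal_dist(12.0, 60)
        assert fano_factor(dist) == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_fano_zero(self):
        alpha = np.zeros(11)
        alpha[5] = 1.0
        dist = JointDistribution(10, alpha, np.zeros(11))
        assert fano_factor(dist) == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_rejected(self):
        alpha = np.zeros(11)
        alpha[0] = 1.0
        dist = JointDistribution(10, alpha, np.zeros(11))
        with pytest.raises(ValueError):
            fano_factor(dist)

    def test_mixture_fano_matches_brute_force(self):
        """F of 0.5*delta_0 + 0.5*Poisson(20), frozen from direct enumeration."""
        n_max = 80
        n = np.arange(n_max + 1)
        pois = scistats.poisson(20).pmf(n)
        p = 0.5 * np.eye(1, n_max + 1, 0).ravel() + 0.5 * pois
        p /= p.sum()
        # independent brute-force moments
        mean = float(p @ n)
        var = float(p @ (n**2)) - mean**2
        # closed enumeration: mean = 10, E[n^2] = 0.5*(400+20) = 210, var = 110
        dist = JointDistribution(n_max, p, np.zeros(n_max + 1))
        assert fano_factor(dist) == pytest.approx(var / mean, rel=1e-12)
        assert var / mean == pytest.approx(11.0, rel=1e-9)

    def test_xi_zero_under_independence(self):
        """k=0 freezes n at 0, so promoter and product are independent."""
        params = PromoterParams(k=0, rho=1, f=1, h2eff=1, mode=Mode.ERG)
        dist = steady_state(params)
        assert covariance_xi(dist, params) == pytest.approx(0.0, abs=1e-12)

    def test_erg_xi_over_mean_equals_fano_minus_one(self):
        params = PromoterParams(k=50, rho=1, f=0.1, h2eff=0.1, mode=Mode.ERG)
        stats = summary_stats(steady_state(params), params)
        assert stats.xi / stats.mean_n == pytest.approx(stats.fano - 1.0, abs=1e-8)

    def test_srg_switching_dominated_xi_negative(self):
        params = PromoterParams(k=50, rho=1, f=500, h1=500, mode=Mode.SRG)
        stats = summary_stats(steady_state(params), params)
        assert stats.xi < 0
        assert stats.fano < 1


class TestSweep:
    def test_single_point_equals_direct_solve(self):
        base = PromoterParams(k=20, rho=1, f=1, h2eff=1, mode=Mode.ERG)
        table = sweep_fano(base, [{}])
        stats = summary_stats(steady_state(base), base)
        assert len(table) == 1
        assert table.loc[0, "fano"] == pytest.approx(stats.fano, rel=1e-12)
        assert table.loc[0, "xi"] == pytest.approx(stats.xi, rel=1e-12)

    def test_srg_fast_switching_all_sub_poissonian(self):
        base = PromoterParams(k=50, rho=1, f=500, h1=500, mode=Mode.SRG)
        table = sweep_fano(base, {"f": [300, 500, 900], "h1": [300, 500, 900]})
        assert table["error"].isna().all()
        assert (table["fano"] < 1).all()

    def test_erg_sweep_all_super_poissonian(self):
        base = PromoterParams(k=50, rho=1, f=1, h2eff=1, mode=Mode.ERG)
        table = sweep_fano(base, {"f": [0.1, 1, 10], "h2eff": [0.1, 1, 10]})
        assert table["error"].isna().all()
        assert (table["fano"] >= 1 - 1e-10).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_fano(PromoterParams(k=1, rho=1, f=1), [])

    def test_per_point_failure_recorded_not_fatal(self):
        base = PromoterParams(k=5, rho=1, f=1, h2eff=1, mode=Mode.ERG)
        table = sweep_fano(base, [{"k": 5.0}, {"k": -3.0}])
        assert table.loc[0, "error"] is None or np.isnan(table.loc[0, "fano"]) is False
        assert isinstance(table.loc[1, "error"], str)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

_rates = st.floats(min_value=0.05, max_value=30.0)


@settings(max_examples=12, deadline=None, derandomize=True)
@given(k=st.floats(min_value=0.5, max_value=60.0), rho=_rates, f=_rates, h=_rates)
@pytest.mark.parametrize("mode", [Mode.SRG, Mode.ERG])
def test_solved_distributions_normalized_and_decomposed(mode, k, rho, f, h):
    """Normalization, F = 1 + xi/<n>, and sign(xi) = sign(F-1) everywhere."""
    kwargs = {"h1": h} if mode is Mode.SRG else {"h2eff": h}
    params = PromoterParams(k=k, rho=rho, f=f, mode=mode, **kwargs)
    dist = steady_state(params)
    assert abs(dist.total - 1.0) <= 1e-9
    stats = summary_stats(dist, params)
    assert stats.fano == pytest.approx(1.0 + stats.xi / stats.mean_n, abs=1e-8)
    if abs(stats.fano - 1.0) > 1e-9:
        assert np.sign(stats.xi) == np.sign(stats.fano - 1.0)


@settings(max_examples=8, deadline=None, derandomize=True)
@given(k=st.floats(min_value=1.0, max_value=30.0), rho=st.floats(min_value=0.2, max_value=3.0))
def test_poisson_limit_property(k, rho):
    """No switching and promoter ON gives F = 1 regardless of k, rho."""
    dist = steady_state(PromoterParams(k=k, rho=rho, mode=Mode.CONSTITUTIVE))
    assert fano_factor(dist) == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("mode", [Mode.CONSTITUTIVE, Mode.SRG, Mode.ERG])
def test_solver_and_ssa_agree_on_random_parameter_sets(mode):
    """Five random parameter draws per mode: TV(solver, SSA) within the
    bootstrap-estimated Monte-Carlo band at the used sample size."""
    rng = np.random.default_rng(2024)
    for rep in range(5):
        k = float(rng.uniform(3, 15))
        rho = float(rng.uniform(0.5, 2))
        f = float(rng.uniform(0.5, 5))
        h = float(rng.uniform(0.2, 3))
        if mode is Mode.CONSTITUTIVE:
            params = PromoterParams(k=k, rho=rho, mode=mode)
        elif mode is Mode.SRG:
            params = PromoterParams(k=k, rho=rho, f=f, h1=h, mode=mode)
        else:
            params = PromoterParams(k=k, rho=rho, f=f, h2eff=h, mode=mode)
        dist = steady_state(params)
        n_samples = 800
        s = ssa_sample_states(params, seed=100 + rep, n_samples=n_samples)
        top = max(dist.n_max, s[:, 1].max())
        emp = np.bincount(s[:, 1], minlength=top + 1) / n_samples
        p = np.zeros(top + 1)
        p[: dist.n_max + 1] = dist.pn
        tv = 0.5 * np.abs(emp - p).sum()
        null = np.array(
            [
                0.5 * np.abs(rng.multinomial(n_samples, p) / n_samples - p).sum()
                for _ in range(200)
            ]
        )
        assert tv <= null.mean() + 3 * null.std(), (mode, params, tv)


def test_srg_sub_fano_when_switching_dominates():
    """f and h1*<n> both >= 10x max(k, rho) force sub-Poissonian output."""
    for k, rho in ((20.0, 1.0), (50.0, 2.0)):
        bound = 10 * max(k, rho)
        params = PromoterParams(k=k, rho=rho, f=bound, h1=bound, mode=Mode.SRG)
        stats = summary_stats(steady_state(params), params)
        assert params.h1 * stats.mean_n >= bound  # regime precondition holds
        assert stats.fano < 1.0
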