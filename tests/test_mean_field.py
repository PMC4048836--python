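"""Mean-field aggregation-fragmentation model: kernels, moments, phases."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from aggrophase import mean_field as mf
from aggrophase.errors import (
    BracketingError,
    FitError,
    InvalidStateError,
    PreconditionError,
)
from aggrophase.etd import integrate_mf_etd
from aggrophase.mean_field import (
    MeanFieldParams,
    SizeDistribution,
    classify_phase,
    find_critical_kout,
    fit_growth_prefactor,
    integrate_mf,
    mean_polymer_length,
    phase_diagram_scan,
    steady_state_relation_residual,
    weighted_mass,
)


def dist(values, i_max=20, **kw):
    n = np.zeros(i_max)
    for i, v in values.items():
        n[i - 1] = v
    return SizeDistribution(n=n, **kw)


# ---------------------------------------------------------------- observables
@pytest.mark.parametrize(
    "values,expected",
    [({2: 5.0}, 2.0), ({2: 1.0, 4: 1.0}, 3.0), ({1: 100.0, 3: 2.0}, 3.0)],
)
def test_mean_polymer_length_excludes_monomers(values, expected):
    assert mean_polymer_length(dist(values)) == pytest.approx(expected)


def test_mean_polymer_length_undefined_without_polymers():
    assert np.isnan(mean_polymer_length(dist({1: 7.0})))


@pytest.mark.parametrize(
    "values,expected",
    [({1: 7.0}, 1.0), ({2: 3.0}, 2.0), ({1: 2.0, 4: 1.0}, 3.0)],
)
def test_weighted_mass(values, expected):
    assert weighted_mass(dist(values)) == pytest.approx(expected)


def test_weighted_mass_undefined_when_empty():
    assert np.isnan(weighted_mass(SizeDistribution(n=np.zeros(5))))


# ---------------------------------------------------------------- mf_rhs
def test_rhs_empty_system_is_zero():
    p = MeanFieldParams(k_p=1.0, k_f=0.5, k_out=1.0, i_max=20)
    d = mf.mf_rhs(SizeDistribution(n=np.zeros(20)), p)
    assert np.all(d.n == 0)


def test_rhs_pure_production_feeds_monomers_only():
    p = MeanFieldParams(k_in=0.7, k_p=0.0, i_max=20)
    d = mf.mf_rhs(SizeDistribution(n=np.zeros(20)), p)
    assert d.n[0] == pytest.approx(0.7)
    assert np.all(d.n[1:] == 0)


def test_rhs_dimerization_convention():
    """Pure monomers: dn1/dt = -k_p a^2, dn2/dt = (k_p/2) a^2.

    Cross-checked against a finite difference of a short integration with
    the same kernel.
    """
    a, kp = 0.8, 1.3
    p = MeanFieldParams(k_p=kp, i_max=20)
    d = mf.mf_rhs(dist({1: a}), p)
    assert d.n[0] == pytest.approx(-kp * a ** 2)
    assert d.n[1] == pytest.approx(0.5 * kp * a ** 2)
    # finite-difference oracle
    h = 1e-5
    traj = integrate_mf(p, dist({1: a}), np.array([0.0, h, 2 * h]),
                        rtol=1e-12, atol=1e-16)
    fd1 = (traj.n1[1] - traj.n1[0]) / h
    assert fd1 == pytest.approx(-kp * a ** 2, rel=1e-3)


def test_rhs_rejects_nonfinite_state():
    with pytest.raises(InvalidStateError):
        SizeDistribution(n=np.array([1.0, np.nan, 0.0]))


def test_moment_bookkeeping_of_kernels():
    """dM0 from aggregation alone is -(k_p/2) M0^2; from fragmentation alone
    +k_f (M1 - M0)."""
    rng = np.random.default_rng(3)
    n = np.zeros(100)
    n[:30] = rng.random(30)  # keep mass far from the truncation ceiling
    d_agg = mf.mf_rhs(SizeDistribution(n=n), MeanFieldParams(k_p=1.7, i_max=100))
    M0 = n.sum()
    assert d_agg.n.sum() == pytest.approx(-0.5 * 1.7 * M0 ** 2, rel=1e-10)
    d_frag = mf.mf_rhs(SizeDistribution(n=n), MeanFieldParams(k_p=0.0, k_f=0.3,
                                                              i_max=100))
    sizes = np.arange(1, 101)
    M1 = float(sizes @ n)
    assert d_frag.n.sum() == pytest.approx(0.3 * (M1 - M0), rel=1e-10)
    assert float(sizes @ d_frag.n) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------- integration
def test_mass_conservation_closed_system():
    p = MeanFieldParams(k_in=0.0, k_out=0.0, k_p=1.0, k_f=0.02, i_max=200)
    init = SizeDistribution.monomers(1.0, 200)
    traj = integrate_mf(p, init, mf.log_time_grid(0.01, 50, 60))
    drift = np.max(np.abs(traj.M1 - traj.M1[0])) / traj.M1[0]
    assert drift < 1e-6


def test_fragmentation_relaxes_to_monomers():
    p = MeanFieldParams(k_p=0.0, k_f=0.5, i_max=40)
    traj = integrate_mf(p, dist({10: 1.0}, i_max=40),
                        np.linspace(0, 100, 30))
    assert traj.M1[-1] == pytest.approx(traj.M1[0], rel=1e-8)
    assert traj.n1[-1] == pytest.approx(traj.M1[0], rel=1e-4)  # all monomers


def test_early_dimerization_growth_linear_in_t():
    """With only aggregation from monomers, m_w - 1 is linear in t at small t
    (halving t halves the excess)."""
    p = MeanFieldParams(k_p=1.0, i_max=50)
    init = SizeDistribution.monomers(1.0, 50)
    traj = integrate_mf(p, init, np.array([0.0, 5e-4, 1e-3]),
                        rtol=1e-11, atol=1e-16)
    e_half, e_full = traj.m_w[1] - 1, traj.m_w[2] - 1
    assert e_full / e_half == pytest.approx(2.0, rel=1e-2)
    assert np.all(np.diff(traj.m_w) > 0)


def test_truncation_doubling_oracle():
    """Direct integration at i_max and 2*i_max agree when the leak is tiny."""
    grid = mf.log_time_grid(0.1, 30, 40)
    init_small = SizeDistribution.monomers(1.0, 120)
    init_big = SizeDistribution.monomers(1.0, 240)
    a = integrate_mf(MeanFieldParams(k_p=1.0, k_f=0.1, i_max=120), init_small, grid)
    b = integrate_mf(MeanFieldParams(k_p=1.0, k_f=0.1, i_max=240), init_big, grid)
    assert a.leak_fraction < 1e-4
    for attr in ("M0", "M1", "M2"):
        rel = np.max(np.abs(getattr(a, attr)[1:] - getattr(b, attr)[1:])
                     / getattr(b, attr)[1:])
        assert rel < 1e-3


def test_etd_matches_reference_solver():
    p = MeanFieldParams(k_in=1, k_p=1, k_f=1e-3, k_out=1.0, c=5, i_max=400)
    grid = mf.log_time_grid(0.1, 100, 40)
    a = integrate_mf(p, SizeDistribution.empty(400), grid,
                     leak_threshold=np.inf)
    b = integrate_mf_etd(p, SizeDistribution.empty(400), grid, eta=0.4)
    sel = slice(5, None)
    assert np.nanmax(np.abs(b.m_p[sel] - a.m_p[sel]) / a.m_p[sel]) < 1e-4


def test_blatz_tobolsky_closed_steady_state_is_geometric():
    """Closed-system steady state n_i = (2 k_f/k_p) r^i with
    r/(1-r) = k_p M0 / (2 k_f)."""
    kp, kf = 1.0, 0.1
    p = MeanFieldParams(k_p=kp, k_f=kf, i_max=300)
    init = SizeDistribution.monomers(1.0, 300)
    traj = integrate_mf(p, init, np.array([0.0, 200.0, 400.0]), rtol=1e-10)
    n = traj.final_state.n
    sel = n > 1e-12
    i = np.arange(1, 301)[sel][:80]
    ln = np.log(n[sel][:80])
    fit = stats.linregress(i, ln)
    r = float(np.exp(fit.slope))
    M0 = traj.final_state.M0
    x = kp * M0 / (2 * kf)
    assert r == pytest.approx(x / (1 + x), rel=1e-3)
    A = float(np.exp(fit.intercept))
    assert A == pytest.approx(2 * kf / kp, rel=1e-2)


def test_c_independence_of_steady_state():
    """Steady observables converge in the degradation cutoff c."""
    mps = []
    for c in (5, 10):
        p = MeanFieldParams(k_in=1, k_p=1, k_f=0.1, k_out=10.0, c=c, i_max=300)
        state, drift = mf.run_to_steady_mf(p, 3000.0)
        assert drift < 1e-8
        mps.append(mean_polymer_length(state))
    assert abs(mps[0] - mps[1]) / mps[1] < 0.01


# ---------------------------------------------------------------- phases
def test_classify_growing_without_degradation():
    p = MeanFieldParams(k_in=1.0, k_p=1.0, k_f=0.1, k_out=0.0, c=1, i_max=400)
    traj = integrate_mf(p, SizeDistribution.empty(400),
                        mf.log_time_grid(0.5, 2000, 120),
                        leak_threshold=np.inf)
    assert classify_phase(traj).phase == "growing"


def test_classify_stationary_without_production():
    p = MeanFieldParams(k_in=0.0, k_p=1.0, k_f=0.5, k_out=2.0, c=1, i_max=60)
    traj = integrate_mf(p, dist({1: 0.5, 4: 0.2}, i_max=60),
                        mf.log_time_grid(0.1, 500, 80))
    assert classify_phase(traj).phase == "stationary"


def test_classify_undecided_on_truncated_run():
    """A growing run cut before its asymptotic regime stays undecided."""
    p = MeanFieldParams(k_in=1.0, k_p=1.0, k_f=0.1, k_out=8.0, c=1, i_max=400)
    traj = integrate_mf(p, SizeDistribution.empty(400),
                        mf.log_time_grid(0.05, 60, 60))
    assert classify_phase(traj).phase == "undecided"


def test_fit_growth_prefactor_recovers_generator():
    t = np.geomspace(1, 100, 60)
    traj = mf.MeanFieldTrajectory(
        times=t, M0=t, M1=t, M2=t, n1=np.zeros_like(t),
        m_w=np.ones_like(t), m_p=3.0 * t ** 0.5,
        params=MeanFieldParams(i_max=10),
        final_state=SizeDistribution(n=np.zeros(10)),
    )
    fit = fit_growth_prefactor(traj, (1, 100))
    assert fit.params["C"] == pytest.approx(3.0, rel=1e-8)
    assert fit.params["beta"] == pytest.approx(0.5, abs=1e-8)
    with pytest.raises(FitError):
        fit_growth_prefactor(traj, (1, 1.05))


def test_find_critical_kout_trivial_and_bracket_errors():
    p = MeanFieldParams(k_in=0.0, k_p=1.0, k_f=0.1, c=1, i_max=100)
    assert find_critical_kout(p, (1.0, 2.0), t_max=10.0) == (0.0, 0.0)
    p2 = MeanFieldParams(k_in=1.0, k_p=1.0, k_f=0.1, c=1, i_max=300)
    with pytest.raises(BracketingError):
        find_critical_kout(p2, (0.5, 1.0), t_max=300.0)  # both growing


def test_find_critical_kout_locates_c1_transition():
    """At c=1 the stationary/growing boundary sits at k_in k_p/(2 k_f);
    the bisected value at a finite horizon lands near it (biased high by
    slowly-relaxing supercritical points)."""
    p = MeanFieldParams(k_in=1.0, k_p=1.0, k_f=0.1, c=1, i_max=500)
    k, unc = find_critical_kout(p, (3.0, 8.0), t_max=3000.0, rel_width=0.05,
                                t_cap_factor=4)
    assert 4.5 <= k - unc <= k + unc + 1e-9
    assert abs(k - 5.0) <= max(1.0, unc + 0.5)


def test_phase_diagram_scan_monotone_and_ratio_invariant():
    base = MeanFieldParams(k_in=1.0, k_p=1.0, k_f=0.1, c=1, i_max=300)
    grid = [replace(base, k_out=v) for v in (0.0, 2.0, 10.0)]
    pts = phase_diagram_scan(grid, t_max=1500.0)
    assert pts[0].phase == "growing"
    assert pts[1].phase == "growing"
    assert pts[2].phase == "stationary"
    # in the large-k_f regime the phase depends on k_in k_p/(k_out k_f) only
    scaled = replace(base, k_in=2.0, k_f=0.2, k_out=10.0)  # same ratio as 10.0
    assert phase_diagram_scan([scaled], t_max=1500.0)[0].phase == "stationary"


# ---------------------------------------------------------------- c=1 identity
def test_steady_state_relation_holds_and_guards():
    p = MeanFieldParams(k_in=1.0, k_p=1.0, k_f=0.1, k_out=10.0, c=1, i_max=200)
    state, drift = mf.run_to_steady_mf(p, 2000.0)
    lhs = steady_state_relation_residual(p, state, drift=drift)
    assert lhs == pytest.approx(1.0, abs=1e-3)
    # perturbing M0 upward lowers the second term -> LHS < 1
    bigger = SizeDistribution(n=state.n * 1.1)
    assert steady_state_relation_residual(p, bigger) < lhs
    with pytest.raises(PreconditionError):
        steady_state_relation_residual(replace(p, c=5), state)
    with pytest.raises(PreconditionError):
        steady_state_relation_residual(replace(p, k_in=0.0),
                                       SizeDistribution(n=np.zeros(200)))


def test_activation_model_monotone_growth():
    """Activation layer: m_w rises monotonically from 1; inactive pool decays."""
    p = MeanFieldParams(k_p=1.0, k_A=1.0, i_max=200)
    init = SizeDistribution.monomers(1.0, 200, species="inactive")
    traj = integrate_mf(p, init, mf.log_time_grid(0.01, 20, 60))
    assert traj.m_w[0] == pytest.approx(1.0, abs=1e-6)
    assert np.all(np.diff(traj.m_w) >= -1e-9)
    assert traj.final_state.inactive < 1e-6 * traj.M1[-1]
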