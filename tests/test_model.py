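"""Time discretization, interval matrices, the joint coalescence matrix
and the HMM transition matrix."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from imcoal.model import (
    IsolationParameters,
    ModelParameters,
    discretize,
    discretize_isolation,
    hmm_transition,
    interval_chain,
    isolation_interval_chain,
    joint_matrix,
    upto,
)
from imcoal.states import StateClass, build_epoch_stack


def test_discretize_equal_widths():
    p = ModelParameters(0.001, 0.002, 1000.0, 0.4, 100.0)
    d = discretize(p, n_mig=10, n_anc=10)
    assert d.n == 20
    assert d.delta == pytest.approx(0.0001)
    assert d.breakpoints[10] == pytest.approx(0.002)
    assert np.all(np.diff(d.breakpoints[:-1]) > 0)
    assert np.isinf(d.breakpoints[-1])
    assert len(d.breakpoints) == 21


def test_discretize_degenerate_epoch_rejected():
    p = ModelParameters(0.001, 0.001, 1000.0, 0.4, 100.0)
    with pytest.raises(ValueError, match="degenerate"):
        discretize(p)


def test_discretize_isolation_span():
    p = IsolationParameters(0.002, 500.0, 0.4)
    d = discretize_isolation(p, n_intervals=20)
    assert d.n == 20 and d.n_mig == 0
    assert d.breakpoints[0] == pytest.approx(0.002)
    # default span 4/C
    assert d.delta == pytest.approx(4.0 / 500.0 / 20.0)


def test_interval_matrices_row_stochastic(short_epoch_params):
    chain = interval_chain(short_epoch_params)
    assert chain.alpha0.sum() == pytest.approx(1.0, abs=1e-10)
    for P in chain.mats:
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert P.min() > -1e-12


def test_interval_matrix_matches_ode_integration(short_epoch_params):
    """expm over one interval against independent ODE integration of the
    Kolmogorov forward equation dP/dt = P Q."""
    p = short_epoch_params
    stack = build_epoch_stack(p.coal_rate, p.rec_rate, p.mig_rate)
    delta = (p.tau2 - p.tau1) / 10
    P_expm = expm(stack.Q_mig * delta)
    n = stack.mig.size
    sol = solve_ivp(
        lambda _, y: (y.reshape(n, n) @ stack.Q_mig).ravel(),
        (0.0, delta),
        np.eye(n).ravel(),
        rtol=1e-12,
        atol=1e-14,
        method="DOP853",
    )
    P_ode = sol.y[:, -1].reshape(n, n)
    assert np.abs(P_expm - P_ode).max() < 1e-9


def test_delta_to_zero_limit_is_identity(short_epoch_params):
    p = short_epoch_params
    stack = build_epoch_stack(p.coal_rate, p.rec_rate, p.mig_rate)
    P = expm(stack.Q_mig * 1e-12)
    assert np.abs(P - np.eye(stack.mig.size)).max() < 1e-8


def test_upto_matrices_compose(short_epoch_params):
    chain = interval_chain(short_epoch_params)
    U = upto(chain, 0, 19)
    assert np.allclose(U.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(upto(chain, 0, 10) @ upto(chain, 10, 19), U, atol=1e-12)
    assert np.allclose(upto(chain, 3, 3), np.eye(chain.mats[3].shape[0]))


def test_joint_matrix_is_probability_and_symmetric(canonical_params):
    J = joint_matrix(interval_chain(canonical_params))
    assert J.min() >= 0
    assert J.sum() == pytest.approx(1.0, abs=1e-8)
    assert np.abs(J - J.T).max() < 1e-10


def test_joint_matrix_diagonal_when_no_recombination():
    p = ModelParameters(0.0005, 0.001, 1000.0, 0.0, 250.0)
    J = joint_matrix(interval_chain(p))
    assert J.sum() - np.trace(J) < 1e-10


def test_joint_matrix_no_migration_closed_form():
    """With M = 0 no coalescence can happen before tau2 and the marginal
    interval masses are truncated-exponential integrals at rate C."""
    p = ModelParameters(0.0005, 0.001, 1000.0, 0.4, 0.0)
    chain = interval_chain(p)
    J = joint_matrix(chain)
    marg = J.sum(axis=1)
    assert marg[:10].sum() < 1e-12
    bp = chain.disc.breakpoints
    C = p.coal_rate
    for i in range(10, 20):
        hi = 0.0 if np.isinf(bp[i + 1]) else np.exp(-C * (bp[i + 1] - p.tau2))
        expect = np.exp(-C * (bp[i] - p.tau2)) - hi
        assert marg[i] == pytest.approx(expect, abs=1e-8)


def test_no_migration_reduces_to_isolation_model():
    """The IM pipeline at M = 0 must equal the clean-split pipeline with
    split tau2 on the ancestral block of the discretization."""
    p = ModelParameters(0.0005, 0.001, 1000.0, 0.4, 0.0)
    chain = interval_chain(p, n_mig=10, n_anc=10)
    J_im = joint_matrix(chain)
    delta = chain.disc.delta
    iso = isolation_interval_chain(
        IsolationParameters(tau=p.tau2, coal_rate=p.coal_rate, rec_rate=p.rec_rate),
        n_intervals=10,
        span=10 * delta,
    )
    J_iso = joint_matrix(iso)
    assert np.abs(J_im[10:, 10:] - J_iso).max() < 1e-10
    assert J_im[:10, :].sum() < 1e-12


def test_strong_migration_approaches_half_coalescence_rate():
    """With M >> C the two demes mix instantly and the marginal
    coalescence rate inside the gene-flow window approaches C/2 (the two
    lineages share a deme half the time)."""
    C, tau1, tau2 = 1000.0, 0.0005, 0.001
    half = C / 2.0
    # at M = 1e4*C*(tau2-tau1) the initial cross-deme placement leaves a
    # mixing transient of duration ~1/(2M) = two interval widths, so the
    # 1% band is checked from interval 4 on; at larger M it holds
    # everywhere.
    for M, first in ((1e4 * C * (tau2 - tau1), 4), (1e6, 0)):
        p = ModelParameters(tau1, tau2, C, 0.4, M)
        chain = interval_chain(p)
        marg = joint_matrix(chain).sum(axis=1)
        bp = chain.disc.breakpoints
        for i in range(first, 10):
            expect = np.exp(-half * (bp[i] - tau1)) - np.exp(-half * (bp[i + 1] - tau1))
            assert marg[i] == pytest.approx(expect, rel=0.01)


def test_joint_matrix_prefix_dp_equals_naive_products():
    """On a 4-interval toy discretization the dynamic program must equal
    the naive class-restricted full-product sum exactly."""
    p = ModelParameters(0.0005, 0.001, 800.0, 0.5, 300.0)
    chain = interval_chain(p, n_mig=2, n_anc=2)
    J = joint_matrix(chain)
    n = chain.disc.n

    def naive(i, j):
        cls = chain.classes
        a = chain.alpha0.copy()
        mask = np.zeros_like(a)
        mask[cls[0][StateClass.B]] = 1
        a = a * mask
        if i == j:
            for k in range(i):
                a = a @ chain.mats[k]
                m = np.zeros_like(a)
                m[cls[k + 1][StateClass.B]] = 1
                a = a * m
            if i == n - 1:
                return a.sum()
            a = a @ chain.mats[i]
            return a[cls[i + 1][StateClass.E]].sum()
        lo, hi = min(i, j), max(i, j)
        side = StateClass.L if i < j else StateClass.R
        for k in range(lo):
            a = a @ chain.mats[k]
            m = np.zeros_like(a)
            m[cls[k + 1][StateClass.B]] = 1
            a = a * m
        a = a @ chain.mats[lo]
        m = np.zeros_like(a)
        m[cls[lo + 1][side]] = 1
        a = a * m
        for k in range(lo + 1, hi):
            a = a @ chain.mats[k]
            m = np.zeros_like(a)
            m[cls[k + 1][side]] = 1
            a = a * m
        if hi == n - 1:
            return a.sum()
        a = a @ chain.mats[hi]
        return a[cls[hi + 1][StateClass.E]].sum()

    for i in range(n):
        for j in range(n):
            assert J[i, j] == pytest.approx(naive(i, j), abs=1e-12)


def test_hmm_transition_conditional_properties(canonical_params):
    J = joint_matrix(interval_chain(canonical_params))
    T, pi = hmm_transition(J)
    assert np.allclose(T.sum(axis=1), 1.0, atol=1e-8)
    assert pi.sum() == pytest.approx(1.0, abs=1e-8)
    flux = pi[:, None] * T
    assert np.abs(flux - flux.T).max() < 1e-10  # detailed balance from J symmetry
    # stationarity of pi follows
    assert np.allclose(pi @ T, pi, atol=1e-10)


def test_hmm_transition_identity_when_no_recombination():
    p = ModelParameters(0.0005, 0.001, 1000.0, 0.0, 250.0)
    T, _ = hmm_transition(joint_matrix(interval_chain(p)))
    assert np.abs(T - np.eye(len(T))).max() < 1e-8


def test_hmm_transition_underflow_guard():
    J = np.array([[0.5, 0.0], [0.0, 0.5]])
    J[1] = 0.0  # second interval unreachable
    with pytest.warns(RuntimeWarning, match="vanishing occupancy"):
        T, pi = hmm_transition(J)
    assert np.allclose(T[1], 0.5)
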