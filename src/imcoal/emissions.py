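"""Emission probabilities: end-conditioned mean coalescence times and
Jukes-Cantor alignment-column probabilities.

Each hidden interval emits alignment columns as if the two sequences
diverged exactly at the interval's mean coalescence time, conditional on
coalescing inside the interval.  The one-nucleotide-per-genome CTMC (the
two-nucleotide system marginalised to a single site) gives the interval
coalescence masses; inside the migration epoch the end-conditioned mean
requires integrating t against the absorption density, done in closed
form through an eigendecomposition of the transient part of the rate
matrix.  In the panmictic ancestral epoch the waiting time is a plain
exponential and the truncated-exponential mean applies.

The migration-epoch generator is not reversible, so the eigendecomposition
may be complex; all final quantities are provably real and the imaginary
residue is asserted small before discarding it.  If the eigenvector matrix
is ill-conditioned the integrals fall back to adaptive quadrature of the
same integrand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.linalg import eig, expm

from .model import IsolationParameters, ModelParameters, TimeDiscretization
from .states import StateClass, build_epoch_stack, single_initial_state

__all__ = [
    "EndConditionedMeans",
    "single_nuc_stack",
    "single_nuc_interval_masses",
    "end_conditioned_means",
    "isolation_means",
    "jc_mismatch",
    "jc_emissions",
]

log = logging.getLogger(__name__)

_COND_LIMIT = 1e10  # eigenvector condition number beyond which we integrate numerically


@dataclass(frozen=True)
class EndConditionedMeans:
    """Per-interval expected coalescence time (conditional on coalescing in
    the interval, per-lineage substitution units) and interval masses."""

    mean: np.ndarray
    mass: np.ndarray


def single_nuc_stack(params: ModelParameters):
    """Epoch CTMCs for a single nucleotide per genome (no recombination is
    possible with one site, so the recombination rate is irrelevant)."""
    return build_epoch_stack(
        params.coal_rate, 0.0, params.mig_rate, initial=single_initial_state()
    )


def _alpha_at_breakpoints(params: ModelParameters, disc: TimeDiscretization, stack):
    """State distribution of the single-nucleotide CTMC at each break point
    of the migration epoch (over the migration-epoch state space)."""
    e0 = np.zeros(stack.iso.size)
    e0[stack.iso.initial] = 1.0
    alpha = e0 @ expm(stack.Q_iso * params.tau1) @ stack.injection
    delta = (params.tau2 - params.tau1) / disc.n_mig
    P = expm(stack.Q_mig * delta)
    out = [alpha]
    for _ in range(disc.n_mig):
        alpha = alpha @ P
        out.append(alpha)
    return np.array(out)


def single_nuc_interval_masses(
    params: ModelParameters, disc: TimeDiscretization, stack=None
) -> np.ndarray:
    """P(the two sequences coalesce in [t_i, t_{i+1})) for every hidden
    interval, from the single-nucleotide CTMC with the same epoch
    composition as the transition model.  Sums to 1."""
    if stack is None:
        stack = single_nuc_stack(params)
    alphas = _alpha_at_breakpoints(params, disc, stack)
    coal = stack.mig.class_indices(StateClass.E)
    F_mig = alphas[:, coal].sum(axis=1)  # CDF at t_0..t_{n_mig}
    C = params.coal_rate
    bp = disc.breakpoints
    surv_tau2 = 1.0 - F_mig[-1]
    F_anc = [
        1.0 - surv_tau2 * (0.0 if np.isinf(t) else np.exp(-C * (t - params.tau2)))
        for t in bp[disc.n_mig + 1 :]
    ]
    F = np.concatenate([F_mig, F_anc])
    mass = np.diff(F)
    # guard tiny negative round-off
    return np.clip(mass, 0.0, None)


def _integral_te(lam: np.ndarray, delta: float) -> np.ndarray:
    """int_0^Delta u * exp(lam u) du, elementwise; series for small lam."""
    out = np.empty_like(lam, dtype=complex)
    small = np.abs(lam) * delta < 1e-8
    l = lam[~small]
    out[~small] = delta * np.exp(l * delta) / l - (np.exp(l * delta) - 1.0) / l**2
    out[small] = delta**2 / 2.0 + lam[small] * delta**3 / 3.0
    return out


def _integral_e(lam: np.ndarray, delta: float) -> np.ndarray:
    """int_0^Delta exp(lam u) du, elementwise; series for small lam."""
    out = np.empty_like(lam, dtype=complex)
    small = np.abs(lam) * delta < 1e-8
    l = lam[~small]
    out[~small] = (np.exp(l * delta) - 1.0) / l
    out[small] = delta + lam[small] * delta**2 / 2.0
    return out


def _truncated_exp_mean(a: float, delta: float, C: float) -> float:
    """Mean of an Exp(C) arrival on [a, a + delta], conditioned to land there."""
    x = C * delta
    if x < 1e-12:
        return a + delta / 2.0
    return a + 1.0 / C - delta * np.exp(-x) / (1.0 - np.exp(-x))


def end_conditioned_means(
    params: ModelParameters, disc: TimeDiscretization, stack=None
) -> EndConditionedMeans:
    """Expected coalescence time for every hidden interval, conditional on
    coalescing within it.

    Migration-epoch intervals integrate t against the absorption density
    alpha_{t_i} expm(Q_tt u) c (c = rates from transient states into the
    coalesced state); by time homogeneity the integral over one interval
    width is evaluated once from the eigendecomposition of Q_tt and reused
    for every interval.  Ancestral intervals use the truncated-exponential
    closed form, the unbounded final interval t_{n-1} + 1/C.
    """
    if stack is None:
        stack = single_nuc_stack(params)
    alphas = _alpha_at_breakpoints(params, disc, stack)
    trans = np.flatnonzero(stack.mig.state_class != StateClass.E)
    coal = stack.mig.class_indices(StateClass.E)
    Qtt = stack.Q_mig[np.ix_(trans, trans)]
    c = stack.Q_mig[np.ix_(trans, coal)].sum(axis=1)
    delta = (params.tau2 - params.tau1) / disc.n_mig
    bp = disc.breakpoints
    C = params.coal_rate

    lam, V = eig(Qtt)
    cond = np.linalg.cond(V)
    use_spectral = np.isfinite(cond) and cond < _COND_LIMIT
    if use_spectral:
        Vinv = np.linalg.inv(V)
        # interval-independent accumulators: one Delta-integral per eigenvalue
        wt = V @ np.diag(_integral_te(lam, delta)) @ Vinv @ c.astype(complex)
        wm = V @ np.diag(_integral_e(lam, delta)) @ Vinv @ c.astype(complex)
    else:  # pragma: no cover - exercised only for pathological parameters
        log.info(
            "eigendecomposition ill-conditioned (cond=%.2e); "
            "falling back to adaptive quadrature", cond,
        )

    mean = np.empty(disc.n)
    mass = single_nuc_interval_masses(params, disc, stack=stack)
    for i in range(disc.n_mig):
        a = alphas[i][trans]
        if use_spectral:
            num = a @ wt
            den = a @ wm
            assert abs(num.imag) < 1e-9 * max(1.0, abs(num.real))
            assert abs(den.imag) < 1e-9 * max(1.0, abs(den.real))
            num, den = num.real, den.real
        else:
            f = lambda u: float(a @ expm(Qtt * u) @ c)
            num = quad(lambda u: u * f(u), 0.0, delta, limit=200)[0]
            den = quad(f, 0.0, delta, limit=200)[0]
        if den <= 0:
            mean[i] = bp[i] + delta / 2.0  # empty interval; value immaterial
        else:
            mean[i] = bp[i] + num / den
    for i in range(disc.n_mig, disc.n - 1):
        mean[i] = _truncated_exp_mean(bp[i], bp[i + 1] - bp[i], C)
    mean[disc.n - 1] = bp[disc.n - 1] + 1.0 / C
    return EndConditionedMeans(mean=mean, mass=mass)


def isolation_means(
    params: IsolationParameters, disc: TimeDiscretization
) -> EndConditionedMeans:
    """Interval means and masses of the clean-split model: coalescence is a
    plain Exp(C) clock after tau, so everything is closed form."""
    bp = disc.breakpoints
    C = params.coal_rate
    n = disc.n
    mean = np.empty(n)
    surv = np.exp(-C * (bp[:-1] - params.tau))
    mass = np.empty(n)
    for i in range(n - 1):
        mean[i] = _truncated_exp_mean(bp[i], bp[i + 1] - bp[i], C)
        mass[i] = surv[i] - surv[i + 1]
    mean[n - 1] = bp[n - 1] + 1.0 / C
    mass[n - 1] = surv[n - 1]
    return EndConditionedMeans(mean=mean, mass=mass)


def jc_mismatch(t: np.ndarray | float) -> np.ndarray | float:
    """Jukes-Cantor probability that two sequences separated by per-lineage
    time t (total path 2t) differ at a site: (3/4)(1 - exp(-8t/3))."""
    return 0.75 * (1.0 - np.exp(-(8.0 / 3.0) * np.asarray(t, dtype=float)))


def jc_emissions(means: EndConditionedMeans) -> np.ndarray:
    """Emission matrix e[i, s] over column symbols
    (IDENTICAL, DIFFERENT, MISSING).  Missing columns emit probability 1 in
    every state so they carry no information but preserve position."""
    p = jc_mismatch(means.mean)
    E = np.column_stack([1.0 - p, p, np.ones_like(p)])
    return E
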