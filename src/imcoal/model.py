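"""Time discretization and HMM transition probabilities.

The hidden states of the CoalHMM are time intervals in which the pair of
aligned nucleotides finds its most recent common ancestor.  Time is cut
into ``n_mig`` equal-width intervals covering the migration epoch
[tau1, tau2], and ``n_anc`` intervals of the same width extending into the
panmictic ancestral epoch, the last of which is unbounded.  No coalescence
can happen before tau1 (the samples sit in different demes with no gene
flow), so hidden time starts at tau1.

For each interval we compute the CTMC probability matrix by matrix
exponentials of the epoch rate matrices, composing the 0/1 injection and
projection bridges where an interval abuts an epoch boundary.  Summing
over all CTMC paths that keep the left nucleotide uncoalesced until
interval i and the right until interval j gives the joint matrix
J[i, j] = P(left coalesces in interval i, right in interval j); the HMM
transition matrix is the conditional T[i, j] = J[i, j] / pi[i] with
pi[i] = sum_j J[i, j].  The sums are evaluated with prefix accumulators
over intervals (a dynamic program) instead of full matrix products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .states import EpochStack, StateClass, StateSpace, build_epoch_stack

__all__ = [
    "ModelParameters",
    "IsolationParameters",
    "TimeDiscretization",
    "discretize",
    "discretize_isolation",
    "IntervalChain",
    "interval_chain",
    "isolation_interval_chain",
    "joint_matrix",
    "hmm_transition",
    "upto",
]


@dataclass(frozen=True)
class ModelParameters:
    """Demographic parameters of the isolation-with-migration model.

    All rates and times are scaled by the expected number of substitutions
    per site: ``tau1`` is the time gene flow ceased and ``tau2`` the
    initial population split (both backwards from the present),
    ``coal_rate`` the coalescence rate (inverse population size),
    ``rec_rate`` the recombination rate per adjacent-nucleotide link, and
    ``mig_rate`` the symmetric migration rate, active only on
    [tau1, tau2].
    """

    tau1: float
    tau2: float
    coal_rate: float
    rec_rate: float
    mig_rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.tau1 <= self.tau2:
            raise ValueError("need 0 <= tau1 <= tau2")
        if self.coal_rate <= 0:
            raise ValueError("coal_rate must be positive")
        if self.rec_rate < 0 or self.mig_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class IsolationParameters:
    """Parameters of the clean-split comparison model: a single split time
    ``tau`` with no gene flow afterwards."""

    tau: float
    coal_rate: float
    rec_rate: float

    def __post_init__(self) -> None:
        if self.tau < 0 or self.coal_rate <= 0 or self.rec_rate < 0:
            raise ValueError("invalid isolation-model parameters")


@dataclass(frozen=True)
class TimeDiscretization:
    """Hidden-interval break points t_0 < t_1 < ... < t_n = inf.

    ``breakpoints`` has length n+1 and starts at tau1 (or the split time
    of the isolation model); the final entry is +inf.  ``n_mig`` of the
    intervals lie inside the migration epoch.
    """

    breakpoints: np.ndarray
    n_mig: int
    n_anc: int

    @property
    def n(self) -> int:
        return self.n_mig + self.n_anc

    @property
    def delta(self) -> float:
        return float(self.breakpoints[1] - self.breakpoints[0])

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if len(bp) != self.n + 1 or not np.isinf(bp[-1]):
            raise ValueError("breakpoints must have n+1 entries ending at inf")
        if np.any(np.diff(bp[:-1]) <= 0):
            raise ValueError("breakpoints must be strictly increasing")


def discretize(
    params: ModelParameters,
    n_mig: int = 10,
    n_anc: int = 10,
    anc_span: float | None = None,
) -> TimeDiscretization:
    """Equally spaced break points: Delta = (tau2 - tau1)/n_mig inside the
    migration epoch, reused for the ancestral intervals unless ``anc_span``
    overrides the total finite ancestral span.  The last interval is
    [t_{n-1}, inf).
    """
    if params.tau2 <= params.tau1:
        raise ValueError("degenerate migration epoch: need tau2 > tau1")
    delta = (params.tau2 - params.tau1) / n_mig
    mig_bp = params.tau1 + delta * np.arange(n_mig + 1)
    delta_anc = delta if anc_span is None else anc_span / n_anc
    anc_bp = params.tau2 + delta_anc * np.arange(1, n_anc)
    bp = np.concatenate([mig_bp, anc_bp, [np.inf]])
    return TimeDiscretization(breakpoints=bp, n_mig=n_mig, n_anc=n_anc)


def discretize_isolation(
    params: IsolationParameters, n_intervals: int = 20, span: float | None = None
) -> TimeDiscretization:
    """Break points for the clean-split model: n equal intervals after the
    split.  The finite span defaults to 4 / coal_rate (≈98% of the
    post-split coalescence mass) with the final interval unbounded.
    """
    if span is None:
        span = 4.0 / params.coal_rate
    delta = span / n_intervals
    bp = params.tau + delta * np.arange(n_intervals)
    bp = np.concatenate([bp, [np.inf]])
    return TimeDiscretization(breakpoints=bp, n_mig=0, n_anc=n_intervals)


@dataclass
class IntervalChain:
    """Per-interval CTMC matrices plus the class partition at each break
    point, ready for the joint-coalescence dynamic program.

    ``alpha0`` is the state distribution at t_0 (the initial point mass
    evolved through the no-gene-flow epoch and injected / projected into
    the state space at t_0).  ``mats[i]`` maps states at t_i to states at
    t_{i+1} for i < n-1; the unbounded final interval is handled by
    absorption.  ``classes[k][cls]`` are the state indices of class
    ``cls`` in the space at break point t_k.
    """

    alpha0: np.ndarray
    mats: list[np.ndarray]
    classes: list[dict[StateClass, np.ndarray]]
    disc: TimeDiscretization
    stack: EpochStack


def _class_table(space: StateSpace) -> dict[StateClass, np.ndarray]:
    return {cls: space.class_indices(cls) for cls in StateClass}


def interval_chain(
    params: ModelParameters,
    disc: TimeDiscretization | None = None,
    stack: EpochStack | None = None,
    n_mig: int = 10,
    n_anc: int = 10,
    anc_span: float | None = None,
) -> IntervalChain:
    """Assemble the interval matrices of the IM model.

    The isolated epoch [0, tau1] contributes a single factor
    expm(Q_iso * tau1) composed with the injection, prepended to interval
    0; the first ancestral interval composes the projection.  Because the
    break points are equally spaced, one matrix exponential per epoch is
    reused for all its interior intervals.
    """
    if disc is None:
        disc = discretize(params, n_mig=n_mig, n_anc=n_anc, anc_span=anc_span)
    if stack is None:
        stack = build_epoch_stack(params.coal_rate, params.rec_rate, params.mig_rate)
    delta = (params.tau2 - params.tau1) / disc.n_mig
    delta_anc = float(disc.breakpoints[disc.n_mig + 1] - disc.breakpoints[disc.n_mig]) \
        if disc.n_anc > 1 else delta

    P_mig = expm(stack.Q_mig * delta)
    P_anc = expm(stack.Q_anc * delta_anc)
    if not (np.all(np.isfinite(P_mig)) and np.all(np.isfinite(P_anc))):
        raise FloatingPointError("matrix exponential produced non-finite entries")

    e0 = np.zeros(stack.iso.size)
    e0[stack.iso.initial] = 1.0
    alpha0 = e0 @ expm(stack.Q_iso * params.tau1) @ stack.injection

    mats: list[np.ndarray] = []
    classes: list[dict[StateClass, np.ndarray]] = []
    for i in range(disc.n - 1):
        if i < disc.n_mig - 1:
            mats.append(P_mig)
        elif i == disc.n_mig - 1:
            mats.append(P_mig @ stack.projection)
        else:
            mats.append(P_anc)
    for k in range(disc.n):
        classes.append(_class_table(stack.mig if k < disc.n_mig else stack.anc))
    return IntervalChain(alpha0=alpha0, mats=mats, classes=classes, disc=disc, stack=stack)


def isolation_interval_chain(
    params: IsolationParameters,
    n_intervals: int = 20,
    span: float | None = None,
    stack: EpochStack | None = None,
) -> IntervalChain:
    """Interval matrices of the clean-split model: the two populations stay
    isolated until tau, then merge directly into the panmictic ancestor
    (the migration epoch has zero width)."""
    disc = discretize_isolation(params, n_intervals=n_intervals, span=span)
    if stack is None:
        stack = build_epoch_stack(params.coal_rate, params.rec_rate, 0.0)
    delta = float(disc.breakpoints[1] - disc.breakpoints[0])
    P_anc = expm(stack.Q_anc * delta)
    e0 = np.zeros(stack.iso.size)
    e0[stack.iso.initial] = 1.0
    alpha0 = e0 @ expm(stack.Q_iso * params.tau) @ stack.injection @ stack.projection
    mats = [P_anc] * (disc.n - 1)
    classes = [_class_table(stack.anc) for _ in range(disc.n)]
    return IntervalChain(alpha0=alpha0, mats=mats, classes=classes, disc=disc, stack=stack)


def upto(chain: IntervalChain, i: int, j: int) -> np.ndarray:
    """State-transition probabilities from the start of interval i to the
    start of interval j (matrix product of the interval matrices)."""
    if not 0 <= i <= j <= chain.disc.n - 1:
        raise ValueError("need 0 <= i <= j <= n-1")
    n_i = chain.mats[i].shape[0] if i < len(chain.mats) else chain.mats[-1].shape[1]
    U = np.eye(n_i)
    for k in range(i, j):
        U = U @ chain.mats[k]
    return U


def joint_matrix(chain: IntervalChain) -> np.ndarray:
    """J[i, j] = P(left nucleotide coalesces in interval i, right in j).

    A path contributing to J[i, j] with i < j is in class B at break
    points t_0..t_i, in L at t_{i+1}..t_j and in E at t_{j+1}; the final
    unbounded interval absorbs all remaining mass (coalescence is
    certain).  Prefix accumulators over intervals avoid O(n^2) full
    products: the B-mass vector is pushed forward once, and for each entry
    interval the L- (and symmetrically R-) mass vector is pushed forward
    across later intervals.
    """
    n = chain.disc.n
    J = np.zeros((n, n))
    B0 = chain.classes[0][StateClass.B]
    mass_outside_B = chain.alpha0.sum() - chain.alpha0[B0].sum()
    if mass_outside_B > 1e-12:
        raise ValueError("initial distribution has mass outside class B")
    alphaB = chain.alpha0[B0]

    for i in range(n):
        if i == n - 1:
            J[i, i] += alphaB.sum()
            break
        P = chain.mats[i]
        cls_i = chain.classes[i]
        cls_n = chain.classes[i + 1]
        B_i, B_n = cls_i[StateClass.B], cls_n[StateClass.B]
        L_n, R_n, E_n = (cls_n[StateClass.L], cls_n[StateClass.R], cls_n[StateClass.E])
        PB = P[np.ix_(B_i, B_n)]
        J[i, i] += alphaB @ P[np.ix_(B_i, E_n)].sum(axis=1)
        vL = alphaB @ P[np.ix_(B_i, L_n)]
        vR = alphaB @ P[np.ix_(B_i, R_n)]
        for j in range(i + 1, n):
            if j == n - 1:
                J[i, j] += vL.sum()
                J[j, i] += vR.sum()
                break
            Pj = chain.mats[j]
            cj, cjn = chain.classes[j], chain.classes[j + 1]
            J[i, j] += vL @ Pj[np.ix_(cj[StateClass.L], cjn[StateClass.E])].sum(axis=1)
            J[j, i] += vR @ Pj[np.ix_(cj[StateClass.R], cjn[StateClass.E])].sum(axis=1)
            vL = vL @ Pj[np.ix_(cj[StateClass.L], cjn[StateClass.L])]
            vR = vR @ Pj[np.ix_(cj[StateClass.R], cjn[StateClass.R])]
        alphaB = alphaB @ PB
    return J


def hmm_transition(J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Conditional transition matrix and initial distribution of the HMM:
    T[i, j] = J[i, j] / pi[i] with pi[i] = sum_j J[i, j].  By the
    left/right symmetry of J, pi is stationary for T and T is in detailed
    balance.  Rows with vanishing pi get a uniform fallback.
    """
    pi = J.sum(axis=1)
    n = len(pi)
    T = np.empty_like(J)
    tiny = pi < 1e-300
    if np.any(tiny):
        warnings.warn(
            f"{int(tiny.sum())} hidden interval(s) have vanishing occupancy; "
            "using uniform transition rows",
            RuntimeWarning,
        )
    T[~tiny] = J[~tiny] / pi[~tiny, None]
    T[tiny] = 1.0 / n
    return T, pi
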