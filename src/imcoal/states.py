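"""Structured-coalescent state spaces and rate matrices.

The ancestry of one or two neighbouring nucleotides in a two-deme
demography is a finite continuous-time Markov chain.  A *lineage* carries
ancestral material for the left and right nucleotide, each a subset of the
sampled sequences {1, 2}; a *state* is a set of lineages, each assigned to
a deme.  Events are

* coalescence  -- two lineages in the same deme merge (per-side set union,
  allowed when the per-side materials are disjoint or empty),
* recombination -- a lineage carrying material on both sides splits into a
  left-only and a right-only lineage, and
* migration    -- a lineage switches deme (only in epochs with gene flow).

When a side's material reaches the full sample set {1, 2} that nucleotide
has found its most recent common ancestor and the material is dropped from
the lineage: the chain is lumped over the (irrelevant) further history of
coalesced material, so the fully-coalesced state is the single empty,
absorbing state.  This lumping is exact because every pair of lineages in
a deme coalesces at the same rate, so events that only involve dropped
material never change the distribution over the retained states.

Ancestral material per side is encoded as a bitmask: 0 = none, 1 = {1},
2 = {2}; the union 3 = {1, 2} is mapped to 0 at the moment of coalescence.
A lineage is an ``(left, right, deme)`` triple and a state a frozenset of
such triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "TransitionKind",
    "StateClass",
    "EpochRates",
    "StateSpace",
    "EpochStack",
    "enumerate_state_space",
    "build_rate_matrix",
    "build_epoch_stack",
    "pair_initial_state",
    "single_initial_state",
    "serialize_state",
]

Lineage = tuple[int, int, int]  # (left material, right material, deme)
State = frozenset  # frozenset[Lineage]

FULL = 3  # bitmask of the full sample set {1, 2}


class TransitionKind(Enum):
    COALESCENCE = "C"
    RECOMBINATION = "R"
    MIGRATION = "M"


class StateClass(Enum):
    """Which nucleotides have found their MRCA in a state."""

    B = "B"  # neither
    L = "L"  # left only
    R = "R"  # right only
    E = "E"  # both


@dataclass(frozen=True)
class EpochRates:
    """Event rates for one epoch, in units of expected substitutions.

    ``coal`` maps deme index to the coalescence rate (inverse population
    size) in that deme; ``rec`` is the recombination rate per
    adjacent-nucleotide link per lineage; ``mig`` the symmetric migration
    rate per lineage (must be 0 when the epoch's state space has no
    migration edges).
    """

    coal: dict[int, float]
    rec: float
    mig: float = 0.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.coal.values()) or self.rec < 0 or self.mig < 0:
            raise ValueError("rates must be non-negative")


def pair_initial_state() -> State:
    """Two fully linked sequences, one per deme: {1|1 in deme 0, 2|2 in deme 1}."""
    return frozenset({(1, 1, 0), (2, 2, 1)})


def single_initial_state() -> State:
    """One-nucleotide system: sequence 1 in deme 0, sequence 2 in deme 1."""
    return frozenset({(1, 0, 0), (2, 0, 1)})


def _validate_state(state: State, n_demes: int) -> None:
    left_union = 0
    right_union = 0
    for l, r, d in state:
        if not (0 <= l <= 2 and 0 <= r <= 2):
            raise ValueError(f"bad material encoding in lineage {(l, r, d)}")
        if l == 0 and r == 0:
            raise ValueError("lineage with no ancestral material")
        if not 0 <= d < n_demes:
            raise ValueError(f"deme {d} out of range for {n_demes} demes")
        if left_union & l or right_union & r:
            raise ValueError("ancestral material is not a partition across lineages")
        left_union |= l
        right_union |= r
    if left_union not in (0, FULL) or right_union not in (0, FULL):
        raise ValueError("per-side material must be empty (coalesced) or all of {1,2}")


def classify(state: State) -> StateClass:
    left = 0
    right = 0
    for l, r, _ in state:
        left |= l
        right |= r
    if left and right:
        return StateClass.B
    if right:
        return StateClass.L  # left coalesced
    if left:
        return StateClass.R
    return StateClass.E


def _merge_side(a: int, b: int) -> int | None:
    """Union of two side materials; None if they overlap, 0 if MRCA is reached."""
    if a & b:
        return None
    u = a | b
    return 0 if u == FULL else u


def _transitions(state: State, allow_migration: bool, n_demes: int):
    """Yield (kind, deme, successor) for every single event from ``state``."""
    lineages = sorted(state)
    n = len(lineages)
    # coalescence: unordered pairs in the same deme
    for i in range(n):
        li, ri, di = lineages[i]
        for j in range(i + 1, n):
            lj, rj, dj = lineages[j]
            if di != dj:
                continue
            lm = _merge_side(li, lj)
            rm = _merge_side(ri, rj)
            if lm is None or rm is None:
                continue  # overlapping material cannot coalesce
            new = set(state)
            new.discard(lineages[i])
            new.discard(lineages[j])
            if lm or rm:
                new.add((lm, rm, di))
            yield TransitionKind.COALESCENCE, di, frozenset(new)
    for lin in lineages:
        l, r, d = lin
        # recombination: split a doubly linked lineage
        if l and r:
            new = set(state)
            new.discard(lin)
            new.add((l, 0, d))
            new.add((0, r, d))
            yield TransitionKind.RECOMBINATION, d, frozenset(new)
        # migration: move a lineage to the other deme
        if allow_migration and n_demes == 2:
            new = set(state)
            new.discard(lin)
            new.add((l, r, 1 - d))
            yield TransitionKind.MIGRATION, d, frozenset(new)


def serialize_state(state: State) -> str:
    """Canonical one-line text form, e.g. ``{1|1}@0 {2|2}@1`` (sorted)."""
    if not state:
        return "-"
    parts = []
    for l, r, d in sorted(state):
        ls = ",".join(str(s) for s in (1, 2) if l & (1 << (s - 1))) or "."
        rs = ",".join(str(s) for s in (1, 2) if r & (1 << (s - 1))) or "."
        parts.append(f"{{{ls}|{rs}}}@{d}")
    return " ".join(parts)


def _canonical_key(state: State):
    return (len(state), tuple(sorted(state)))


@dataclass
class StateSpace:
    """Indexed closure of a state under the epoch's transitions."""

    states: list[State]
    index: dict[State, int]
    edges: list[tuple[int, int, TransitionKind, int]]  # (from, to, kind, deme)
    state_class: np.ndarray  # array of StateClass per index
    initial: int
    n_demes: int

    @property
    def size(self) -> int:
        return len(self.states)

    def class_indices(self, cls: StateClass) -> np.ndarray:
        return np.flatnonzero(self.state_class == cls)

    def to_debug_text(self) -> str:
        lines = []
        for i, s in enumerate(self.states):
            lines.append(f"{i}\t{self.state_class[i].value}\t{serialize_state(s)}")
        return "\n".join(lines) + "\n"


def enumerate_state_space(
    initial: State, n_demes: int = 2, allow_migration: bool = True
) -> StateSpace:
    """Breadth-first closure of ``initial`` under coalescence, recombination
    and migration, with deterministic canonical indexing.
    """
    if n_demes not in (1, 2):
        raise ValueError("n_demes must be 1 or 2")
    initial = frozenset(initial)
    _validate_state(initial, n_demes)
    seen = {initial}
    frontier = [initial]
    while frontier:
        nxt = []
        for s in frontier:
            for _, _, succ in _transitions(s, allow_migration, n_demes):
                if succ not in seen:
                    seen.add(succ)
                    nxt.append(succ)
        frontier = nxt
    states = sorted(seen, key=_canonical_key)
    index = {s: i for i, s in enumerate(states)}
    edges = []
    for s in states:
        i = index[s]
        for kind, deme, succ in _transitions(s, allow_migration, n_demes):
            edges.append((i, index[succ], kind, deme))
    cls = np.array([classify(s) for s in states], dtype=object)
    return StateSpace(
        states=states,
        index=index,
        edges=edges,
        state_class=cls,
        initial=index[initial],
        n_demes=n_demes,
    )


def build_rate_matrix(space: StateSpace, rates: EpochRates) -> np.ndarray:
    """Assemble the CTMC generator: off-diagonal entries accumulate the rates
    of every single event mapping state i to state j, diagonals make rows
    sum to zero.  The fully-coalesced state has an all-zero (absorbing) row.
    """
    n = space.size
    Q = np.zeros((n, n))
    for i, j, kind, deme in space.edges:
        if kind is TransitionKind.COALESCENCE:
            rate = rates.coal[deme]
        elif kind is TransitionKind.RECOMBINATION:
            rate = rates.rec
        else:
            rate = rates.mig
        Q[i, j] += rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class EpochStack:
    """The three epoch CTMCs of the isolation-with-migration demography and
    the 0/1 bridges between their state spaces.

    ``iso``: two demes, no migration (present back to tau1).
    ``mig``: two demes with migration (tau1 to tau2).
    ``anc``: one panmictic deme (beyond tau2).
    ``injection`` maps iso states into the mig space (identity on shared
    structure); ``projection`` maps mig states onto anc states by
    relabelling every lineage to deme 0.
    """

    iso: StateSpace
    mig: StateSpace
    anc: StateSpace
    Q_iso: np.ndarray
    Q_mig: np.ndarray
    Q_anc: np.ndarray
    injection: np.ndarray
    projection: np.ndarray


def _project_to_deme0(state: State) -> State:
    moved = {}
    for l, r, _ in state:
        key = (l, r, 0)
        if key in moved:
            raise AssertionError("projection produced duplicate lineage")
        moved[key] = None
    return frozenset(moved)


_SPACE_CACHE: dict[tuple, StateSpace] = {}


def _cached_space(initial: State, n_demes: int, allow_migration: bool) -> StateSpace:
    key = (tuple(sorted(initial)), n_demes, allow_migration)
    if key not in _SPACE_CACHE:
        _SPACE_CACHE[key] = enumerate_state_space(initial, n_demes, allow_migration)
    return _SPACE_CACHE[key]


def build_epoch_stack(
    coal_rate: float,
    rec_rate: float,
    mig_rate: float,
    *,
    coal_rate_anc: float | None = None,
    coal_rates_by_deme: dict[int, float] | None = None,
    initial: State | None = None,
) -> EpochStack:
    """Build the three epoch rate matrices and bridges for a parameter set.

    ``coal_rates_by_deme`` optionally gives distinct present-day deme rates;
    the ancestral deme uses ``coal_rate_anc`` (defaults to the shared rate).
    """
    if initial is None:
        initial = pair_initial_state()
    iso = _cached_space(initial, 2, False)
    mig = _cached_space(initial, 2, True)
    anc_initial = _project_to_deme0(initial)
    anc = _cached_space(anc_initial, 1, False)

    coal = coal_rates_by_deme or {0: coal_rate, 1: coal_rate}
    Q_iso = build_rate_matrix(iso, EpochRates(coal=coal, rec=rec_rate, mig=0.0))
    Q_mig = build_rate_matrix(mig, EpochRates(coal=coal, rec=rec_rate, mig=mig_rate))
    anc_coal = coal_rate if coal_rate_anc is None else coal_rate_anc
    Q_anc = build_rate_matrix(anc, EpochRates(coal={0: anc_coal}, rec=rec_rate, mig=0.0))

    injection = np.zeros((iso.size, mig.size))
    for s, i in iso.index.items():
        injection[i, mig.index[s]] = 1.0
    projection = np.zeros((mig.size, anc.size))
    for s, i in mig.index.items():
        projection[i, anc.index[_project_to_deme0(s)]] = 1.0
    return EpochStack(
        iso=iso, mig=mig, anc=anc,
        Q_iso=Q_iso, Q_mig=Q_mig, Q_anc=Q_anc,
        injection=injection, projection=projection,
    )
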