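"""State-space enumeration and rate-matrix construction.

The independent oracle here is a second, deliberately different closure
implementation: lineages are represented as frozensets of sample labels
(not bitmasks), the worklist is a stack (depth-first, reversed insertion)
rather than a BFS queue, and the transition rules are written from the
verbal definitions.  The two enumerations must agree state-set for
state-set under a common serialization.
"""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from imcoal.states import (
    EpochRates,
    StateClass,
    TransitionKind,
    build_epoch_stack,
    build_rate_matrix,
    enumerate_state_space,
    pair_initial_state,
    single_initial_state,
    serialize_state,
)

# ---------------------------------------------------------------------------
# brute-force oracle: frozenset-of-frozensets representation, DFS closure
# ---------------------------------------------------------------------------

FULL = frozenset({1, 2})


def _oracle_successors(state, allow_migration):
    succ = set()
    lineages = list(state)
    for (la, ra, da), (lb, rb, db) in itertools.combinations(lineages, 2):
        if da != db:
            continue
        if la & lb or ra & rb:
            continue
        lu, ru = la | lb, ra | rb
        lu = frozenset() if lu == FULL else lu
        ru = frozenset() if ru == FULL else ru
        new = set(state) - {(la, ra, da), (lb, rb, db)}
        if lu or ru:
            new.add((lu, ru, da))
        succ.add(frozenset(new))
    for lin in lineages:
        l, r, d = lin
        if l and r:
            new = set(state) - {lin}
            new |= {(l, frozenset(), d), (frozenset(), r, d)}
            succ.add(frozenset(new))
        if allow_migration:
            new = set(state) - {lin}
            new.add((l, r, 1 - d))
            succ.add(frozenset(new))
    return succ


def _oracle_closure(initial, allow_migration):
    seen = {initial}
    stack = [initial]
    while stack:
        s = stack.pop()
        for nxt in _oracle_successors(s, allow_migration):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def _as_oracle_state(state):
    conv = {0: frozenset(), 1: frozenset({1}), 2: frozenset({2})}
    return frozenset((conv[l], conv[r], d) for l, r, d in state)


@pytest.mark.parametrize("allow_migration", [True, False])
def test_enumeration_matches_bruteforce_closure(allow_migration):
    space = enumerate_state_space(pair_initial_state(), 2, allow_migration)
    oracle = _oracle_closure(_as_oracle_state(pair_initial_state()), allow_migration)
    ours = {_as_oracle_state(s) for s in space.states}
    assert ours == oracle


def test_state_space_sizes_regression():
    # frozen from the brute-force oracle above
    assert enumerate_state_space(pair_initial_state(), 2, True).size == 65
    assert enumerate_state_space(pair_initial_state(), 2, False).size == 4
    assert enumerate_state_space(frozenset({(1, 1, 0), (2, 2, 0)}), 1, False).size == 10
    assert enumerate_state_space(single_initial_state(), 2, True).size == 5


def test_single_deme_single_nucleotide_has_two_configurations():
    space = enumerate_state_space(frozenset({(1, 0, 0), (2, 0, 0)}), 1, False)
    assert space.size == 2  # two separate lineages, or their MRCA (empty state)
    kinds = {kind for _, _, kind, _ in space.edges}
    assert kinds == {TransitionKind.COALESCENCE}


def test_migration_disabled_yields_no_migration_edges():
    space = enumerate_state_space(pair_initial_state(), 2, False)
    assert all(kind is not TransitionKind.MIGRATION for _, _, kind, _ in space.edges)


def test_enumeration_order_independent():
    # the canonical index must not depend on traversal order; the DFS
    # oracle above already traverses differently, here we also check the
    # serialized listing is sorted and stable
    space = enumerate_state_space(pair_initial_state(), 2, True)
    again = enumerate_state_space(pair_initial_state(), 2, True)
    assert [serialize_state(s) for s in space.states] == [
        serialize_state(s) for s in again.states
    ]
    keys = [(len(s), tuple(sorted(s))) for s in space.states]
    assert keys == sorted(keys)


def test_malformed_initial_state_rejected():
    with pytest.raises(ValueError):
        enumerate_state_space(frozenset({(1, 1, 0), (1, 2, 1)}), 2, True)
    with pytest.raises(ValueError):
        enumerate_state_space(frozenset({(1, 1, 0), (2, 2, 5)}), 2, True)


# ---------------------------------------------------------------------------
# rate matrices
# ---------------------------------------------------------------------------

def test_rate_matrix_generator_properties(short_epoch_params):
    p = short_epoch_params
    space = enumerate_state_space(pair_initial_state(), 2, True)
    Q = build_rate_matrix(
        space, EpochRates(coal={0: p.coal_rate, 1: p.coal_rate}, rec=p.rec_rate, mig=p.mig_rate)
    )
    assert np.abs(Q.sum(axis=1)).max() < 1e-12
    off = Q - np.diag(np.diag(Q))
    assert off.min() >= 0
    absorbing = [i for i, c in enumerate(space.state_class) if c is StateClass.E]
    assert len(absorbing) == 1
    assert np.all(Q[absorbing[0]] == 0)


def test_two_lineage_coalescence_rate_is_C():
    space = enumerate_state_space(frozenset({(1, 0, 0), (2, 0, 0)}), 1, False)
    C = 123.0
    Q = build_rate_matrix(space, EpochRates(coal={0: C}, rec=0.7, mig=0.0))
    i = space.index[frozenset({(1, 0, 0), (2, 0, 0)})]
    j = space.index[frozenset()]
    assert Q[i, j] == pytest.approx(C)


def test_fully_linked_pair_diagonal_is_C_plus_2R():
    space = enumerate_state_space(frozenset({(1, 1, 0), (2, 2, 0)}), 1, False)
    C, R = 50.0, 3.0
    Q = build_rate_matrix(space, EpochRates(coal={0: C}, rec=R, mig=0.0))
    i = space.index[frozenset({(1, 1, 0), (2, 2, 0)})]
    assert Q[i, i] == pytest.approx(-(C + 2 * R))


def test_negative_rate_rejected():
    with pytest.raises(ValueError):
        EpochRates(coal={0: -1.0}, rec=0.0, mig=0.0)


# ---------------------------------------------------------------------------
# epoch stack and bridges
# ---------------------------------------------------------------------------

def test_migration_zero_reduces_to_isolated_generator():
    stack = build_epoch_stack(1000.0, 0.4, 0.0)
    img = stack.injection.argmax(axis=1)
    assert np.allclose(stack.Q_mig[np.ix_(img, img)], stack.Q_iso)


def test_projection_relabels_demes():
    stack = build_epoch_stack(1000.0, 0.4, 250.0)
    for s, i in stack.mig.index.items():
        j = int(stack.projection[i].argmax())
        assert stack.anc.states[j] == frozenset((l, r, 0) for l, r, _ in s)
    assert np.all(stack.projection.sum(axis=1) == 1)
    assert np.all(stack.injection.sum(axis=1) == 1)


def test_ancestral_matrix_matches_direct_single_deme_build():
    C, R = 777.0, 0.3
    stack = build_epoch_stack(C, R, 100.0)
    space = enumerate_state_space(frozenset({(1, 1, 0), (2, 2, 0)}), 1, False)
    Q = build_rate_matrix(space, EpochRates(coal={0: C}, rec=R, mig=0.0))
    assert np.allclose(stack.Q_anc, Q)


def test_pair_chain_marginalises_to_single_nucleotide_chain():
    """Left-side MRCA probability from the two-nucleotide CTMC must match
    the one-nucleotide CTMC at any time (exact lumping check)."""
    C, R, M = 800.0, 0.5, 300.0
    pair = build_epoch_stack(C, R, M)
    single = build_epoch_stack(C, 0.0, M, initial=single_initial_state())
    e_pair = np.zeros(pair.mig.size)
    e_pair[pair.mig.index[pair_initial_state()]] = 1.0
    e_single = np.zeros(single.mig.size)
    e_single[single.mig.index[single_initial_state()]] = 1.0
    left_done = np.array(
        [c in (StateClass.L, StateClass.E) for c in pair.mig.state_class]
    )
    coal = np.array([c is StateClass.E for c in single.mig.state_class])
    for t in (1e-4, 5e-4, 2e-3):
        p_pair = e_pair @ expm(pair.Q_mig * t)
        p_single = e_single @ expm(single.Q_mig * t)
        assert p_pair[left_done].sum() == pytest.approx(p_single[coal].sum(), abs=1e-8)


def test_debug_text_export_roundtrips_states():
    space = enumerate_state_space(pair_initial_state(), 2, True)
    text = space.to_debug_text()
    lines = text.strip().split("\n")
    assert len(lines) == space.size
    assert lines[space.initial].split("\t")[2] == serialize_state(pair_initial_state())
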