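"""Exact coalescent-with-recombination simulator for the two-deme
isolation-with-migration demography, plus the robustness perturbations
used in the validation study.

The simulator runs the full (non-Markov) ancestral recombination graph
backwards in time: lineages carry ancestral material as intervals over
[0, L); within-deme pairs coalesce at the coalescence rate, lineages
recombine at the per-link rate over their breakable span (trapped
non-ancestral material included, so lineages can coalesce back — the
behaviour the Markov-approximate HMM cannot capture), and lineages migrate
during the gene-flow window [tau1, tau2] only.  The demes merge at tau2.
Times are in expected substitutions per site, matching the inference
model.

Sequences are then generated over the local genealogies with the
Jukes-Cantor model, optionally with block-wise mutation-rate multipliers
(geometric block lengths, uniform factors) or a per-link recombination
map.  Unknown genome phase is emulated by random-allele mosaics of two
within-deme samples.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .model import ModelParameters, TimeDiscretization
from .states import StateClass, build_epoch_stack, pair_initial_state
from .symbols import DIFFERENT, IDENTICAL

__all__ = [
    "SimConfig",
    "TmrcaTrack",
    "SimulatedAlignment",
    "simulate_arg",
    "mutate",
    "simulate_alignment",
    "perturb_mutation_rate",
    "synthetic_recombination_map",
    "random_phase_mosaic",
    "gillespie_two_nucleotide",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated alignment.

    ``params`` are the demographic parameters (substitution units), ``L``
    the number of sites, ``n_per_deme`` the haploid samples per deme (1
    for the standard pairwise analyses, 2 for the phase experiments).
    ``mut_blocks`` optionally gives (mean block length, low factor, high
    factor) for block-wise mutation-rate variation; ``rec_map`` an
    optional per-link multiplier vector of length L-1.
    """

    params: ModelParameters
    L: int
    seed: int
    n_per_deme: int = 1
    mut_blocks: tuple[float, float, float] | None = None
    rec_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("need at least two sites")
        if self.n_per_deme not in (1, 2):
            raise ValueError("n_per_deme must be 1 or 2")
        if self.rec_map is not None and len(self.rec_map) != self.L - 1:
            raise ValueError("rec_map must have L-1 entries")


@dataclass
class TmrcaTrack:
    """Piecewise-constant per-site coalescence time of the two cross-deme
    samples, as half-open [start, end) runs."""

    starts: np.ndarray
    ends: np.ndarray
    times: np.ndarray

    def per_site(self, L: int) -> np.ndarray:
        out = np.empty(L)
        for s, e, t in zip(self.starts, self.ends, self.times):
            out[s:e] = t
        return out


@dataclass
class SimulatedAlignment:
    """Simulated sequences (rows = samples, first all deme-0 samples) and
    the genealogical record they were generated from."""

    seqs: np.ndarray  # (n_samples, L) uint8 codes 0..3
    track: TmrcaTrack
    config: SimConfig

    @property
    def n_samples(self) -> int:
        return self.seqs.shape[0]

    def columns(self, i: int = 0, j: int | None = None) -> np.ndarray:
        """Column-symbol sequence for one pair of samples (defaults to the
        cross-deme pair)."""
        if j is None:
            j = self.config.n_per_deme
        return np.where(self.seqs[i] == self.seqs[j], IDENTICAL, DIFFERENT).astype(np.int8)

    def to_fasta(self, names: list[str] | None = None) -> str:
        if names is None:
            names = [f"sample_{i}" for i in range(self.n_samples)]
        recs = []
        for name, row in zip(names, self.seqs):
            recs.append(f">{name}\n{BASES[row].tobytes().decode()}")
        return "\n".join(recs) + "\n"


# ---------------------------------------------------------------------------
# ancestral recombination graph
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("segs", "deme", "span_w")

    def __init__(self, segs, deme, Wc):
        self.segs = segs  # list of (start, end, mask), sorted, non-adjacent merged
        self.deme = deme
        first = segs[0][0]
        last = segs[-1][1] - 1
        self.span_w = Wc[last] - Wc[first]  # breakable-link weight


def _merge_segments(a, b, full_mask, pieces, time):
    """Union of two segment lists.  Overlapping material with both masks
    non-empty is a coalescence of ancestral material and is recorded in
    ``pieces``; if the union reaches the full sample set the material has
    found its MRCA and is dropped."""
    out = []
    ia = ib = 0
    ca = cb = None  # current remainders
    while True:
        if ca is None and ia < len(a):
            ca = a[ia]; ia += 1
        if cb is None and ib < len(b):
            cb = b[ib]; ib += 1
        if ca is None and cb is None:
            break
        if cb is None or (ca is not None and ca[1] <= cb[0]):
            out.append(ca); ca = None; continue
        if ca is None or cb[1] <= ca[0]:
            out.append(cb); cb = None; continue
        # overlap
        s1, e1, m1 = ca
        s2, e2, m2 = cb
        lo = max(s1, s2)
        if s1 < lo:
            out.append((s1, lo, m1)); ca = (lo, e1, m1)
        elif s2 < lo:
            out.append((s2, lo, m2)); cb = (lo, e2, m2)
        s1, e1, m1 = ca
        s2, e2, m2 = cb
        hi = min(e1, e2)
        m = m1 | m2
        pieces.append((lo, hi, m1, m2, time))
        if m != full_mask:
            out.append((lo, hi, m))
        ca = (hi, e1, m1) if hi < e1 else None
        cb = (hi, e2, m2) if hi < e2 else None
    # merge adjacent runs with equal masks to keep lists short
    merged = []
    for seg in out:
        if merged and merged[-1][1] == seg[0] and merged[-1][2] == seg[2]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


def simulate_arg(config: SimConfig):
    """Run the backwards ARG and return (pieces, n_samples).

    ``pieces`` is a list of (start, end, maskA, maskB, time) records, one
    per coalescence of ancestral material over a maximal interval: the two
    child clades (sample bitmasks) joining at that time over those sites.
    The per-site genealogy of any interval is the time-ordered list of
    pieces covering it.
    """
    p = config.params
    rng = np.random.default_rng(config.seed)
    L = config.L
    n = 2 * config.n_per_deme
    full = (1 << n) - 1
    w = np.ones(L - 1) if config.rec_map is None else np.asarray(config.rec_map, float)
    Wc = np.concatenate([[0.0], np.cumsum(w)])  # Wc[k] = weight of links < k

    lineages: list[_Lineage] = []
    for s in range(n):
        deme = 0 if s < config.n_per_deme else 1
        lineages.append(_Lineage([(0, L, 1 << s)], deme, Wc))

    pieces: list[tuple] = []
    t = 0.0
    boundaries = [(p.tau1, "open_flow"), (p.tau2, "merge")]
    bi = 0
    mig_active = p.tau1 == 0.0 and p.tau2 > 0.0
    C, R, M = p.coal_rate, p.rec_rate, p.mig_rate

    while lineages:
        k0 = sum(1 for l in lineages if l.deme == 0)
        k1 = len(lineages) - k0
        rate_coal = C * (k0 * (k0 - 1) / 2 + k1 * (k1 - 1) / 2)
        rec_w = [l.span_w for l in lineages]
        rate_rec = R * sum(rec_w)
        rate_mig = M * len(lineages) if mig_active else 0.0
        total = rate_coal + rate_rec + rate_mig
        if total <= 0 and bi >= len(boundaries):
            raise RuntimeError("ARG stalled with uncoalesced material")  # unreachable
        t_next = t + (rng.exponential(1.0 / total) if total > 0 else np.inf)
        if bi < len(boundaries) and t_next >= boundaries[bi][0]:
            t, action = boundaries[bi]
            bi += 1
            if action == "open_flow":
                mig_active = True
            else:  # merge demes; gene flow window over
                mig_active = False
                M = 0.0
                for l in lineages:
                    l.deme = 0
            continue
        t = t_next
        u = rng.random() * total
        if u < rate_coal:
            # choose a deme weighted by its pair count, then a uniform pair
            pairs0 = k0 * (k0 - 1) / 2
            deme = 0 if rng.random() * (pairs0 + k1 * (k1 - 1) / 2) < pairs0 else 1
            idx = [i for i, l in enumerate(lineages) if l.deme == deme]
            i, j = rng.choice(len(idx), size=2, replace=False)
            a, b = lineages[idx[i]], lineages[idx[j]]
            segs = _merge_segments(a.segs, b.segs, full, pieces, t)
            for k in sorted((idx[i], idx[j]), reverse=True):
                lineages.pop(k)
            if segs:
                lineages.append(_Lineage(segs, deme, Wc))
        elif u < rate_coal + rate_rec:
            # lineage weighted by breakable-link weight, link by map weight
            v = (u - rate_coal) / R
            acc = 0.0
            for li, lw in enumerate(rec_w):
                acc += lw
                if v <= acc or li == len(lineages) - 1:
                    break
            lin = lineages[li]
            first = lin.segs[0][0]
            last = lin.segs[-1][1] - 1
            # link j in [first, last): split between sites j and j+1
            uw = Wc[first] + rng.random() * (Wc[last] - Wc[first])
            j = int(np.searchsorted(Wc, uw, side="right")) - 1
            j = min(max(j, first), last - 1)
            left = [(s, min(e, j + 1), m) for s, e, m in lin.segs if s <= j]
            right = [(max(s, j + 1), e, m) for s, e, m in lin.segs if e > j + 1]
            lineages.pop(li)
            if left:
                lineages.append(_Lineage(left, lin.deme, Wc))
            if right:
                lineages.append(_Lineage(right, lin.deme, Wc))
        else:
            li = rng.integers(len(lineages))
            lineages[li].deme = 1 - lineages[li].deme
    return pieces, n


def _pieces_to_track(pieces, n_per_deme: int, L: int) -> TmrcaTrack:
    """Extract the TMRCA of the cross-deme pair (first sample of each deme)."""
    a_bit = 1 << 0
    b_bit = 1 << n_per_deme
    runs = []
    for s, e, mA, mB, t in pieces:
        u = mA | mB
        if (u & a_bit) and (u & b_bit) and not (
            (mA & a_bit and mA & b_bit) or (mB & a_bit and mB & b_bit)
        ):
            runs.append((s, e, t))
    runs.sort()
    starts = np.array([r[0] for r in runs], dtype=np.int64)
    ends = np.array([r[1] for r in runs], dtype=np.int64)
    times = np.array([r[2] for r in runs])
    return TmrcaTrack(starts=starts, ends=ends, times=times)


def _local_forest(pieces, L: int):
    """Yield (start, end, merges) for maximal intervals with a constant
    genealogy; ``merges`` is the time-sorted list of (maskA, maskB, time)."""
    events = sorted(pieces)  # by start
    cuts = sorted({0, L, *(p[0] for p in events), *(p[1] for p in events)})
    heap: list[tuple] = []  # (end, maskA, maskB, time)
    ei = 0
    for s, e in zip(cuts[:-1], cuts[1:]):
        while ei < len(events) and events[ei][0] <= s:
            ps, pe, mA, mB, t = events[ei]
            heapq.heappush(heap, (pe, t, mA, mB))
            ei += 1
        while heap and heap[0][0] <= s:
            heapq.heappop(heap)
        merges = sorted((t, mA, mB) for _, t, mA, mB in heap)
        yield s, e, merges


def mutate(
    pieces,
    n_samples: int,
    config: SimConfig,
    rate_mult: np.ndarray | None = None,
) -> np.ndarray:
    """Generate Jukes-Cantor sequences over the local genealogies.

    The root base of each site is uniform over {A, C, G, T}; along a
    branch of length t (times the site's rate multiplier) the base is
    redrawn uniformly from all four with probability 1 - exp(-4t/3),
    giving JC transition probabilities exactly.
    """
    rng = np.random.default_rng(config.seed + 1 if config.seed is not None else None)
    L = config.L
    seqs = np.empty((n_samples, L), dtype=np.uint8)
    for s, e, merges in _local_forest(pieces, L):
        k = e - s
        mult = rate_mult[s:e] if rate_mult is not None else None
        # node bases indexed by clade bitmask; build top-down after
        # computing each clade's parent time bottom-up
        node_time = {1 << i: 0.0 for i in range(n_samples)}
        children: list[tuple[int, int, int, float]] = []  # (parent, childA, childB, t)
        for t, mA, mB in merges:
            parent = mA | mB
            node_time[parent] = t
            children.append((parent, mA, mB, t))
        # bases: start every clade that has no parent ("root" of its tree)
        has_parent = set()
        for parent, mA, mB, _ in children:
            has_parent.add(mA)
            has_parent.add(mB)
        bases: dict[int, np.ndarray] = {}
        for m in node_time:
            if m not in has_parent:
                bases[m] = rng.integers(0, 4, size=k, dtype=np.uint8)
        for parent, mA, mB, t in sorted(children, key=lambda c: -c[3]):
            pb = bases[parent]
            for child in (mA, mB):
                blen = t - node_time[child]
                eff = blen * mult if mult is not None else blen
                pr = 1.0 - np.exp(-(4.0 / 3.0) * eff)
                redraw = rng.random(k) < pr
                cb = pb.copy()
                if np.any(redraw):
                    cb[redraw] = rng.integers(0, 4, size=int(redraw.sum()), dtype=np.uint8)
                bases[child] = cb
        for i in range(n_samples):
            seqs[i, s:e] = bases[1 << i]
    return seqs


def perturb_mutation_rate(
    L: int, mean_block: float, low: float, high: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-site mutation-rate multipliers: blocks of geometrically
    distributed length (given mean), each with a factor drawn uniformly
    from [low, high]."""
    if mean_block < 1:
        raise ValueError("mean block length must be >= 1")
    if not 0 < low <= high:
        raise ValueError("factor range must be positive")
    out = np.empty(L)
    pos = 0
    pgeom = 1.0 / mean_block
    while pos < L:
        blen = int(rng.geometric(pgeom))
        out[pos : pos + blen] = rng.uniform(low, high)
        pos += blen
    return out


def synthetic_recombination_map(
    L: int, rng: np.random.Generator, block: int = 20000, sigma: float = 0.7
) -> np.ndarray:
    """A map-like per-link multiplier vector: lognormal block multipliers
    with autocorrelation from averaging neighbouring blocks, normalised to
    mean 1.  A synthetic stand-in for an empirical recombination map."""
    nb = (L - 1) // block + 1
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=nb + 1)
    smooth = 0.5 * (raw[:-1] + raw[1:])
    per_link = np.repeat(smooth, block)[: L - 1]
    return per_link / per_link.mean()


def simulate_alignment(config: SimConfig) -> SimulatedAlignment:
    """Simulate the ARG and sequences under the study conditions."""
    pieces, n = simulate_arg(config)
    rate_mult = None
    if config.mut_blocks is not None:
        mean_block, low, high = config.mut_blocks
        rng = np.random.default_rng(config.seed + 2)
        rate_mult = perturb_mutation_rate(config.L, mean_block, low, high, rng)
    seqs = mutate(pieces, n, config, rate_mult=rate_mult)
    track = _pieces_to_track(pieces, config.n_per_deme, config.L)
    return SimulatedAlignment(seqs=seqs, track=track, config=config)


def random_phase_mosaic(seqs: np.ndarray, n_per_deme: int, seed: int) -> np.ndarray:
    """One pseudo-haploid sequence per deme: at every position where the
    two within-deme samples differ, pick either allele with probability
    1/2 independently."""
    if seqs.shape[0] != 2 * n_per_deme or n_per_deme != 2:
        raise ValueError("random-phase mosaics need two samples per deme")
    rng = np.random.default_rng(seed)
    out = np.empty((2, seqs.shape[1]), dtype=seqs.dtype)
    for d in range(2):
        a, b = seqs[2 * d], seqs[2 * d + 1]
        pick_b = rng.random(seqs.shape[1]) < 0.5
        out[d] = np.where(pick_b, b, a)
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo oracle for the transition model
# ---------------------------------------------------------------------------

def gillespie_two_nucleotide(
    params: ModelParameters,
    disc: TimeDiscretization,
    n_paths: int,
    seed: int,
) -> np.ndarray:
    """Empirical joint coalescence-interval matrix from exact event-driven
    simulation of the two-nucleotide CTMC with epoch switching at tau1 and
    tau2.  Returns counts / n_paths on the discretization's intervals."""
    rng = np.random.default_rng(seed)
    stack = build_epoch_stack(params.coal_rate, params.rec_rate, params.mig_rate)
    inj = stack.injection.argmax(axis=1)
    proj = stack.projection.argmax(axis=1)

    t = np.zeros(n_paths)
    left_t = np.full(n_paths, np.nan)
    right_t = np.full(n_paths, np.nan)
    state = np.full(n_paths, stack.iso.initial, dtype=np.int64)

    for space, Q, t_end in (
        (stack.iso, stack.Q_iso, params.tau1),
        (stack.mig, stack.Q_mig, params.tau2),
        (stack.anc, stack.Q_anc, np.inf),
    ):
        exit_rate = -np.diag(Q)
        P = np.where(exit_rate[:, None] > 0, Q / np.where(exit_rate, exit_rate, 1.0)[:, None], 0.0)
        np.fill_diagonal(P, 0.0)
        cum = np.cumsum(P, axis=1)
        is_left_done = np.array(
            [c in (StateClass.L, StateClass.E) for c in space.state_class]
        )
        is_right_done = np.array(
            [c in (StateClass.R, StateClass.E) for c in space.state_class]
        )
        active = np.arange(n_paths)
        while active.size:
            rates = exit_rate[state[active]]
            dt = np.where(rates > 0, rng.exponential(1.0, active.size) / np.where(rates, rates, 1.0), np.inf)
            t_new = t[active] + dt
            crossed = t_new >= t_end
            jumping = active[~crossed]
            t[jumping] = t_new[~crossed]
            if jumping.size:
                u = rng.random(jumping.size)
                rows = cum[state[jumping]]
                state[jumping] = (u[:, None] > rows).sum(axis=1)
                newly_left = jumping[is_left_done[state[jumping]] & np.isnan(left_t[jumping])]
                left_t[newly_left] = t[newly_left]
                newly_right = jumping[is_right_done[state[jumping]] & np.isnan(right_t[jumping])]
                right_t[newly_right] = t[newly_right]
            active = jumping
        # epoch boundary: clamp time and map indices
        if np.isfinite(t_end):
            t[:] = np.maximum(t, t_end)
            if space is stack.iso:
                state = inj[state]
            else:
                state = proj[state]

    bp = disc.breakpoints
    li = np.clip(np.searchsorted(bp, left_t, side="right") - 1, 0, disc.n - 1)
    ri = np.clip(np.searchsorted(bp, right_t, side="right") - 1, 0, disc.n - 1)
    J = np.zeros((disc.n, disc.n))
    np.add.at(J, (li, ri), 1.0)
    return J / n_paths
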