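# Methods

## The model

`imcoal` infers the demographic history of two closely related species
(or populations) from a pairwise alignment of one haploid genome per
species.  Divergence is modelled as an isolation-with-migration (IM)
history with three epochs, looking backwards from the present:

1. **Isolation** `[0, tau1)` — the two populations are separate and
   exchange no migrants.  The two sampled lineages sit in different
   demes, so no cross coalescence can happen here.
2. **Gene flow** `[tau1, tau2)` — the populations are separate but
   exchange migrants at a symmetric rate `M` per lineage.  Lineages that
   migrate into a shared deme may coalesce.
3. **Ancestral panmixia** `[tau2, inf)` — a single randomly mating
   ancestral population.

All times and rates are scaled by the expected number of substitutions
per site: `tau1` and `tau2` are substitution distances, `C` is the
coalescence rate (the inverse of the population-scaled mutation depth;
`N_e = 1/(2 C mu_g)` for per-generation mutation rate `mu_g`), `R` the
recombination rate per adjacent-base link, and `M` the migration rate.
`C`, `R` and `M` are assumed constant in time and across lineages, and
migration symmetric; these restrictions keep the model identifiable from
a single genome pair.

### From coalescent to hidden Markov model

The genealogy underlying a recombining alignment is not Markov along the
sequence, but the ancestry of any *two adjacent nucleotides* is a finite
continuous-time Markov chain (CTMC) whose states are sets of lineages
carrying left/right ancestral material, each assigned to a deme, and
whose events are coalescence, recombination and migration
(`imcoal.states`).  The state spaces are enumerated generatively (65
states for the two-deme gene-flow epoch, 4 for the isolated epoch, 10
for the panmictic ancestor); 0/1 injection/projection matrices bridge the
epochs.  Material that reaches the full sample set has found its MRCA and
is dropped from the state — an exact lumping (every lineage pair in a
deme coalesces at the same rate), which makes the fully-coalesced state a
single absorbing state.

Time from `tau1` onwards is discretized into `n_mig + n_anc` intervals
(default 10 + 10, following the standard choice for this model class):
equal widths `Delta = (tau2 - tau1)/n_mig` in the gene-flow window,
reused in the ancestral epoch, with the final interval unbounded.  Matrix
exponentials of the epoch generators give per-interval transition
matrices, and a dynamic program over interval prefixes yields the joint
probability `J[i, j]` that the left nucleotide coalesces in interval `i`
and the right in interval `j`.  The HMM over alignment columns then has

* hidden states: the coalescence interval of a column,
* initial distribution `pi[i] = sum_j J[i, j]` (the marginal, which by
  the left/right symmetry of `J` is also the stationary distribution),
* transitions `T[i, j] = J[i, j] / pi[i]` (in detailed balance),
* emissions from the Jukes-Cantor mismatch probability
  `p_i = 3/4 (1 - exp(-8 t_i / 3))` at the interval's *end-conditioned
  mean* coalescence time `t_i` (total tree length `2 t_i` for two
  sequences).  Columns reduce to IDENTICAL / DIFFERENT / MISSING;
  missing columns emit probability 1 in every state, contributing no
  information while preserving genomic coordinates.

The end-conditioned means in the gene-flow window integrate
`t x (absorption density)` of the single-nucleotide CTMC over one
interval, evaluated in closed form through an eigendecomposition of the
transient generator block (complex arithmetic, provably real results;
imaginary residue asserted < 1e-9, with an adaptive-quadrature fallback
if the eigenvector matrix is ill-conditioned).  Ancestral intervals use
the truncated-exponential mean `a + 1/C - Delta e^{-C Delta}/(1 -
e^{-C Delta})`; the unbounded final interval `t_{n-1} + 1/C`.

### Likelihood and estimation

The forward algorithm runs over a run-length encoding of the column
sequence: a run of `k` equal symbols advances the forward vector by
`(T diag(e_s))^k` via renormalised binary powers, so cost scales with the
number of runs (tens of thousands per Mbp) rather than positions.  A
numba-compiled kernel implements the inner loop, with a pure-numpy
fallback; both are exact scaled recursions and are tested against each
other and against exhaustive path enumeration.

Parameters are estimated by Nelder-Mead on log-transformed coordinates;
the IM model optimizes `(log tau1, log(tau2 - tau1), log C, log R,
log M)` so the constraint `tau1 <= tau2` never binds.  Starting values
come from a method-of-moments argument: the Jukes-Cantor distance fixes
`tau2 + 1/C` jointly, split evenly; `tau1 = tau2/2`; `M = 100`; and
`R = 4e-4 C` (the canonical great-ape ratio of ~0.8 cM/Mb to 1e-9
substitutions/bp/yr — a moment estimator for `R` from a genome pair does
not exist, so the start only needs the right order of magnitude).
Optional seeded log-normal restarts guard against local optima.  The
clean-split isolation model (I) shares all machinery with a single split
`tau` and no migration epoch; model choice uses
`AIC = 2k - 2 log L` with `k = 5` (IM) vs `k = 3` (I), reported as
`delta = AIC(I) - AIC(IM)` (positive prefers gene flow; at the nested
boundary `delta -> -4` exactly).

### Numerical choices

* **Ancestral interval width.**  The equal-width rule is used whenever
  `Delta >= 0.4/C`; for more recent splits the width is floored at
  `0.4/C` so the finite intervals always cover ~98% (`4/C`) of the
  post-split coalescence mass.  Without the floor, a split much more
  recent than `1/C` would leave nearly all mass in the single unbounded
  interval and the discretization would carry no resolution.  The
  `anc_span` argument overrides the span explicitly.
* **Isolation-model span.**  The I model discretizes `[tau, tau + 4/C)`
  into equal intervals plus the unbounded tail.
* **Underflow.**  Forward vectors and power matrices are renormalised
  with accumulated logs; hidden intervals with vanishing occupancy
  (`pi < 1e-300`, reachable in degenerate optimizer corners) get uniform
  transition rows and a warning.
* **Ties/degenerate inputs.**  `tau1 = tau2` is rejected for the IM
  discretization (use the I model); all-missing alignments have
  likelihood exactly 1.

## The simulator

`imcoal.simulate` is an exact (non-Markov) backwards simulation of the
coalescent with recombination and migration: lineages carry ancestral
material as genomic intervals, recombine at `R` per breakable link across
their span (trapped non-ancestral material included), coalesce within
demes at `C` per pair, and migrate at `M` per lineage during
`[tau1, tau2]` only; demes merge at `tau2`.  Because the ancestral
recombination graph is simulated in full, lineages can recombine apart
and coalesce back to the same ancestor — precisely the behaviour the
sequentially-Markov HMM cannot represent, which is what makes the
recombination-rate bias experiment meaningful.  Sequences evolve over the
recorded local genealogies under Jukes-Cantor (uniform root, branch-wise
redraw with probability `1 - e^{-4t/3}`), for one or two samples per
deme.

Validation perturbations mirror the robustness experiments:

* block-wise mutation-rate multipliers (geometric block lengths, uniform
  factors in a configured range);
* an arbitrary per-link recombination map, plus a synthetic
  autocorrelated lognormal "map-like" generator standing in for an
  empirical human recombination map (which would require external data);
* random-phase mosaics: one pseudo-haploid per deme drawn allele-by-
  allele from a within-deme pair, emulating unknown phase.

What the simulator deliberately does not emulate: sequencing error,
alignment artefacts, CpG hypermutability or other rate heterogeneity
beyond the block model, gene conversion, selection, and more than two
demes.  Passing recovery tests therefore demonstrate statistical
identifiability under the model's own generative assumptions (plus the
full-ARG violation of the Markov assumption), not robustness to real
data pathologies.

A cross-check against `msprime` configured with the identical demography
(independent Hudson implementation) guards the simulator itself; an
event-driven Gillespie simulation of the two-nucleotide CTMC serves as
the Monte-Carlo oracle for the transition probabilities.

## Validation study conditions

The study is replayed at desk scale; all quantities below are computed
at run time by the test suite and `scripts/acceptance.py`, never stored.

| experiment | parameters (tau1, tau2, C, R, M) | data |
|---|---|---|
| parameter recovery, recombination bias (t1) | 1e-3, 3e-3, 1000, 0.4, 250 | 10 x 3-4 Mbp |
| random-phase mosaics (t2) | 1e-4, 2.5e-4, 1000, 0.4, 250; 2 samples/deme | 10 x 1 Mbp |
| model selection, gene flow | 1e-3, 3e-3, 1000, 0.4, 1000 | 10 x 1 Mbp |
| model selection, clean split | tau = 2e-3, 1000, 0.4 | 10 x 0.5 Mbp |
| mutation-rate variation | recovery set + blocks (mean 500 bp, factors 0.5-1.5) | 10 x 0.5 Mbp |

Rationale.  `C = 1000` and `R = 0.4` correspond to `N_e ~ 25,000`
(20-year generations, 1e-9 substitutions/bp/yr) and 0.8 cM/Mb — standard
great-ape values.  Full-scale analyses of this model class use 10 Mbp
segments; at 1 Mbp a shallow split (`tau2 = 1e-3`) is not statistically
identifiable (pilot medians of `tau2` off severalfold), so the recovery
set uses deeper splits (~1 and ~3 Myr, the orang-utan range).  Replicate
length for the recovery experiment is 3-4 Mbp: the ML sampling
distribution of the coalescence rate at 1 Mbp has a heavy right tail
(likelihood-surface ridge between `C`, `R`, `tau1` and `M`; verified not
to be an optimizer artefact by truth-started and multi-start fits
converging to the same optima, and calibrated fits on data generated from
the HMM itself recovering `C` without bias), and since the estimated `R`
rides on `C` — their ratio is tightly identified — the recombination-rate
bias measurement is diluted at 1 Mbp.  The phase experiment sits at the ~250
kyr divergence below which shared polymorphism makes the random-phase
bias detectable.  The gene-flow model-selection scenario satisfies
`M (tau2 - tau1) = 2` migrations per lineage, a clearly gradual
divergence; its clean-split counterpart uses an intermediate single
split.  Replicate counts follow the study design (10); sequence lengths
of 0.5 Mbp for the direction-only experiments keep the full suite within
a practical runtime.

## Known limitations

* The recombination rate is structurally underestimated — a property of
  the Markov approximation, not a bug.  In the recovery experiment the
  mean underestimation is ~18-20% (per-replicate values scatter from a
  few percent to ~30%, and at 1 Mbp single replicates can even
  overestimate when the coalescence rate lands high); the validation
  asserts the downward direction per replicate and measures the mean.
* `M` is the hardest parameter: at 1 Mbp its replicate-to-replicate
  spread spans a factor of ~4 even in the recovery regime (medians are
  within a factor of 2).
* Very recent splits (`tau2 << 1/C`) push the model towards a
  boundary where `tau1`, `M` and `C` trade off; estimates there should
  be read as effective, not literal, parameters.
* Asymmetric or time-varying migration, more than two demes/samples, and
  admixture pulses are out of scope.
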