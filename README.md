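# imcoal

**Isolation-with-migration coalescent hidden Markov model for pairwise
genome alignments.**

Did two species separate abruptly, or did they keep exchanging genes
while diverging?  Whole genomes answer this where short loci cannot: a
pairwise alignment of one haploid genome per species contains hundreds of
thousands of partially independent genealogies, and the joint pattern of
*how divergent* each region is and *how long* regions of equal divergence
are is shaped by the split times, population size, recombination rate and
migration rate.

`imcoal` models this signal with a coalescent hidden Markov model
(CoalHMM).  Looking backwards in time the demography has three epochs: a
present-day isolation epoch `[0, tau1)` with no gene flow, a gene-flow
epoch `[tau1, tau2)` with symmetric migration at rate `M`, and a
panmictic ancestral population beyond `tau2`.  The ancestry of each pair
of adjacent nucleotides is an exact continuous-time Markov chain over
lineages carrying ancestral material (coalescence rate `C`, recombination
rate `R`, migration rate `M`, all scaled by expected substitutions per
site); discretizing coalescence time into intervals turns this into an
HMM along the alignment whose transition matrix is the conditional joint
coalescence distribution `T[i,j] = J[i,j] / sum_j J[i,j]` and whose
emissions are Jukes-Cantor column probabilities at each interval's
end-conditioned mean coalescence time.  Maximum-likelihood estimates of
`(tau1, tau2, C, R, M)` come from Nelder-Mead on the exact forward
likelihood, and an AIC comparison against the nested clean-split
isolation model (single `tau`; `delta = AIC_I - AIC_IM`, positive
preferring gene flow) tests whether divergence was gradual.

The package is aimed at population geneticists working with closely
related species pairs (the model class was developed for the great apes).
It bundles an exact coalescent-with-recombination simulator for the
two-deme IM demography — including mutation-rate-block, recombination-map
and random-phase perturbations — so the entire validation study runs from
scratch with no external data.

## Worked example

Simulate 500 kb under a gradual divergence and re-estimate the history
(`python examples/fit_im_model.py`):

```
parameter         true    estimate
tau1             0.001    0.001317
tau2             0.003    0.003231
C                 1000        1197
R                  0.4      0.4182
M                  250       289.4
log-likelihood -20393.8, AIC 40797.7, 373 evaluations

at 1e-9 substitutions/bp/year and 20-year generations:
  gene flow ceased ~1,316,809 years ago
  initial split    ~3,230,920 years ago
  N_e              ~20,879 individuals
```

The two split times bracket the gene-flow period: this simulated pair
began diverging ~3 Myr ago but kept exchanging migrants until ~1 Myr ago.
`tau1`, `tau2` and `C` are estimated from a single 500 kb fragment to
within ~20-30% here and sharpen with more sequence; averaged over
replicates the recombination rate is biased roughly 20% low, a known
property of the Markov approximation (the real ancestral recombination
graph often recombines and coalesces back to the same ancestor, so the
effective recombination rate the HMM sees is smaller).

Other capabilities, one script each, under `examples/`:

* `simulate_alignment.py` — simulate and inspect the genealogical truth;
* `compare_models.py` — AIC test of gradual vs clean divergence;
* `decode_tmrca.py` — posterior-decode the TMRCA landscape along the
  genome.

Real alignments enter either as FASTA (two aligned, equal-length
records) or MAF projected to a species pair; columns reduce to
identical / different / missing, and `N`s, gaps and masked bases are
treated as missing (uninformative but coordinate-preserving).  The same
functionality is exposed as a thin command line:

```sh
imcoal simulate --seed 1 -L 1000000 --out pair.fa --truth-out truth.tsv
imcoal fit pair.fa --model im --mu 1e-9 --out fit.json
imcoal compare pair.fa --segment-size 10000000 --out segments.tsv
imcoal decode pair.fa --tau1 0.001 --tau2 0.003 --coal-rate 1000 \
       --rec-rate 0.4 --mig-rate 250 --out tmrca.bed
```

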