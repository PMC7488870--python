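# Methods

## Model

A shoot's bud-fate sequence `x_0..x_{T-1}` (symbols 0–5, base to tip) is
modelled by a hidden semi-Markov chain whose transient states are branching
zones.  The chain is left-to-right and transient — the transition matrix is
strictly upper-triangular over the transient states with an extra absorbing
end column — so each state occupies at most one contiguous run of nodes.
A state `j` carries

* an occupancy distribution `d_j` on the zone length in nodes, supported on
  `d ≥ 1` (families: point mass, shifted Poisson, shifted negative binomial,
  shifted binomial; the shift guarantees `P(d ≥ 1) = 1`), truncated and
  renormalised on `1..support_max` (default 150 nodes, far beyond any
  observed shoot);
* a categorical emission over the six symbols with a support mask.

Two published structures are provided as templates.  The 3+1-state model
(monocyclic shoots with short/medium growth duration) has a forced-latent
basal zone S0, a free diffuse floral zone S1 and a free acrotonic
vegetative zone S2.  The 7+1-state model (monocyclic long-duration plus
bicyclic shoots) has forced-latent L0 and L3, a forced bud-scar cessation
zone L2 separating the two growth units, free zones L1 (diffuse floral),
L4 (short shoot), L5 (floral), L6 (acrotonic vegetative), and allows
monocyclic shoots to bypass the scar through L1 → L3.  Initial probability
is fixed on the first state in both templates (the basal latent zone is
universal); the API accepts free initial vectors.

The final zone is treated as complete (no right-censoring): sequence length
is governed entirely by the transient occupancies, and termination into the
end state exactly at the sequence end is part of the likelihood.

## Algorithms

*Likelihood.* A forward recursion over zone end-times:
`α_j(t) = Σ_d d_j(d) · B_j(t-d,t) · in_j(t-d)` with
`in_j(s) = π_j` at `s = 0` and `Σ_i α_i(s) p_ij` otherwise; the sequence
likelihood is `Σ_j α_j(T) p_j,end`.  Because the chain is left-to-right and
transient this recursion is exact (verified against brute-force enumeration
of all segmentations on toy models, tolerance 1e-10).  Computation is in
log space; impossible emissions use a large finite negative sentinel so
cumulative-sum differences stay well-defined, and any total below −1e8 is
reported as −∞.

*Restoration.* A duration-explicit Viterbi recursion with back-pointers.
Ties are broken locally toward the earliest predecessor (sequence start,
then the lowest state index) and then the shorter zone duration, so tied
restorations prefer low state indices and short initial zones.

*Estimation.* EM on the same lattice: the E-step accumulates posterior
segment weights `P(state j spans [s, s+d))`, giving expected initial,
transition, duration and per-node emission counts; the M-step renormalises
free cells under the structural masks, refits each state's declared
occupancy family by weighted maximum likelihood, and floors free emission
cells at 1e-6 (cells still at the floor after convergence are removed from
the final report).  Convergence: relative log-likelihood change < 1e-6,
at most 500 iterations.  Restarts: the first start uses positional symbol
frequencies (state `j` seeded from the `j`-th fraction of each sequence);
further restarts draw emissions from a flat Dirichlet over each mask and
jitter occupancy means — latent-dominated frequency inits otherwise sink
into a local optimum that splits the basal latent zone.  Ten restarts by
default; the best final log-likelihood wins.  BIC is `−2·loglik + k·log N`
with `N` the total node count and `k` the count of free cells (each
probability row contributes `nonzero − 1`) plus occupancy parameters.
The inner recursions are JIT-compiled with numba.

*Occupancy family selection* fits each family by maximum likelihood (the
negative binomial by profile likelihood over its shape on a bounded log
grid; the binomial by scanning `n`) and picks the lowest BIC, breaking ties
toward fewer parameters.  Constant durations short-circuit to a point mass.

## Shoot categorisation

An observation qualifies as stagnating when its gain over the nearest
observation at least 14 days earlier is below 0.5 cm; a maximal run of
qualifying observations is one cessation episode, dated at its earliest
observation (the earliest detectable stop — the rule itself does not name
an endpoint).  The window is realised as "nearest observation ≥ 14 days
earlier" to tolerate irregular visits.  The start date is the first
observation at ≥ 5 cm; a second growth unit opens only if, after the first
cessation, the length exceeds the cessation length by a further 5 cm —
smaller rebounds are treated as measurement noise, which keeps a single
noisy fortnight in a plateau from fabricating a bicyclic shoot.  Growth
duration boundaries are closed into the medium class (30 and 90 days are
medium); a start date exactly on a calendar threshold counts as early.
Shoots that never reach 5 cm, never cease, or whose second unit never
ceases are excluded with a logged reason.  When a growth-derived category
contradicts bud-scar evidence in the sequence itself, the sequence's
category wins (scars are direct evidence of a within-season cessation).

## Statistical comparisons

Zone lengths are compared with a log-link negative binomial regression on
a group indicator (Wald test); non-convergence falls back to Poisson with a
flag, and groups with fewer than 3 zones yield a no-test result.  Fisher's
exact test uses the hypergeometric 2×2 form, exhaustive enumeration of
tables with matching margins when the total is ≤ 200 (and the enumeration
is tractable), and otherwise a Monte-Carlo exact test with 100,000
Patefield draws under a fixed internal seed, flagged as such.  Count GLM
comparisons select Poisson unless a Pearson chi-square goodness-of-fit test
(tail bins pooled to expectation ≥ 5, one estimated parameter) rejects it
at 5%, then use negative binomial with the MLE shape; all pairwise
contrasts are adjusted single-step via the max-|z| multivariate normal
distribution of the contrast vector (a Tukey analogue appropriate for GLM
contrasts) and summarised as compact letters by insert-and-absorb, which
guarantees significant pairs never share a letter and never-separated pairs
do.  Rank comparisons use Mann–Whitney (two groups, continuity-corrected)
or Kruskal–Wallis followed, when significant, by Dunn's tie-corrected z
tests with Holm adjustment (the post-hoc adjustment is a convention, as is
Holm for the pairwise chi-square tests on proportions — a literal "Tukey
test after chi-square" is not a defined procedure).  Proportion tables
route to Fisher when any expected cell is below 5.  Significance codes:
`*` p < 0.05, `**` p < 0.01.

Zone occurrence is presence in the restored Viterbi path (not posterior
state probabilities), matching the use of most-probable state sequences
throughout; the diffuse-floral correlation analysis includes only shoots
possessing that zone.

## Synthetic data

The generator emulates the study conditions: 71%/29% monocyclic/bicyclic,
growth-duration sub-mixes 65/28/7% (short/medium/long) for monocyclic
shoots, 67% long first growth units and 58% long second units, early/late
growth-period proportions per class, spring start dates ~N(April 30, 6 d)
and post-pruning starts ~N(June 26, 6 d).  Growth trajectories are
piecewise linear in expectation (rate ~N(3, 0.5) cm/week, plateau drift
0.05 cm/week, Gaussian measurement noise sd 0.3 cm, recorded lengths never
dropping more than 0.4 cm below the running maximum), engineered so the
trailing two-week rule detects cessation one window after true growth stop,
i.e. at start + GD; class target durations keep ≥ 8 days of margin from the
30/90-day boundaries so that detection jitter (±1 week) rarely crosses a
class.  Bicyclic trajectories hold the inter-unit plateau for at least
three weeks and jump past the second-start criterion exactly on a weekly
observation date.  Target durations for bicyclic "long" units are bounded
by the remaining season (36–70 days) rather than the monocyclic long range.

Bud-fate sequences are drawn from per-category ground-truth chains whose
zone visit probabilities equal the published occurrence rows (e.g. 0.26 /
0.09 mutually exclusive branched zones for short-duration shoots, 0.65 for
the bicyclic diffuse floral zone) — a left-to-right chain realises any
marginal visit profile over the post-cessation zones by independent skip
decisions.  Occupancy means (7 nodes basal, 3.9 / 13.4 / 16 diffuse floral
by category, ~2 scar, 3–5 others) reproduce the printed zone and node-count
means.  Emission mixtures are invented defaults consistent with the verbal
zone descriptions; the diffuse floral zones use a 0.45/0.45/0.10
latent/short-bourse/long-bourse mixture — floral-marked enough to keep the
zone statistically identifiable next to the forced-latent basal zone, which
a heavily latent-dominated mixture is not.

What passing tests show — and do not.  Synthetic growth curves are smooth
single- or double-plateau trajectories with independent Gaussian noise;
real shoots pause and resume with weather, and measurement errors are
correlated.  Sequences are exchangeable given category: there is no
within-tree correlation, no pruning-treatment effect, and zone emissions
are i.i.d. within a zone.  Recovery results therefore demonstrate the
correctness and calibration of the algorithms under the stated generating
laws, not the adequacy of those laws for any particular orchard.

## Problem sizes and numerical choices

Recovery checks use 300–500 sequences per category (simulation→EM closes
the loop within ±0.07 on free transitions and ±15% on occupancy means at
500 sequences); path-level checks use 10,000 simulated paths; the
zone-length test's type-I error is assessed over 1,000 null replicates.
Templates default to shifted negative binomial occupancies: zone lengths
pooled across shoot categories in a shared model are overdispersed, and the
family nests the Poisson (a Poisson-occupancy template misallocates the
short-duration floral zones of a pooled cohort).  Model files serialise
probabilities as decimal strings with 12 significant digits and round-trip
at that precision.

## Known limitations

* Occurrence via hard Viterbi assignment loses marginal zones whose
  emissions resemble a neighbour's; with the default emissions the loss is
  within the tolerances above but grows as zones blur.
* The left-to-right label order of the free post-cessation zones is only
  identified through their emission mixtures; on data where two free zones
  have similar mixtures, restarts can converge to label-permuted optima of
  equal likelihood (the tests identify zones semantically, by dominant
  lateral type, where this matters).
* No right-censoring of final zones, no covariate-dependent transitions,
  no multi-scale or bidirectional structures.
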