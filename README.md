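# shootzones

Branching-zone analysis of apple shoots with constrained hidden semi-Markov
chains.

In apple (*Malus × domestica*), the fate of each axillary bud along a parent
shoot — latent, vegetative (short/long) or floral (a bourse bearing a short
or long bourse shoot) — is organised in successive homogeneous *zones*
(basal latent zone, diffuse floral zone, acrotonic vegetative zone, …).
`shootzones` quantifies how a parent shoot's growth rhythm shapes that
zonation.  It is written for researchers in tree architecture and fruit-tree
physiology who have (or want to simulate) two kinds of records per shoot:
weekly cumulative length measurements, and a node-by-node bud-fate sequence
scored the following year with the coding `0` latent, `1` short vegetative,
`2` long vegetative, `3` bourse + short bourse shoot, `4` bourse + long
bourse shoot, `5` bud scar.

The package provides:

* **Shoot categorisation** from growth curves: growth cessation (length gain
  < 0.5 cm over two weeks), start date (first crossing of 5 cm), growth
  duration classes (< 30 d / 30–90 d / > 90 d), growth period classes
  (early/late relative to calendar thresholds), and monocyclic (one growth
  unit) vs bicyclic (two growth units) shoots.
* **Hidden semi-Markov chains** over bud-fate sequences.  A chain with
  transient states `j = 0..S-1` and an absorbing end state is *left-to-right*
  (`p_ij = 0` for `j ≤ i`); each state carries an explicit occupancy law
  `d_j(u)` on zone length in nodes (point mass, shifted Poisson, shifted
  negative binomial or shifted binomial) and a categorical observation law
  `b_j(v)` over bud fates.  Structural constraints (forced-latent basal
  zones, the forced bud-scar state of bicyclic shoots) are masks preserved
  exactly through estimation.  The likelihood

  `P(x_0..x_{T-1}) = Σ_paths π_{j1} d_{j1}(u_1) Π b_{j}(x_t) p_{j1 j2} d_{j2}(u_2) ...`

  is computed by an explicit-duration forward recursion; estimation is EM
  (forward–backward over zone segmentations, multiple restarts), and the
  optimal segmentation is restored by a duration-aware Viterbi algorithm.
* **Zone statistics**: occurrence probabilities per shoot category, zone
  length comparisons (negative binomial GLM), lateral-type distributions
  within zones (Fisher's exact test, exact or Monte-Carlo for r×c tables),
  and zone-length vs shoot-length Pearson correlations.
* **Category comparisons**: count GLMs with Poisson/negative-binomial family
  selection and Tukey-style single-step pairwise letters, Kruskal–Wallis /
  Dunn, Mann–Whitney, chi-square and Fisher tests.
* **A synthetic study generator** with known ground truth (the published
  cohort composition: 71% monocyclic / 29% bicyclic, the reported zone
  occurrence rows, start dates centred on April 30 / June 26), so the whole
  pipeline is testable without field data.

## Worked example

Simulate a 227-shoot study and run the full pipeline:

```sh
shootzones simulate --n 227 --seed 1 --out demo
shootzones run --growth demo/growth.csv --sequences demo/sequences.tsv \
               --out demo/results --seed 1
```

`demo/results/report.txt` then contains (excerpt):

```
cohort one-GU-short-medium: 158 sequences, model fitted
cohort one-GU-long-and-two-GUs: 69 sequences, model fitted

Zone occurrence probabilities:
                                    model    n   S0     S1     S2   L0     L1   L2   L3    L4     L5     L6
group
one-GU short GD       one-GU-short-medium  106  1.0  0.283  0.066  NaN    NaN  NaN  NaN   NaN    NaN    NaN
one-GU medium GD      one-GU-short-medium   52  1.0  0.635  0.212  NaN    NaN  NaN  NaN   NaN    NaN    NaN
one-GU long GD    one-GU-long-and-two-GUs   10  NaN    NaN    NaN  1.0  1.000  0.0  1.0  0.70  0.700  0.900
two-GUs           one-GU-long-and-two-GUs   59  NaN    NaN    NaN  1.0  0.678  1.0  1.0  0.61  0.407  0.661

Node numbers per category (count GLM, compact letters):
           group  mean letter            family
 one-GU short GD  8.57      a negative-binomial
one-GU medium GD 15.56      b negative-binomial
  one-GU long GD 48.80      c negative-binomial
         two-GUs 30.86      d negative-binomial
```

Reading this: shoots are split into the two estimation cohorts (monocyclic
short/medium-duration shoots get the 3+1-state model S0–S2; monocyclic
long-duration and bicyclic shoots share the 7+1-state model L0–L6).  Every
decoded shoot starts in the basal latent zone (occurrence 1.0 for S0/L0);
the diffuse floral zone S1 occurs on 28% of short-duration shoots but 64%
of medium-duration shoots — branching enriches as growth duration extends —
and groups not sharing a compact letter differ significantly in node number
at the 5% level.  The generating values behind this run (S1 visits 0.26 /
0.71, bicyclic L1 visit 0.65, …) sit inside the corresponding sampling
error.  TSV tables (`occurrence.tsv`, `zone_lengths.tsv`,
`lateral_types.tsv`, `node_numbers.tsv`, `correlations.tsv`) and the two
serialized models accompany the report.

The same objects are available as a library:

```python
from shootzones import fit_em, simulate, monocyclic_template
from shootzones.synthetic import monocyclic_spec

truth = monocyclic_spec(0.26, 0.09)          # short-GD generator
seqs, _ = simulate(truth, 500, seed=11)
res = fit_em(seqs, monocyclic_template(9.0), n_restarts=10, seed=2)
print(res.summary())                         # states, occupancies, transitions
paths = res.decode(seqs)                     # optimal segmentations
```

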