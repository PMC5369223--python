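# cpseg

Bayesian segmentation of three-species genomic alignments and calling of
putative functional elements (PFEs) — deeply conserved intronic and
intergenic sequences of the kind that often harbour non-coding RNAs and
regulatory elements.

## The problem

Vertebrate introns contain short elements that have stayed recognisably
similar between fish and mammals for hundreds of millions of years.
Finding them from a 3-way alignment (say zebrafish / mouse / human) means
simultaneously answering two questions: *where do the statistical
properties of the alignment change*, and *what kind of region is each
piece* — exon-like, conserved non-coding, neutrally evolving background?
`cpseg` answers both with a single Bayesian segmentation-classification
model and then applies explicit, gene-specific filtering rules to call
PFEs, producing BED/WIG tracks ready for a genome browser.

## The model

Each ungapped alignment column over three species is one of 4³ = 64 base
triples; a triple and its base-wise complement are equivalent (the
alignment reads the same from either strand), leaving **32 symbols**
`a…z, U…Z`. An alignment therefore becomes a single string over this
alphabet — `a` and `v` are the two fully conserved column types — with
indel columns excluded but tallied in a gap ledger, and `#` marking
alignment-block discontinuities.

The string is modelled as homogeneous segments delimited by change-points:

- change-point indicators at every boundary are independent Bernoulli(φ)
  (`#` boundaries are change-points with probability 1), so the number of
  change-points varies;
- each segment draws a class label from Categorical(π), one of *T*
  classes;
- a segment of class *c* draws its own composition θ ~ Dirichlet(α_c) and
  emits its symbols i.i.d. Multinomial(θ); θ is collapsed analytically,
  giving each segment an ordered Dirichlet-multinomial marginal.

A partially-collapsed Gibbs sampler (numba-accelerated; labels summed out
of every boundary toggle, then redrawn) samples segmentations, labels, π,
optionally φ, and α_c by random-walk Metropolis. *T* is chosen by running
the sampler at several values and comparing AIC, BIC and a DIC variant on
post-burn-in samples, screening out models with near-empty or unstable
classes. The conservation level of a class is
**E(θ) = (θ_a + θ_v) / Σ_j θ_j**, the expected fraction of fully matching
columns.

Post-burn-in samples are averaged into per-position **profiles** — the
probability that each reference position belongs to each class. A **PFE**
is a run of ≥ 100 nt in which every position has ≥ 0.9 probability of the
conserved class(es) anchoring the gene in question (the classes
overlapping its exons, plus any class more conserved than those, all above
50% conservation), broken at alignment gaps of ≥ 20 columns, discarded
when gaps reach 10% of the run, clipped to intronic space — or, outside
gene bodies, taken from the single most conserved class (intergenic PFEs).

An exact enumeration oracle verifies the sampler on small instances, and a
synthetic-alignment generator with planted ground truth (segment classes,
exons, intronic elements) makes every stage testable end to end.

## Worked example

```python
import numpy as np
from cpseg import (TruthConfig, generate_alignment, encode_alignment,
                   score_models, select_model, class_profiles, call_pfes,
                   PfeCriteria, score_recovery)
from cpseg.model import ModelConfig, gibbs_sample

truth = generate_alignment(TruthConfig(seed=0))      # 20 kb, 3 classes
seq = encode_alignment(truth.alignment)

scores, _ = score_models(seq, range(1, 6), seed=100, n_iter=1000,
                         cp_prior_phi="sample")
T = select_model(scores)

trace = gibbs_sample(seq, ModelConfig(T=T, seed=100, n_iter=3000,
                                      cp_prior_phi="sample"))
profile = class_profiles(trace, seq, burnin=1500)
pfes = call_pfes(profile, truth.gene_bodies, truth.exons, PfeCriteria())
```

which prints (abridged):

```
T=1  AIC=   109133  BIC=   109412  DICV=   109065  mixture=[1.]
T=2  AIC=   108585  BIC=   109782  DICV=   107177  mixture=[0.51 0.49]
T=3  AIC=   108366  BIC=   109838  DICV=   106462  mixture=[0.48 0.3  0.22]
T=4  AIC=   108424  BIC=   110172  DICV=   106276  mixture=[0.24 0.47 0.29 0.01]
selected T = 3
class conservation: [0.447 0.494 0.62 ]
PFE chrSim:3641-3879  class 2 (62% conserved)  min profile 0.90
PFE chrSim:6454-6650  class 2 (62% conserved)  min profile 0.90
...
recovery vs planted truth: precision 0.83, recall 0.83
```

The generator planted three classes at conservation 0.45 / 0.50 / 0.65;
AIC and DICV bottom out (and the information-criteria vote settles) at
T = 3, the T = 4 model betrays itself with a 0.01-mixture class, the
recovered conservation levels land near the planted ones, and the planted
300-nt intronic elements come back as PFEs with their edges eroded by
genuine posterior uncertainty about the exact boundaries.

The same pipeline is available from the shell:

```bash
cpseg simulate --total-length 20000 --seed 5 --out sim/
cpseg segment sim/alignment.maf --t-min 1 --t-max 5 --out run/
cpseg callpfe run/profile --genes sim/genes.bed --exons sim/exons.bed \
      --track evofold my_tracks/evofold.bed --out pfes/
```

`segment` writes `scores.tsv`, a selection log, per-class WIG/BED tracks
and the profile directory; `callpfe` writes `pfes.bed` (name =
`gene|class`, score = 1000 × minimum profile value), a per-track support
table and Venn counts.

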