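# Methods

## Column encoding

An ungapped column of a 3-way alignment is a triple over {A,C,G,T} in row
order (reference, species 2, species 3). Complementary triples carry the
same information regardless of strand, so the 64 triples pair into 32
strand-equivalence classes. The symbol index is `i1 + 4·i2 + 16·i3`
(A,C,G,T → 0..3), computed for whichever member of the pair has the
smaller index — exactly one member has its row-3 base in {A,C}, which
pins the index below 32. Symbols `a` (index 0, A/A/A ≡ T/T/T) and `v`
(index 21, C/C/C ≡ G/G/G) are the fully conserved column types.

Columns containing `-` are excluded from the symbol string and counted in
a per-position gap ledger (`gap_before[i]` = columns skipped since the
previous emitted symbol); columns containing IUPAC ambiguity codes are
excluded and tallied separately — inventing emission probabilities for
them would add nothing. Columns gapped in all three rows are dropped
entirely: they carry no positional information for any species.
Reference-gap columns occupy no reference coordinate; element lengths are
therefore always reference-species nucleotides. Soft-masked (lowercase)
bases are encoded normally, with an option to exclude them. Block
discontinuities and concatenation joins become single `#` characters,
which the model treats as mandatory change-points. Row order is stored
explicitly in the `EncodingScheme` and is configurable, since different
analyses may reference different species.

## Segmentation-classification model

For a symbol string of length *n*:

- Boundary *b* (between positions *b* and *b*+1) carries an indicator
  `I_b ~ Bernoulli(φ)`; `#` boundaries are fixed at 1. The indicator form
  is the minimal structure that lets the number of change-points vary.
  φ defaults to 0.01, or is given a Beta(1,1) hyperprior and sampled
  (`cp_prior_phi="sample"`), in which case its conjugate update uses the
  current count of free change-points.
- Segment labels are i.i.d. Categorical(π), π ~ Dirichlet(`pi_prior`,
  default all-ones).
- A segment of class *c* draws θ ~ Dirichlet(α_c) and emits its symbols
  i.i.d.; θ is integrated out, so a segment with counts **n** contributes
  `log Γ(A) − log Γ(A+N) + Σ_j [log Γ(α_cj + n_j) − log Γ(α_cj)]`,
  A = Σα_cj. No multinomial coefficient appears: segments are ordered
  strings, and the coefficient would cancel in every acceptance ratio
  anyway.
- α_c gets independent Exponential(rate 1e-3) priors per coordinate — a
  weakly informative choice that still lets the concentration grow to the
  tens of thousands the data demand when within-class dispersion is
  negligible.

### Sampler

One sweep walks the boundaries left to right. At each free boundary the
on/off indicator is resampled from its full conditional with the labels
of the affected segments summed out (`p(on) ∝ φ·Σ_cπ_cM(left|α_c) ·
Σ_cπ_cM(right|α_c)`, `p(off) ∝ (1−φ)·Σ_cπ_cM(merged|α_c)`), after which
the affected labels are redrawn — a blocked, partially-collapsed Gibbs
move. Left and right segment marginals are maintained incrementally (an
O(1) update per class when the boundary advances), so a sweep costs O(nT)
plus O(32T) per segment; the kernel is numba-compiled. After each sweep:
conjugate updates of π (and φ when sampled), then `alpha_mh_steps` (2)
Metropolis proposals per class on log α_c, alternating element-wise
N(0, 0.15²·…) jitter and a common log-scale (concentration) move, with a
log-space Jacobian and the exponential prior in the ratio. Acceptance
runs ~30% on the benchmark. The recorded log-likelihood is the plug-in
multinomial likelihood at the sweep's posterior-predictive class
compositions — the same parameterisation the information criteria use.

### Warm start

With α_c initialised near all-ones the classes are statistically
exchangeable, and on realistic inputs the chain takes very long to break
that symmetry (in practice one class absorbs everything). The sampler
therefore seeds its initial state deterministically from the data: the
sequence is tiled into 200-symbol windows, windows are k-means-clustered
(5 seeded restarts) in the two features that separate classes —
conservation (f_a + f_v) and reference GC — and the clustering supplies
initial labels, window-boundary change-points, and moment-matched
α_c = 100 · (cluster composition). This sets only the starting point;
the target distribution is untouched, and passing `alpha0` or
`warm_start=False` restores a cold start.

### Exact oracle

`enumerate_posterior` sums the collapsed joint over all 2^(n−1)
segmentations (≤ 14 free boundaries, T ≤ 3) with labels summed
independently per segment, which is exact when π and α are held fixed —
so the oracle requires `sample_pi=False, sample_alpha=False` and a fixed
φ, and the sampler-vs-oracle checks run in that regime. Sampled boundary
marginals agree with enumeration to total variation < 0.01 at 20 000
sweeps on 8–12-symbol instances.

## Burn-in, information criteria, choice of T

Burn-in is the earliest sweep after which a trailing 100-sweep window
shows no significantly positive log-likelihood slope (one-sided t-test,
α = 0.05), combined with the same test (two-sided) on each class's
conservation series — the likelihood can plateau while compositions still
drift — and capped at half the run.

With k = 31T + (T−1) + mean change-point count (compositions, mixture,
and the segmentation's effective parameter cost):
AIC = 2k − 2·max ln L, BIC = k·ln n − 2·max ln L (n = encoded length),
and DICV = 2·mean deviance − deviance at the posterior-mean compositions
and the modal segmentation (boundaries with posterior marginal ≥ 0.5,
labels by maximum plug-in likelihood). DICV is an approximation and is
labelled as such in output.

Models are screened before selection: any class with mixture mean below
0.01, or whose conservation series has post-burn-in standard deviation
above 0.05 ("unstable"), disqualifies its model as over-fitted. Each
criterion nominates the smallest admissible T at one of its local minima;
the default selection takes the median of the three nominations. This
replaces a BIC-only rule: with this k, BIC's per-class cost (≈ 31·ln n ≈
307 nats at 20 kb) exceeds the likelihood gain of resolving classes whose
conservation differs by only ~0.05, so BIC alone under-segments
moderate-length inputs while AIC and DICV recover the planted class
count; using all three mirrors how the criteria are meant to be read
together, and the full decision trail is logged so a human can override.

## Profiles and conservation

Class conservation is E(θ) = (θ_a + θ_v)/Σθ_j per class per sweep.
Because chain labels are arbitrary, sweeps are aligned by Hungarian
assignment of each sweep's compositions to running centroids (L1 cost)
before averaging; classes are reported ranked by conservation. The
membership profile at position *i* is the post-burn-in average of the
probability that *i*'s segment carries each (aligned) label — the
Rao-Blackwellised form, averaging each segment's label posterior given
that sweep's (π, α) rather than the sampled label, which estimates the
same marginal with lower variance. Rows sum to 1 by construction.
Positions absent from the alignment get no profile value; writers emit
variableStep WIG (1-based) and BED (0-based half-open) accordingly.

## PFE calling

Defaults: minimum 100 aligned positions, per-position profile ≥ 0.9, runs
split at ≥ 20 consecutive skipped alignment columns, rejected when
skipped columns reach 10% of the run's aligned length, classes reported
only above 50% conservation. Gene-specifically, the anchoring classes are
those whose thresholded segments intersect the gene's exons plus every
class strictly more conserved than the best of them. Candidates are
generated directly on the intronic position set (gene body minus exons),
so a run overlapping an exon edge is clipped and every threshold
re-applied to the clipped piece; an emitted interval spans its first to
last aligned position, so `end − start` can exceed the aligned-position
count when internal columns were skipped. Intergenic PFEs come from the
single most conserved class on positions outside all gene bodies (ties
broken to the lowest class index and logged). Nested genes each receive
their own attribution of a shared interval; identical intervals from
multiple classes keep the more conserved class. A curated exclusion list
(e.g. alignments of non-homologous genes) is honoured as an input, not
automated. The two-proportion enrichment test is the standard pooled
z-test; on the printed transcription-factor counts it gives z ≈ 13.4
(p ≈ 1e-40), which does not reproduce the 1.2e-56 printed alongside those
counts, so the package reports the statistic and makes no claim about
that p-value.

## Synthetic benchmark

The generator emulates the model's own statistical structure — that is
deliberate: the tests certify the inference machinery, not evolutionary
realism. Segments tile a single reference chromosome (geometric lengths,
mean 500 nt; background classes mixed equally), columns are drawn i.i.d.
from per-class compositions built by `composition_from_targets`
(conservation mass on `a`/`v` split by GC; remaining mass uniform within
each reference-GC half — E(θ) and GC are matched exactly), and each
symbol is rendered as either of its two strand-equivalent triples with
probability ½. Indels arrive in geometric runs (rate 0.002/position,
mean 4 columns; insertions gap the reference, deletions gap species 2 or
3), and blocks break at rate 1e-4 — both suppressed inside planted
features, as deeply conserved elements align contiguously in real data.
Defaults: 20 kb, three classes at conservation 0.45/0.50/0.65 (the levels
a 3-class run reports on real vertebrate gene alignments) with GC
0.35/0.55/0.45, six 150-nt exons (hosted, with 25-nt flanks, in the most
conserved class) and six 300-nt planted intronic elements. What passing
does **not** show: robustness to alignment error, rearrangement,
phylogenetic rate variation within segments, or paralogy.

Recovery scoring matches calls to planted elements at ≥ 50% reciprocal
overlap, one call per element; on five benchmark replicates the calls
pool to precision ≈ 0.9 and recall ≈ 0.93–0.97 (counts pooled because six
elements per replicate quantise a per-replicate rate in steps of 1/6).

## Known limitations

- At the default class separations the exact posterior itself leaves
  10–15% of positions below 0.9 membership probability (boundary windows
  of ±10–20 nt around every change-point, plus genuine carving of locally
  atypical runs into the nearest class): a run of the sampler with the
  generator's true parameters held fixed reaches only ~87% — so
  per-position certainty at the 0.9 level should not be expected from
  data like this, and the recovered conservation of a sparsely
  represented top class can sit a few hundredths low for the same reason.
- The move set is a redesign with the same target distribution as the
  generalized-Gibbs approach it replaces; per-move behaviour (and any
  IC approximations of the original software) will differ even where the
  posterior does not.
- Whether the original implementation fixed or sampled per-class
  Dirichlet parameters is not recoverable; both are supported
  (`sample_alpha`), with sampling the default.
- Problem sizes in the reference benchmark (20 kb, T ≤ 5, 1000-sweep
  selection runs, 3000-sweep recovery runs) are the package's defaults;
  all are configurable.
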