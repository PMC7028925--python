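# Methods

`hybridgate` implements a standardized workflow for detecting and managing
wild × domestic admixture from multilocus codominant genotypes — the
motivating system being wolf × dog hybridization scored at panels of 39 (or
a reduced 12) autosomal microsatellites. This note documents the models, the
synthetic study conditions, the numerical choices, and the limits of what
the test suite demonstrates.

## The admixture model (`hybridgate.admixture`)

Each diploid individual *i* carries two allele copies per locus *l*. The
K=2 admixture model with independent allele frequencies assumes every allele
copy has a latent origin `Z ∈ {wild, domestic}` with `Pr(Z = k) = q_ik`,
and, given its origin, is an independent draw from that cluster's frequency
vector `p_kl·`. The Gibbs sampler alternates the conjugate updates

* `Z_ila | q, P` — categorical ∝ `q_ik · p_kl x_ila`,
* `P_kl· | Z` — Dirichlet(λ + origin-specific allele counts), λ = 1,
* `q_i | Z` — Dirichlet(α + per-cluster copy counts),

with a shared admixture hyperparameter α updated by random-walk Metropolis
(uniform prior on (0, 10], proposal SD 0.025, the conventional defaults for
this model family). Missing locus calls are absent from the copy list and
contribute nothing — no imputation. Monomorphic loci are retained; they
contribute a constant factor and are harmless.

Reference individuals carry **no** prior population flags: the two clusters
are inferred unsupervised and anchored post hoc by requiring the wild
references' mean membership to the cluster reported as "wild" to exceed
0.5. A run in which the wild references load 50/50 is rejected as
degenerate rather than silently mis-anchored.

**One-by-one assignment.** Each query is analysed in its own chain together
with the full reference panel, independently of all other queries, so that
assignment cannot be distorted by the admixture composition of the rest of
the sample. Per-query chain seeds are derived from the configuration seed
and a CRC-32 of the query's identifier, which makes results exactly
invariant to query order and lets a re-assignment of the same individual
(e.g. before/after error injection) reuse the same chain seed.

**Chain lengths.** The desk-scale default is 5×10³ burn-in + 2×10⁴ sweeps
with thinning 10 (2,000 retained draws). On strongly differentiated
reference panels the q posterior for a single query mixes within a few
hundred sweeps, and between-run variation of posterior means is well below
0.01 at this length; the full-scale 5×10⁴/5×10⁵ protocol is available
through `McmcConfig`. 90% credibility intervals are equal-tailed 5th/95th
percentiles of the thinned draws. Group summaries (`Q`) average member
means; their 90% interval pools all members' draws (the group-level
interval has no standard definition in this workflow; pooling is this
package's choice and is documented as such).

The sampler's hot loop is compiled with numba and uses an inline
xorshift64\* generator (uniforms directly from the integer state, normals
via Box–Muller, gammas via Marsaglia–Tsang with the shape<1 boost); all
draws are deterministic given the integer seed.

## The genotype-frequency-class model (`hybridgate.genoclass`)

The discrete-class alternative assigns each individual to one of five
classes — PW, PD, F1, F2, BC1W — characterised by the probability vector
`g = (g0, g1, g2)` that a locus carries (two wild copies, one of each, two
domestic copies): PW (1,0,0), PD (0,0,1), F1 (0,1,0), F2 (¼,½,¼), BC1W
(½,½,0). The Gibbs sampler alternates: individual class `z_i`
(marginalising per-locus origin states), origin state `w_il`, latent allele
origins within mixed loci, population allele frequencies and class mixing
proportions, both Dirichlet. "Jeffreys-like" priors use concentration
1/(alleles at the locus) and 1/(number of classes); "uniform" uses 1. The
exact Jeffreys-like constants of the original model family are not uniquely
documented; these readings are this package's declared choice, and the test
suite verifies the two prior flavours give statistically indistinguishable
posteriors on the synthetic fixture.

The wild/domestic orientation of the two latent populations is anchored by
initialising reference-labelled individuals in their parental classes (and
re-checked post hoc). Classes older than BC1W are deliberately not
modelled: old backcrosses get absorbed into PW or BC1W — a documented
negative property of the class set, reproduced by the tests, not a bug.

## Synthetic reference populations (`hybridgate.synthref`)

The empirical wolf/dog reference genotypes behind the motivating study are
not redistributable, so the package generates synthetic parental pools that
emulate their one essential property: strong, stable differentiation.

Per locus, an ancestral frequency vector is drawn from a symmetric
Dirichlet(1) over 8 alleles, and each population draws its own vector from
Dirichlet(ancestral × (1−F)/F) — a multiallelic Balding–Nichols
construction in which F is the target FST between either population and the
ancestor. Defaults: 39 loci, 8 alleles per locus, F = 0.30, 100 wild + 95
domestic reference individuals (well above the ~40-per-pool floor usually
recommended for reference populations in admixture assignment).
No definitive wolf–dog FST exists for such STR panels; F = 0.30 was
chosen once as the value that reproduces the qualitative K=2 behaviour of
the empirical system (complete reference separation, F1 at q ≈ 0.5,
backcrosses merging into the wild cluster from about the fifth generation)
and is validated only at that level. Realized differentiation is checked
with a multi-locus Weir–Cockerham θ estimator.

What the generator does **not** emulate: within-pool substructure (village
dogs plus many breeds are a heterogeneous pool in reality), linkage,
mutation, null alleles, and any geographic signal. Passing tests therefore
demonstrate correctness of the machinery under idealised two-pool
conditions, not field performance on any particular population.

## Hybrid ladder simulation (`hybridgate.hybsim`)

Twelve classes: PW, PD, F1, F2 and BC1W–BC8W (wild-direction backcrosses
only). Parental gametes are drawn from the population frequency pools;
gametes of every later generation are drawn from simulated individuals (one
random parent, one random allele per locus, loci independent). Drawing
later-generation gametes from individuals rather than refitting frequencies
preserves the within-individual correlation of ancestry across loci, which
is what makes the variance of q among old backcrosses realistic. The wild
gamete of each backcross comes from the wolf frequency pool — equivalent
in distribution to sampling simulated PW individuals, and simpler.
Everything is selectively neutral, so the expected domestic ancestry of
BCnW is exactly 0.5^(n+1) (BC8W < 0.2%).

## Genotyping-error injection (`hybridgate.errorsim`)

Allelic dropout is applied per heterozygous locus call (with the given
probability one allele, chosen uniformly, overwrites the other), missing
data per locus call, in that fixed order — so a dropped-out call can still
go missing. The per-heterozygous-call reading of the ADO rate follows the
convention of the standard genotyping-error simulators for microsatellite
pilot studies. The robustness metric is the mean absolute difference of
posterior mean q_wild across individuals between clean and degraded runs
("discrepancy" — a quantity this family of robustness analyses reports
without a standard formula; mean |Δq| is this package's declared reading).

## Threshold selection and classification (`hybridgate.thresholds`)

Candidate thresholds run 0.500–0.995 in steps of 0.005 plus a terminal
0.999 (101 values). Splits of the simulated ladder into a non-admixed and
an admixed side are nested, moving one class at a time from {PW}|{rest} to
{PW, BC8W…BC2W}|{BC1W, F2, F1}; F1, F2 and BC1W never reach the pure side,
and the domestic parental is excluded throughout (classification is against
the wild cluster only).

For each cell, efficiency = flagged true admixed / all true admixed
(sensitivity) and accuracy = flagged true admixed / all flagged (positive
predictive value); performance is their product. The literature on this
style of performance analysis admits a second reading of "accuracy"
(recall-like); both are
implemented behind `mode=` with the one-sided PPV reading as default, and
the acceptance checks are on the qualitative optimum location, which is
insensitive to the choice.

`t_recent` is chosen conservatively: among splits whose best performance
reaches 0.90, take the highest threshold on each split's max-performance
plateau, then the highest across splits. `t_pure` is the minimum q_wild of
all wild parental individuals (reference + simulated), floored to 3
decimals so the defining individual still counts as pure. Classification
is a three-way partition with closed lower boundaries: q ≥ t_pure → pure /
operational pure; t_recent ≤ q < t_pure → older admixed / introgressed;
q < t_recent → recent admixed / operational hybrid. Type-I error: truly
pure individuals not classified pure; type-II: truly admixed classified
pure.

## Evidence integration (`hybridgate.report`)

Uniparental markers (mtDNA, Y-STR haplotypes), the K-locus 3-bp deletion
and phenotypic flags never change a q-based category; they annotate it. A
pure-classified carrier of any dog-derived marker is flagged as a possible
older admixed individual. Y-haplotype percentages always use the male-only
denominator. Welch's t-test is used wherever group CI widths are compared
(the variance-equality assumption is clearly false between parental and
admixed groups). The CI-width/q relationship is summarised by Pearson
correlation.

## Problem sizes used by the tests and the acceptance script

* Main fixture: 39 loci × 8 alleles, F = 0.30, 100 + 95 references, chains
  5×10³/2×10⁴ — used for the F1-detection (50 F1), robustness (5 per class
  across all 12 simulated classes, 30% ADO + 30% missing; the discrepancy
  metric is defined over the whole simulated sample, parental and admixed
  classes alike) and reference-anchoring checks.
* Ladder-shape fixture: 60 + 60 references, 16 individuals per class over
  PW + all ten admixed classes, chains 2×10³/10⁴ — enough to resolve the
  qualitative q ladder (medians, CI widths, overlap with the pure region).
* Genoclass fixture: 40 + 40 references, 12 per class, chains 2×10³/10⁴.

These sizes are the package's chosen trade-off between Monte-Carlo noise
and turnaround; all are configurable upward.

## Known limitations

* Only K = 2 and the independent-frequencies model; no correlated
  frequencies, no LOCPRIOR, no multi-run cluster matching (the one-by-one
  design makes the latter unnecessary).
* The genotype-class model stops at BC1W by design; deeper pedigree classes
  are not identifiable with marker panels of this size.
* Synthetic references idealise the parental pools (see above); absolute
  error rates measured on the fixture transfer to real systems only to the
  extent that the real wild/domestic differentiation matches F ≈ 0.3 at
  comparable locus numbers.
* The synthetic 8-allele loci carry less per-locus information than highly
  polymorphic empirical microsatellites. One visible consequence under
  heavy simulated genotyping error (30% dropout + 30% missing): because the
  shared admixture hyperparameter α is inferred small when almost all
  individuals in a chain are pure, the prior on q is U-shaped, and an
  intermediate-ancestry query that loses a third of its heterozygous signal
  is pulled toward an extreme — the mean q discrepancy of recent hybrid
  classes can then exceed the few-percent level that highly diagnostic
  empirical panels achieve. The robustness test computes this discrepancy
  over the full simulated ladder and reports it as measured.
* The threshold pair is a property of the marker panel and reference
  system; 0.955/0.995 are not universal constants and should be re-derived
  per study system.
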