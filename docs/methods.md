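# Methods

## The admixture test

The core procedure treats each locus as an independent witness of a strain's
ancestry. Haploid consensus sequences (one per strain per locus, pre-aligned)
yield per-locus F84 distance matrices, neighbor-joining trees, and bootstrap
supports; reference strains — at least two prespecified members of each
population — anchor population identity inside each tree. A query strain is
assigned per locus by the supported groups it shares with references, and a
strain is called admixed only when two loci carry labels that cannot belong
to one population. The test is deliberately conservative: weak signal at a
locus produces "undefined", which never conflicts with anything, so missing
resolution reduces sensitivity rather than inflating false positives. This is
the property that distinguishes it from ancestry-proportion thresholding,
which can misread plain divergence from the reference panel as admixture.

## Distances

F84 distances use the standard closed form (see README) with base
frequencies pooled over all sequences and sites of the locus, not per pair —
per-pair frequencies degenerate on short loci. Missing data (`N` from
quality masking, `-` from alignment gaps; any IUPAC ambiguity code collapses
to `N` on input) are handled by **complete (global) deletion** by default:
every column containing missing data in any sequence is excluded for all
pairs, matching the default semantics of the distance implementation the
workflow descends from. Pairwise deletion is available by flag. A pair whose
transition/transversion load pushes an F84 logarithm argument to ≤ 0 is
*saturated*: the distance is flagged invalid rather than raised as an error.
An invalid entry aborts the main tree (a tree from a partially invalid
matrix is meaningless); in bootstrap replicates it voids only that
replicate, which is dropped from the support denominator (a warning fires
when more than 1% of replicates are dropped).

## Trees and support

Neighbor joining follows Saitou–Nei agglomeration with the Studier–Keppler
criterion. Ties in the criterion break to the lowest (row, column) index
pair in the current matrix order, so output is bit-stable across platforms.
Negative branch lengths are retained as computed (logged, never clamped),
and the final three-way join is kept as a trifurcating root, so the tree is
effectively unrooted.

Bootstrap support is computed on **unrooted bipartitions**. Rooted "clades"
depend on a plotting convention; bipartitions do not, and both sides of each
supported bipartition are exposed as candidate groups so the assignment rule
can rely on reference purity rather than on an arbitrary root. Support is
the percentage of valid replicate trees containing the bipartition; the
default of 10,000 replicates per locus is configurable (tests and the
synthetic validation use 200, which puts the Monte-Carlo standard error of a
support value near 70% at about 3 percentage points). Column resampling is
implemented as multinomial column weights over precomputed per-column pair
indicators, which makes a replicate a single matrix product rather than a
fresh alignment scan. One master seed yields an independent, reproducible
substream per locus.

## Assignment and calling

Within one locus, every supported group containing the query and at least
one reference votes: all references from one population → that population;
references spanning several populations inside a single supergroup → the
supergroup; references spanning supergroups → uninformative ("mixed") and
ignored — every strain sits in near-root groups containing all references,
so only ref-pure or supergroup-pure groups carry information. If the
surviving labels are hierarchically compatible the most specific wins; any
conflict within the locus collapses to "undefined" (conservative; this also
covers the possibility of a strain grouping with population X on one side of
one edge and population Y inside a larger group of the same tree).

Across loci, two labels conflict unless one is "undefined", they are equal,
or one is the other's supergroup. Two distinct populations always conflict —
including the two members of one supergroup. A strain with any conflicting
pair is admixed; the populations involved are the distinct defined labels
after each supergroup label with an observed member population is absorbed
into that population (after this collapse all remaining labels are pairwise
incompatible). The **majority component** — our operationalization of the
"main" genome — is the compatible label set (a population plus its own
supergroup, or a bare label) covering the most defined loci; ties break
toward more population-level loci, then lexicographically, and are logged.
Defined loci outside the majority component are minority loci;
`n_minority_loci == 1` marks single-locus admixture, the signature of
backcrossing after hybridization.

The threshold classifier consumes an externally produced ancestry (Q)
matrix; the Bayesian clustering MCMC itself is out of scope. A strain is
admixed when its top ancestry proportion is strictly below 0.94 — the value
equivalent to one locus in sixteen from another population (15/16 =
0.9375 < 0.94). The synthetic generator emits a pseudo-ancestry matrix (the
true fraction of loci from each source population) to exercise this path
without an MCMC run.

## Exact tests

Habitat × admixture tables use the probability-mass two-sided convention:
p = total null probability of all tables with the observed margins whose
probability does not exceed the observed table's, with a relative tolerance
of 1e-7 on the comparison to avoid floating-point boundary misclassification.
The 2×2 case delegates to `scipy.stats.fisher_exact`; the r×c
(Freeman–Halton) case enumerates tables depth-first by rows with pruning on
remaining column margins, guarded at ~10⁷ candidate tables, with a
seeded Monte-Carlo fallback (permutation of individual-level column labels;
(1 + hits)/(1 + reps) estimator with standard error) for larger tables.
Proportions are reported unrounded; display rounding is left to the caller.

## The synthetic generator

The generator emulates the study conditions: seven populations, two
two-member supergroups ("European", "USA"), sixteen loci, two reference
strains per population, between-population divergence far above
within-population diversity. Populations sit on a star phylogeny —
independent stems from one uniform-composition ancestral sequence per locus
— except that supergroup members share the first half of their stem, so
supergroup-level signal arises naturally. Mutation uses a Jukes–Cantor
kernel (per-site substitution probability; a mutated site takes one of the
other three bases uniformly), deliberately *not* the F84 inference model, so
generator and inference stay independent. Admixed strains receive a freshly
drawn donor-population strain sequence at the designated loci; habitats are
assigned by a configurable rule (planted-admixed strains default to
"fruit_or_flower", others to "oak_or_other_trees") purely to exercise the
contingency-table stage.

Defaults: stem divergence 0.10 expected substitutions/site, tip diversity
0.005 (a 20:1 separation, comfortably above the ≥10:1 regime the assignment
rule assumes), locus length 800 sites (about the per-locus share of a ~13 kb
sixteen-locus dataset). The validation runs use locus length 300 — still
≥150 segregating sites per locus across seven populations — with one query
per population plus three planted admixed strains (1, 2 and 4 donor loci),
200 bootstrap replicates per locus, and 20 independent seeds; these sizes
are the package's chosen validation scale and complete in a couple of
minutes on one CPU. Observed recovery at this scale: sensitivity 1.0,
false-positive rate 0.0 (the acceptance script recomputes both).

What the generator does **not** emulate: recombination within loci,
coalescent variance in within-population genealogies, selection, real
centromere base composition, incomplete lineage sorting, and
sequencing/masking error beyond what the user plants. Passing recovery tests
therefore show the pipeline is correct under clean separation, not that real
data will be as easy; on real data the "undefined" rate rises and
sensitivity falls before false positives appear, by construction of the
conflict rule.

## Numerical and design notes

- Alignment columns are stored with gaps; deletion policy is applied at
  distance time, so both policies can be run from one dataset object.
- Reference strains must be present, with at least one unambiguous base, at
  every locus (they define the allele pools); queries may be absent from a
  locus, which then yields no assignment for them.
- The NJ bootstrap tensors are float32: entries are small integer counts,
  exactly representable, and memory halves on 80-strain loci.
- All randomness flows from explicit seeds: per-locus substreams via
  `SeedSequence(master, spawn_key=(locus_index,))`; simulation, bootstrap
  and Monte-Carlo tests each take their own seed.
- Exact-test enumeration is deterministic; its Monte-Carlo fallback reports
  p ± s.e. and matches the exact value within sampling error on tables where
  both are computable (tested).

## Known limitations

- With very few informative sites a locus can support a wrong-population
  group by chance; the <70% filter and the conflict-to-undefined collapse
  bound, but do not eliminate, this (observed wrong-supergroup label rate on
  synthetic data: <1% of strain-locus pairs).
- Bootstrap support near the 70% threshold is Monte-Carlo noisy at low
  replicate counts; borderline groups can flip between runs with different
  seeds unless the full 10,000 replicates are used.
- The concordance between the conflict caller and the threshold classifier
  on the original survey (55/66 strains) requires the original sequences and
  external clustering runs and is not reproduced here; the comparison path
  is exercised on synthetic pseudo-ancestry instead.
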