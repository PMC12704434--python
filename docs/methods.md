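# Methods

This note records the models, estimators and numerical choices behind
`panbgc`, the assumptions they rest on, and what the synthetic test bed
does and does not establish about real data.

## The population model

A gene cluster family (GCF) is treated as a population of biosynthetic
gene clusters (BGCs), analogous to genomes within a bacterial species.
The unit of comparison is the ortholog group (OG): genes across members
judged homologous. All statistics operate on the BGC × OG copy-number
matrix; gene order enters only through the consensus-order layout, never
through the openness metrics.

Assumptions inherited from this framing:

- family delineation is taken as given (the package consumes
  already-clustered families; the clustering tools themselves are out of
  scope);
- every gene belongs to exactly one OG (orthology is a partition, not a
  graph);
- presence, not copy number, determines prevalence — a tandem duplication
  does not make an OG "more core".

## Core / accessory / unique classification

With n members, an OG present in k of them has prevalence k/n. It is
**core** when k/n ≥ t (default t = 1.0), otherwise **unique** when k = 1,
otherwise **accessory**. Core is tested first, so in a single-member
family every OG is core rather than unique: prevalence-1.0 OGs are
definitionally core, and single-member families are excluded from
openness anyway.

The default threshold is 100 % rather than the 95 % conventional for
genomes: clusters hold tens of genes, not thousands, and a 95 % cutoff
would inflate the core whenever just a few members differ. The threshold
is adjustable per call.

The comparison k/n ≥ t runs in exact rational arithmetic. Float
thresholds are first snapped to the nearest small-denominator rational
(`Fraction(t).limit_denominator(10^6)`), so t = 0.75 means exactly 3/4
and 19-of-20 members passes t = 0.95 exactly. Without the snap, the
binary representation of 0.95 sits a hair above 19/20 and silently
demotes a boundary OG.

## Consensus gene order

Members are recorded on arbitrary strands, so each member is first
orientation-normalized: the Spearman rank correlation between its OG
order and the first member's (over shared OGs, first occurrences) is
computed, and the member is reversed when the correlation is negative; a
correlation of exactly zero, an undefined correlation, or fewer than two
shared OGs keeps the member as-is. Each gene then receives the normalized
rank position/len(member), an OG's score is the mean normalized rank of
its copies over members containing it, and OGs are sorted ascending by
score with ties broken by higher prevalence, then lexicographic OG id.
The procedure is deterministic and orientation-invariant; it is a
re-derivation, not a reimplementation of any external tool's unpublished
ordering, so numeric agreement with other pipelines is not promised.

The **maximum BGC** is all OGs in consensus order (the family's merged
gene inventory); the **core BGC** is the subset meeting the core
threshold. An empty core list is a valid result and is flagged in the
summary rather than raised.

## Openness metrics

For each of P sampling permutations of the n members (default P = 30; all
n! orders enumerated exactly once when n! ≤ P, which holds for n ≤ 4 at
the default and removes Monte-Carlo noise for the small families that
dominate real collections), three cumulative curves are tracked:

1. **gene_repertoire** — distinct OGs seen after x members;
2. **composition** — distinct OG presence-sets seen after x members
   (sets, not multisets: copy numbers and gene order are ignored, so the
   metric isolates combinatorial reshuffling; a multiset mode is
   available behind a flag);
3. **novel_gene** — OGs appearing for the first time. The default counts
   distinct OGs at first appearance, which makes the cumulative curve
   coincide with metric 1; an alternative mode counts every gene copy
   belonging to a first-seen OG. Both readings of "newly appearing genes"
   are defensible, so both are implemented and the choice is explicit.

Curves are averaged column-wise over permutations and the mean curve is
fitted (fitting each permutation's curve and summarizing the γ
distribution is available as a diagnostic; fitting the mean is the
default because one exponent per family per metric is wanted and the mean
curve is stabler at small n). Families with fewer than three members are
refused — two points cannot constrain a power law — and the summary
records the reason instead of a result.

## Heaps'-law fitting

y = k·x^γ is fitted three ways:

- **loglog** — OLS of log y on log x; k = exp(intercept), γ = slope.
- **weighted** — the same regression with weights w_i = x_i (other
  increasing rules and arbitrary callables accepted), de-emphasizing the
  noisy early points.
- **nls** — bounded non-linear least squares on the original scale
  (`scipy.optimize.least_squares`, trust-region reflective), initialized
  from the loglog estimate clipped into bounds, k ≥ 10⁻⁹,
  γ ∈ [0, 2]. The γ cap is generous — exponents above 1 are already
  super-linear — and prevents divergence on pathological curves.
  Parameter/function tolerances default to 10⁻¹⁰ with a 200-evaluation
  budget; non-convergence returns the last iterate flagged
  `converged=False` with a warning rather than raising.

All three report R² on the **linear** scale, 1 − SSE/SST against
k·x^γ: a log-space R² and a linear-space R² are not comparable, and model
selection takes the single highest R². Exact ties break loglog >
weighted > nls (simplest method wins). For a zero-variance curve
(SST = 0, e.g. a constant composition curve of an identical family) R² is
defined as 1.0 when the fit is exact and 0.0 otherwise, so the γ = 0 fit
of a flat curve is selectable.

Openness categories follow the convention: γ < 0.3 closed, γ > 0.6 open,
boundaries inclusive to intermediate (the closed threshold is a strict
inequality).

γ distributions (e.g. repertoire vs composition across many families) are
compared with a tie-corrected Kruskal–Wallis rank test; H is computed
from the rank formula directly so that fully tied data gives H = 0 and
p = 1 instead of an error, and the p-value is the χ² upper tail at
(groups − 1) degrees of freedom. On non-degenerate data the statistic
matches `scipy.stats.kruskal` to machine precision (asserted in tests).

## Greedy ortholog grouping

A deterministic, self-contained grouper for when no external ortholog
table is supplied. Pairwise similarity is a unit-cost global
(Needleman–Wunsch) alignment via edlib; identity = identical aligned
positions / length of the shorter sequence, gated by the length ratio
shorter/longer ≥ coverage (default identity 0.5, coverage 0.7 — a
conventional protein-homology working point, exposed as flags). Edges
above threshold feed single-linkage connected components; transitive
closure is deliberately permissive, suiting the modular, repetitive genes
of biosynthetic clusters better than reciprocal-best-hit schemes.
OG ids are assigned in first-appearance order, so the output is
deterministic for a given input order. Genes lacking a translation
qualifier are conceptually translated from the nucleotide span when the
record carries sequence; genes with neither are an error naming the gene.

Raising the identity threshold can only split components, never merge
them (refinement monotonicity, property-tested). Note single linkage can
chain A–B–C into one group even when A and C fall below threshold; this
is by design.

## Synthetic family generator

The generator emulates exactly the structure the statistics assume: a
core present in every member, an accessory pool sampled per member with
probability p, fresh never-reused unique OGs at Poisson rate λ, optional
tandem duplication, order shuffling with strand randomization, and
terminal truncation that sets the contig-edge flag. Proteins are per-OG
random templates with per-copy point substitutions at `mutation_rate`
(default 0.02 — close enough for unambiguous grouping, far enough to
exercise the aligner); expected OGs per member is core + p·pool + λ.
Default study conditions (10 members, core 5, pool 5, p = 0.5, λ = 0.5,
150-aa proteins) mirror a typical mid-size family: mean non-singleton
family sizes in large collections sit near 9–10 members with a conserved
scaffold plus a modest variable complement. A member that would be
generated empty under a sparse spec receives one fresh unique gene so
records stay non-empty. GenBank emission uses deterministic
reverse-translated coding sequences with 50-nt spacers, so parsed
fixtures conceptually translate back to the exact proteins.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: biological sequence
composition and domain architecture; boundary-prediction error (real
cluster borders are inferred and often include flanking genes); orthology
ambiguity between paralogous tailoring enzymes; phylogenetic correlation
among members (members are i.i.d. given the family parameters, whereas
real members share descent). Results on synthetic families validate the
*estimators*, not the biology.

## Tanglegram crossings

Gene-tree vs cluster-tree discordance is summarized as the inversion
number of the permutation induced by the two leaf orders, over the
intersection of their label sets (leaves on one side only are dropped and
the shared count reported). Counting uses merge sort (O(m log m)) and is
property-tested against the O(m²) pair check. Leaf orders are taken from
the trees as serialized — no layout optimization — because a
deterministic, layout-faithful count is the honest statistic; an optional
greedy rotation pass that accepts only crossing-reducing child flips is
provided (off by default) to separate topological discordance from
drawing artifacts. The normalized statistic is crossings / (m(m−1)/2).
No numeric congruence statistic is standard for tanglegrams; this count
is this package's formalization and is labelled as such.

## Degenerate inputs and edge behavior

- Families of one or two members: classified and reconstructed normally;
  openness is null with a reason string.
- GenBank records with zero CDS features: an error (a cluster must
  contain genes); unparseable files: a format error naming the file and
  offending line where the parser reports one.
- Compound (join) CDS locations collapse to their min-start/max-end
  envelope with the feature's strand — the framework needs gene order,
  not exon structure.
- Missing locus tags: ids synthesized as `<bgc_id>_g<ordinal>` in
  position order; parsing order is ascending start, ties by end then id.
- Ortholog tables must cover every gene exactly once; missing, unknown
  and conflicting assignments raise distinct errors naming the genes.
- The per-OG "diversity" field in the JSON summary is reserved and
  emitted null: no estimator for it is defined here.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
exhaustive permutation oracles up to 6 members (720 orders), fit-recovery
batteries of 20 noisy curves at n = 30, classification sweeps over 100
seeded families, grouper-recovery runs over 20 families of ~25–30 genes,
and a 60-family openness survey at 9 members each. These sizes were
chosen so every statistic is estimated stably while the whole battery
completes in seconds; all are constants in the code, not tunables.
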