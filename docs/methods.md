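# Methods

This note records the models, conventions and numerical choices behind
`minibarkit`, in the order the pipeline runs them.

## Alignment handling

Input is an aligned FASTA over the IUPAC nucleotide alphabet plus `-`;
input is case-insensitive, stored upper-case, and `U` is mapped to `T`.
Taxonomy comes from `id|order|family|genus|species` headers (delimiter
configurable) or a sidecar TSV, which takes precedence — the field has no
machine-readable convention for taxonomy in FASTA headers, so both routes
are supported. All coordinates are 1-based and inclusive, the convention
used when citing positions on reference mitogenomes.

`trim_ambiguous_ends` removes terminal columns whose fraction of `-`/`N`
exceeds `max_missing_frac` (default 0.5 — i.e. a terminal column is dropped
when most sequences have no call there); interior columns are never
touched, so the operation is idempotent and returns the retained column
range on the input frame.

## Distances

Both models use *pairwise deletion*: a site enters a pair's comparison only
when both sequences carry an unambiguous A/C/G/T. Ambiguity codes are
excluded outright rather than fractionally matched — simpler semantics and
exactly testable. The K2P distance is
`-1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))` with P/Q the transition/transversion
proportions; when a log argument is non-positive (substitution saturation)
or no sites are comparable, the cell is *undefined*, stored as NaN,
excluded from summaries, and treated as +infinity by delimitation (never
within a threshold, never a nearest neighbour) and as the matrix maximum
when a tree must still be built. The all-pairs computation is vectorized
over one-hot base masks; the scalar per-pair functions are kept as the
reference implementation and the test suite asserts elementwise agreement.

Divergence summaries report percent min/mean/max per pair class:
intraspecific (same species), intrageneric (same genus, different
species), intrafamilial (same family, different genus), and interspecific
defined as *all* heterospecific pairs — the intrageneric and intrafamilial
classes are overlapping subsets reported separately, which is the only
reading consistent with interspecific ranges that span across orders.
Empty classes are reported as empty, not zero. Tables round to two
decimals; raw values stay available in memory.

## Neighbor joining and bootstrap

Standard Saitou–Nei agglomeration with two determinism rules: Q-criterion
ties break to the lowest (row, column) pair in the current matrix order
(input order, merged nodes appended), and a negative branch length is
clamped to zero with the deficit moved to its sister branch (floored at
zero), preserving the path length through the join where possible. On
additive matrices the algorithm provably recovers the generating topology;
the suite checks this up to 12 taxa and, for 5–6 taxa, against exhaustive
topology enumeration with least-squares branch fitting.

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree per replicate, and reports for each original internal edge the
percentage of replicates containing the same bipartition — support is
annotated on the original-data tree, not a consensus. The default is 1,000
replicates (support percentages stabilise well below that for the library
sizes targeted here); rendered Newick hides supports below 80% while the
full values remain on the tree object. Bipartitions are canonicalised to
the side not containing the lexicographically smallest leaf.

`shared_clade_proportion(window_tree, reference_tree)` divides the shared
nontrivial splits by the *window* tree's split count by default; the
denominator is switchable because either convention is defensible when
comparing a short-region tree against the full-length tree.

## Window screening

Windows of 70 bp stepped by 10 bp (both configurable) are scored on:
mean pairwise K2P distance over defined pairs; the proportion of
heterospecific pairs at distance exactly zero (the direct measure of
indistinguishable species pairs); clade congruence of the window NJ tree
with the full-length tree; and the summed count of species-diagnostic
columns in the window. A column is diagnostic for a species when all its
specimens share one unambiguous base that occurs in no other species at
that column; a gap or ambiguity inside the species disqualifies the
column, while gaps in other species simply never match a base. Incomplete
terminal windows are dropped by default (flag to keep). Windows whose
distance matrix is entirely undefined get congruence 0.

The four criteria are combined by rank-sum (average ranks on ties, final
ties to the earlier start). Any monotone aggregator would do — the choice
of "best on all criteria" is inherently a reading of four curves — and
rank-sum is scale-free, so no criterion dominates by units.

## Primer toolkit

The per-column mismatch profile counts sequences differing from the
majority A/C/G/T base (ties resolved to the alphabetically first base);
columns containing any gap are flagged with the sentinel value 10 so they
are visually distinct in plots of mismatch counts.

Primer enumeration slides windows of 18–24 bp (bounds configurable within
15–30) over the alignment consensus, keeps windows free of gap columns
whose worst per-sequence mismatch count is within `max_mismatch_per_seq`
(default 0: strictly conserved), and filters on GC fraction 0.20–0.80 and
melting temperature 57–63 °C. Tm uses the salt-adjusted Wallace/Marmur
closed form `Tm = 64.9 + 41 (GC_count - 16.4) / N`; primer-design suites
delegate Tm to nearest-neighbour thermodynamics, but nothing downstream
depends on Tm beyond the 57–63 °C band, so a closed form is preferred over
embedding thermodynamic tables (a config hook accepts an alternative
callable). Amplicon length counts **both primer footprints inclusively** —
the convention under which a 639–831 footprint span is a 193 bp amplicon.
Pairs are sorted by total mismatches, then amplicon length.

In-silico PCR scans every offset of both strands of unaligned templates.
The default (`lenient`) binding rule rejects a site only when it has at
least 3 total mismatches *and* at least 3 mismatches within the 5-base
3′-terminal window — the unintended-target exclusion criterion of
Primer-BLAST inverted for intended targets, reflecting that 3′-end
complementarity is what polymerase extension actually requires. The
conjunction makes the rule deliberately permissive on total mismatches; a
`strict` rule (both bounds must be beaten) is available where a
high-confidence product list is wanted. Degenerate template bases match
when the primer base is contained in the ambiguity set. Products longer
than 400 bp are discarded. Primer mapping reports each primer's
lowest-mismatch site per strand (ties to the leftmost) without a
stringency cut, and the pairwise overlaps between different primer sets'
amplicons.

## Species delimitation

For query `q` and threshold `t`, the match set is
`M(q, t) = {r != q : d(q, r) <= t}`. TP: M non-empty and purely
conspecific; FP: M contains any heterospecific (even alongside
conspecifics — a contaminated match set is an identification error); FN: M
empty though conspecifics exist; TN: M empty and the query is a singleton.
Singletons participate as queries (contributing TN/FP); they are excluded
only from the nearest-neighbour and barcode-gap diagnostics, which are
undefined for them. The default threshold grid is 0.05% to 5% in 0.05%
steps. `optimal_threshold` returns the smallest grid value attaining the
minimum cumulative error — the most conservative choice, which errs toward
splitting rather than lumping. MOTUs are single-linkage connected
components of the graph joining pairs with `d <= t`; "no id" sequences are
necessarily singleton MOTUs. Nearest-neighbour ties count as correct when
any tied neighbour is conspecific.

The ABGD-style partitioner sorts all defined pairwise distances and, for
each prior maximum intraspecific divergence P (default: 10 log-spaced
values in 0.001–0.1), finds the first inter-rank interval whose *upper*
edge exceeds P and whose width exceeds X (default 0.8) times the local
scale, taken as the mean of the preceding 10 inter-rank gaps (fewer near
the start; at least one is required). Qualifying the interval by its upper
edge matters: a prior lying inside the barcode gap must still be able to
detect the gap that brackets it. Sequences linked below the gap form
groups and the procedure recurses within groups until stable; groups of
fewer than 3 sequences cannot split further. Degenerate inputs (no
significant gap) return a single group. All constants sit in `AbgdConfig`.

## Synthetic data generator

The generator emulates a curated single-marker reference library: by
default 67 species and 132 specimens (19 singleton species; the rest carry
2–3 specimens), 565 alignment columns. Species relationships follow a
random ultrametric tree whose split depths are uniform between
`0.75 * target_inter` (so the closest species pair sits at expected
distance 1.5× the 2% minimum target) and 0.08 substitutions/site (deepest
pairs near 30% divergence, the scale seen between orders). Specimens hang
off their species with branch lengths uniform in `[0, target_intra / 2]`
(default target 0.4%), giving intraspecific distances in the ≈0–2% range
with most mass near zero. Sequences evolve under the two-rate Kimura model
(transition/transversion rate ratio κ = 2, a typical mitochondrial value)
using the exact finite-time substitution probabilities — the same model
family the distance stage assumes, so parameter recovery is a clean
end-to-end test rather than a model-mismatch exercise.

Two 20 bp conserved blocks (columns 321–340 and 481–500 at the default
length; positions scale with `seq_length`) are held invariant and given
65% GC content — the composition a 57–63 °C Tm band implies for a 20-mer —
so primer enumeration has satisfiable planted targets bracketing a
variable core. Short 1–3 column deletions are injected per specimen
(Poisson, mean 0.5) outside the blocks, mimicking alignment indels without
modelling indel evolution. Optional ragged `N`-padded ends exercise
trimming. The fixture bundle also writes a gap-free template (the root
sequence with 100 bp random flanks) carrying the conserved blocks
verbatim, so in-silico PCR has planted answers, plus a ground-truth JSON
whose realized divergences are recomputable from the emitted alignment.

What the generator does **not** emulate: rate heterogeneity beyond the
conserved blocks, base-composition bias, indel evolution, sequencing
error, or misidentified taxonomy. Passing tests therefore demonstrate
correctness of the algorithms under the model the methods themselves
assume, not robustness of the methods to real-data violations of it.

A note on threshold optimisation under these conditions: the zero-error
region of the threshold scan begins at the largest nearest-conspecific
distance over queries, which can sit *below* the largest intraspecific
pairwise distance whenever a three-specimen species is chained (its
extreme pair bridged by the middle specimen — exactly what single-linkage
clustering permits). The most conservative optimal threshold then lies
below the pairwise maximum while still committing zero identification
errors and recovering the exact species count.

## Problem sizes and determinism

Defaults throughout are desk-scale: 1,000 bootstrap replicates (the CLI
requires an explicit seed for every stochastic stage), the 132 × 565
default bundle, and exhaustive tree enumeration only at 5–6 taxa in tests.
All randomness flows from a single integer seed per run; identical
configuration and seed reproduce bundles and reports byte-for-byte, which
the suite asserts via manifest checksums.
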