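# Methods

This note documents the models and procedures implemented in `metanet`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical decisions that pin down exact
behavior.

## Rank-product meta-analysis (`deg_meta`)

Each study contributes one fold-change ranking of its measured genes.
The per-gene fold change is computed from class means on the log2
scale, `FC = 2^(mean log2 tumor − mean log2 control)`; ranks are
assigned per direction (rank 1 = largest FC for "up", smallest for
"down"), with ties receiving the average rank. The rank product is the
geometric mean of a gene's ranks over the `k` rankings that contain it;
genes present in fewer than two rankings are reported but never ranked.

**Why ranks.** A per-study additive batch offset shifts every sample of
a study equally, so it cancels exactly in the within-study tumor−control
contrast and leaves the ranking untouched. Rank aggregation therefore
sidesteps the cross-study normalization problem that makes pooled
expression matrices unreliable across chip generations; the synthetic
generator plants exactly this hazard (see below) and the test suite
verifies the cancellation.

**pfp estimation.** The permutation null permutes each ranking's values
among its measured genes, independently per ranking and per
permutation, and pools all resulting null rank products. For the gene
at 1-based position `x` of the observed ranking with rank product `r`,
`pfp = #{null RP ≤ r} / (n_perm · x)` — the expected number of null
genes at least as extreme, divided by the number of genes called at
that threshold. The vector is then made monotone non-decreasing down
the ranking (running maximum) and capped at 1. Two numerical choices:

- Null counting uses `null ≤ r·(1 + 1e−12)`. Rank products are roots of
  small-integer products, so exact rational ties are common at toy
  scale and must count as "≤" regardless of floating-point rounding
  path; the slack is far below the spacing of distinct rationals at any
  practical problem size.
- `n_perm ≥ 100` is enforced; the resolution of a pfp at position `x`
  is `1/(n_perm · x)`.

Exactness is verified against full enumeration of all `(3!)² = 36`
joint permutations on a 3-gene/2-study instance. With no planted
signal, the fraction of genes at `pfp < 0.05` stays far below nominal
(the estimator is conservative because the running maximum only
inflates pfp), measured at ≈ 0.0002 over 10 null simulations.

**Two-stage calling.** Per platform group, a gene is called up when
`pfp_up < 0.01` and the group geometric-mean fold change is ≥ 2
(inclusive), down when `pfp_down < 0.01` and FC ≤ 1/2; the
group-level FC is the geometric mean across studies, consistent with
aggregation on the log scale (the arithmetic mean would not commute
with the within-study log2 contrast). The final DEG set intersects the
two groups and requires the same direction. An FDR threshold of 0.05 is
accepted anywhere 0.01 is, as both conventions circulate for this
design; 0.01 is the stricter default.

A `pairwise=True` option ranks every tumor×control sample pair
separately (the original formulation of the method). The default is one
ranking per study: it keeps the permutation null well-defined and cheap
at desk scale, at the cost of statistical resolution — with `k = 3`
rankings per group, `pfp < 0.01` is reachable only for genes whose
relative rank is within roughly the top 2–3%. The synthetic recovery
analyses are sized accordingly (see below).

## Steiner subnetwork (`ppi_network`)

Edge lists from multiple interaction databases are unioned into a
simple undirected graph (self-loops dropped, reversed duplicates
merged, multiplicity kept as `source_count`). All edges are unweighted:
the source databases provide no comparable confidence scores.

DEGs present in the background are terminals. Per connected component
holding ≥ 2 terminals, the Kou–Markowsky–Berman 2-approximation runs
with deterministic tie-breaking: BFS expands neighbors in lexicographic
order and keeps the lexicographically smallest parent at equal depth;
Kruskal's MST sorts edges by (weight, endpoints); closure edges expand
along the BFS tree rooted at the lexicographically smaller endpoint.
The union of expanded paths may contain cycles, so a spanning tree is
re-extracted and non-terminal leaves pruned to a fixed point. Output
cost is at most `2(1 − 1/ℓ)` times optimal (ℓ = terminal leaves of an
optimal tree); measured against exhaustive optima on random 12-node
instances the worst ratio is ≈ 1.25 and ≥ 96% of instances are within
1.2×.

The subnetwork handed downstream is the Steiner forest plus the
one-intermediary linkers (non-terminals adjacent to ≥ 2 terminals) plus
all background edges induced among the retained nodes. How the tree
reduction and the one-intermediary rule compose is a genuinely open
design point; the union was chosen because a bare tree has density
`(n−1)/(n(n−1)/2) → 0` and would make density-based module detection
degenerate, while the induced edges restore the local interaction
structure that the clustering is supposed to see.

## Dense modules (`module_detection`)

The exported `cohesiveness(V, G, p)` is the plain additive form
`w_in / (w_in + w_bound + p)` (internal edges over internal + boundary
+ penalty, unit weights). The greedy growth, however, maximizes the
per-node-penalty variant

    f_p(V) = w_in(V) / (w_in(V) + w_bound(V) + p·|V|),    p = 2,

which charges every member for its unobserved interactions. The scalar
form was tried first and rejected: adding any degree-1 neighbor leaves
`w_in + w_bound` unchanged while raising `w_in`, so absorbing every
pendant is always profitable and planted dense modules dissolve into
their fringe (planted-clique recovery 0/30 in the scalar form versus
97/100 in the final design).

Growth applies the single best add-external-neighbor or remove-member
move that strictly increases `f_p`, with deterministic tie-breaks
(additions before removals, lexicographically smallest node), stopping
at a local maximum. Additions are affinity-gated: a candidate must
already touch at least `min_density · |V|` current members. The gate is
the module's own admission criterion turned per-node — a member that
cannot individually meet the density the module must satisfy is not
allowed to join — and it is what prevents the greedy from annexing
loosely bridged background clusters (per-node penalty alone recovered
only 50/100 planted cliques).

Seeds are visited in decreasing-degree order, skipping covered nodes;
candidates with overlap score `ω(A,B) = |A∩B|²/(|A||B|) ≥ 0.8` are
merged by union to a fixed point. Survivors are filtered at size ≥ 7,
density ≥ 0.3 and separation p < 0.05, where the separation test is a
one-sided Mann–Whitney U comparing each member's in-module versus
out-of-module edge counts (chosen because it is distribution-free and
well-defined for any module; a binomial edge-count test against the
global density is available via `pvalue_method="binomial"`). The
module p-value definition is a stand-in: no canonical test exists for
this quality score, and the choice is documented rather than hidden.

## Hub rule (`hub_analysis`)

Within the analysis subnetwork, each module member's average unweighted
shortest-path distance to the DEG nodes is computed (self excluded for
DEG members; unreachable DEGs excluded and counted). A member is a hub
when its average distance is strictly below the module's lower quartile
(25th percentile, linear interpolation — the most common convention,
configurable) of member distances, and its subnetwork degree is ≥ 6.
The degree comparison is inclusive by default: the literal "more than
6" reading would exclude known degree-6 hubs reported for this very
rule, so ≥ 6 is the default and a `strict_degree=True` mode implements
the literal reading. The distance sum is reported alongside the mean;
the selection rule operates on means. Modules with fewer than 4 members
make the quartile ill-defined and raise.

## Validated rate (`validation_rates`)

For an up-regulated gene, the threshold is the mean control intensity
(log2 scale, equivalent to linear under a monotone threshold) and the
rate is the fraction of tumor samples strictly above it; strictly below
for down-regulated genes. Ties at the threshold do not validate —
measure-zero on real data, but pinned for exact toy arithmetic. Pooled
rates divide summed concordant tumor counts by summed tumor counts;
pooling by counts rather than averaging rates weights each cohort by
its size, which is the interpretation adopted for "total" columns in
this kind of validation table (the alternative is documented here, not
implemented).

## Enrichment (`enrichment`)

One-sided hypergeometric upper tail `P(X ≥ k)` per gene set, sets
intersected with the background first, zero-overlap sets excluded
before Benjamini–Hochberg correction. The background is the union of
genes actually measured in the expression studies, not the genome:
testing against the genome would reward platform coverage, not biology.

## IHC statistics (`ihc_stats`)

IRS = intensity grade × percent positive, on a 0–300 scale. Grade 0 is
admitted although classical scales list 1–3: a fully negative specimen
requires a zero factor (reported group means of 0.0 exist in this
setting). Group summaries use the sample SD (n−1); comparisons use
classical one-way ANOVA (with an explicit error when within-group
variance vanishes while means differ, and F = 0, p = 1 when the data
are constant); protein co-expression uses Pearson's r with the t-based
two-sided p-value.

## Synthetic data (`synthetic`)

**Expression.** Gene baselines are drawn once per simulation from
N(7, 1.5²) on the log2 scale (typical of normalized array output) and
shared across studies. Each study adds its own batch constant
~ N(0, batch_sd), a planted log2 effect on tumor samples only (positive
for up, negative for down; the same planted sets in every study — they
are the meta-analysis target), and iid Gaussian noise. Per-study panels
are random gene subsets of size `panel_overlap · n_genes` that always
contain the planted genes, emulating platform differences. Defaults
follow the multi-cohort design the pipeline targets: 3 studies per
platform group, 20 tumor/10 control per study, noise_sd 0.7, batch_sd
1.0. Recovery experiments plant 10 up + 10 down genes among 500 (a 4%
DE fraction, within the 1–10% range typical of tumor/normal microarray
comparisons and within the resolution of the k = 3 rank-product design
discussed above). Under those conditions the pipeline recovers ≈ 99% of
planted genes at `pfp < 0.01` and `FC ≥ 2` with no false calls
(averaged over 10 simulations).

What the generator does **not** emulate: probe-level effects,
intensity-dependent variance, correlated gene blocks, heavy-tailed
noise, or confounding between batch and class. Passing tests therefore
demonstrate that the inference machinery is correct and calibrated
under its own model — not that real cohorts satisfy that model.

**Networks.** Erdős–Rényi background (edge probability
`background_degree/(n−1)`) with planted modules re-sampled at their own
internal probability, optionally a hub node wired to a target set, and
a preferential-attachment background behind a flag for degree-criterion
testing. ER was chosen over scale-free as the simplest background under
which the density and cohesiveness thresholds are meaningful; planted
probabilities must exceed the background probability by construction.

**IHC.** Per-(group, protein) Gaussian draws for intensity and percent
positive, rounded/clipped to the valid ordinal and percentage ranges.

**Pipeline fixture.** `write_pipeline_fixture` builds a deterministic
end-to-end bundle: 150 genes, six planted DEGs, a 7-ring + hub module
designed so that exactly one gene satisfies the hub rule (average DEG
distance 1.0 versus quartile 1.6, degree 7), a sparse tail, a two-set
GMT and an IHC cohort. Every output of the pipeline is timestamp-free
JSON/GraphML with sorted keys, so reruns are byte-identical; this is
asserted in the test suite.

## Problem sizes

The test suite and the verification script use deliberately small
instances — 3-gene exhaustive permutation oracles, 12-node Steiner
instances with exact subset-search optima, 60-node module backgrounds
over 100 simulations, 500-gene recovery and calibration runs over 10
simulations, n_perm = 1000 (10 000 where an oracle is compared at
±0.02) — chosen so that every stochastic claim is backed by an exact or
brute-force reference and the whole verification completes in seconds.

## Known limitations

- Gene symbols are canonicalized by case/whitespace only; aliases
  (e.g. BGH3/TGFBI) are not resolved, because alias maps are
  version-dependent. Mismatches surface in the `unmapped` report.
- The module separation p-value is a pragmatic stand-in (see above).
- The single-ranking-per-study default trades statistical resolution
  for a clean permutation null; very large DE fractions cannot all
  reach `pfp < 0.01` with only 3 studies per group (use `pairwise=True`
  for the higher-resolution variant).
- Unit edge weights throughout; confidence-weighted or directed
  interactions are out of scope.
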