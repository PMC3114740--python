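# Methods

## Parsimony model

Characters are columns of state *sets*: a singleton for a fixed observation, a
larger set for a polymorphism, and the full declared state space for missing
(`?`) or inapplicable (`-`) cells. Missing and gap codings are deliberately
not distinguished — both enter the optimization as "any state allowed at zero
cost", which is the default scoring of the standard parsimony programs and the
only defensible reading when the data source does not separate unknown from
inapplicable. Under set-based dynamic programming, scoring a polymorphism as
uncertainty and scoring it as a minimum-cost choice are the same computation,
so the package does not need a switch between the two readings.

Tree length is computed by a generalized Sankoff recursion over every node:
`S(v, s) = Σ_children min_t [ cost(s→t) + S(child, t) ]`, with the tree score
`min_s S(root, s)`. Cost structures:

- **unordered** — unit cost between distinct states (Fitch lengths);
- **ordered** — `|i − j|` in rank units along the declared state order;
- **irreversible** — an explicit square cost table with zero diagonal,
  non-negative entries, and (typically) infinities for reversals. Used for the
  stratigraphic character.

Because the recursion is exact for arbitrary rootings and polytomies, one
implementation serves scoring, ancestral-state enumeration, and the
stratigraphic character. For repeated scoring during search, the matrix is
compiled once: all unordered columns are batched into a single padded numpy
group (padding states are unreachable at tips and can never lower an internal
path cost), ordered columns likewise, and each distinct irreversible cost
table forms its own group. Lengths for reversible cost structures are
invariant under rerooting (tested), so searches treat trees as unrooted.

**Minimum character length** (over all trees) follows the standard convention:
unordered = number of distinct fixed observed states − 1; ordered = range of
fixed observed states in rank units; cells carrying the full state set are
ignored, and partial polymorphisms are not counted — making the value a lower
bound, so homoplasy `h = length − min` is never negative. For irreversible
tables the bound charges each observed state its cheapest incoming transition,
exempting the costliest-to-reach state as the root; with the stratigraphic
character (all states observed, telescoping costs) this is exact.

**Between-character scaling** gives an ordered character of observed range *s*
the weight 1/*s*, so every variable ordered character has weighted minimum
length one, like a binary character; unordered multistate characters keep
weight 1. This prevents high-state-count ordered characters from dominating
the objective. **Implied weighting** minimizes `Σ_c h_c/(h_c + k)` with
concavity constant k (default 3, the value standard practice uses); h is
measured on scaled steps so ordered characters contribute in binary-equivalent
units, keeping one k meaningful across character types.

Floating-point tolerance for "equal length" is 1e-6 weighted steps everywhere
(tie detection in search, optimal tree sets, support differences).

## Tree search

Trees are manipulated in an unrooted convention (a trifurcating root, so each
non-root node is one unrooted edge). A search replicate builds a starting tree
by random-order stepwise addition, placing each taxon on the edge giving the
lowest score (ties broken by the seeded generator), then hill-climbs by
first-improvement SPR (which subsumes NNI) followed by TBR, accepting strict
improvements only. Equal-score optima are collected by a bounded
plateau walk over SPR neighbours (default cap 100 topologies per local
optimum; overall optimal-set cap 10,000). Scores are memoized by canonical
split set within a search, so plateau and re-scan costs stay low. Every
source of randomness flows from one integer seed; repeated runs are
bit-identical.

**Backbone constraints.** A constraint is a resolved tree on a taxon subset
plus a set of floating taxa. A candidate satisfies it when the candidate
restricted to the common tip set contradicts no backbone split ("compatibility"
semantics — the backbone may be less resolved than the candidate; the two
coincide when the backbone is fully resolved). During stepwise addition,
insertion positions that would contradict the restricted backbone are
excluded, which preserves feasibility; during swapping the full predicate
filters every accepted neighbour, and returned trees are checked post hoc.

**Exhaustive search** enumerates all unrooted topologies (3, 15, 105, 945,
10 395, 135 135 for 4–9 taxa) by stepwise insertion; it is the exact oracle
for every heuristic-path test and for branch support on small instances.

## Branch support

Bremer support runs a converse-constraint search — candidate trees containing
the tested split are rejected during search, giving exactness on small
instances rather than a penalty approximation — and reports the score excess
of the best clade-free tree. Double-decay support enforces the extant
backbone with the tested node collapsed (the collapse is performed after
rerooting at a tip outside the clade, because a root-adjacent clade's split
otherwise survives through its complement edge), lets every fossil float, and
requires the *extant-restricted* candidate to lack the tested split, so fossil
members of a clade never count toward the monophyly predicate. Since any tree
whose extant restriction lacks the split also lacks every full-tree clade with
that extant content, the ddBS feasible set is contained in the BS feasible
set and ddBS ≥ BS holds by construction (and is asserted in tests).

The crown-exclusion analysis enforces the extant backbone, floats all fossils,
and additionally requires one focal fossil to attach inside the clade spanned
by a crown's extant members (evaluated on the tree restricted to extant taxa
plus the fossil, rooted at an extant outgroup); the reported value is the step
cost relative to the backbone-only optimum.

Support searches offset the user seed by a CRC of the clade's tip labels so
each clade draws an independent but reproducible addition sequence. Display
conventions follow the field's reporting style: BS is rounded *up* to the
nearest tenth of a step, ddBS up to the nearest step (`format_bs`,
`format_ddbs`); raw values are always returned unrounded.

## Stratigraphic congruence

Node minimum ages take the oldest first-appearance datum (FAD) among a node's
descendants; last appearances are carried for reporting but play no role in
the fit statistics, which are FAD-based by definition. MIG is the sum of
parent-minus-child age differences over all non-root nodes. With
`G_min = FAD_max − FAD_min` and `G_max = Σ_tips (FAD_max − FAD_tip)`,
MSM\* = G_min/MIG (a consistency-index analogue) and
GER = (G_max − MIG)/(G_max − G_min) (a retention-index analogue). Extant tips
participate at age 0, which inflates G_max exactly as in empirical practice.
Polytomies are read as soft: all children of a polytomy share the parent's
age. Degenerate inputs: all FADs equal makes GER undefined (raised as an
error) while MSM\* is defined as 1 (MIG = 0 with zero range is a perfect fit).

The equivalent **stratigraphic character** has one state per distinct FAD,
ordered old → young, with cost(older→younger) = age difference and infinite
reversals; its Sankoff length equals MIG on every tree (exact, tested on
random trees). The number of states is always derived from the supplied age
table — note that published age tables can disagree with their own prose about
the state count (one well-known cetacean table lists 18 distinct codes, 0–9
and A–H, where the accompanying text says 17), which is why the builder never
hard-codes it.

Permutation significance shuffles the multiset of FADs across tips (ties
preserved) and reports `p = (1 + #{permuted MSM* ≥ observed}) / (n_perm + 1)`,
so the smallest attainable p with 999 permutations is 0.001.

## Topology tests

Per-character deltas are weighted length differences (tree B − tree A); their
sum equals the total length difference (asserted to 1e-9). Characters with
zero delta are excluded, standard signed-rank practice. The Templeton test
ranks |delta| with midranks for ties and is evaluated two-tailed: exactly, by
a dynamic-programme enumeration of the signed-rank distribution over all sign
assignments, for ≤ 20 nonzero deltas; by a normal approximation with
tie-corrected variance and a 0.5 continuity correction beyond that (the exact
mode is the reference behaviour; the approximation exists only for large
comparisons). The winning-sites test is the exact two-tailed binomial sign
test at p = 0.5 (scipy's `binomtest`). Both tests are symmetric under swapping
the trees.

## Ancestral states and homology

All most-parsimonious reconstructions are enumerated by backtracking through
the Sankoff tables: choose any root state achieving the minimum, then for each
child any state achieving `min_t [cost(s_parent→t) + S(child, t)]`; every
combination of local optima is a distinct MPR and all MPRs arise this way. The
enumeration cap (default 10 000) raises a descriptive error when exceeded;
homology classification degrades to "ambiguous" in that case.

ACCTRAN and DELTRAN are selected members of the MPR set, chosen in preorder:
DELTRAN keeps the parent's state whenever it is among the local optima
(delaying changes toward the tips, preferring convergence); ACCTRAN prefers a
differing state whenever one is among the local optima (accelerating changes
toward the root, preferring reversal). Remaining ties break to the lowest
state index, making both deterministic. On the classic two-MPR configuration
(two derived tips separated by primitive ones) DELTRAN yields two independent
origins and ACCTRAN one origin plus one loss, and both flavors are verified to
be members of the enumerated MPR set on random characters. Both require the
rooted orientation to be meaningful; the CLI accepts an explicit outgroup flag
to orient input trees.

A state shared by two tips (their observed sets must intersect on a state
fixed in at least one of them) is **homologous** in an MPR when some shared
state labels every node on the path through their most recent common
ancestor, **analogous** otherwise; aggregating over all MPRs yields H (all),
A (none), or ambiguous (mixed). Binary trait mapping (e.g. marine vs riverine
habitat) is the same machinery on a two-state unordered character, reporting
the branches that carry each transition so character changes can be
cross-tabulated against habitat states.

## Synthetic data generator

The generator emulates the structure of a total-evidence supermatrix, not any
particular dataset:

- **Trees**: a forward Gillespie birth–death simulation (defaults birth 1.0,
  death 0.4 per lineage-My — moderate turnover, enough extinct lineages to
  sample fossils from) stopped when the extant count first reaches
  `n_extant`; the present is drawn inside the waiting interval during which
  that count holds, so terminal branches have positive length. Fossil tips are
  a random subset of extinct lineages, carried at their extinction ages;
  unsampled extinct lineages are pruned. Draws whose shortest internal edge
  falls below `min_edge_ratio` (default 0.6) times the mean edge length are
  resampled, so every split of the true tree is in principle resolvable — the
  precondition of any recovery experiment; if the floor is unattainable at the
  requested size within the retry budget, the best-conditioned draw is used.
- **Characters**: continuous-time Markov chains on the true tree — unordered
  characters jump uniformly among the other states, ordered characters step to
  a neighbouring rank (reflecting at the ends). The per-character rate is set
  so the expected number of changes per character across the whole tree equals
  `change_rate` (default 1.0: roughly one change per character per tree, the
  slow-evolution regime in which parsimony is a consistent estimator; the
  true change counts are returned so the parsimony-is-a-lower-bound invariant
  can be asserted).
- **Missingness**: fossils lose their entire molecular block (`?`) plus a
  random fraction of morphology cells (default 0.25; the support-pattern
  experiments use 0.7, a realistic level of fossil incompleteness).
- **Ages**: with preservation rate 1, a fossil's FAD equals its true tip age;
  lower rates push the FAD up to a uniform fraction of the lineage duration
  earlier. LADs trail FADs by a small uniform offset for I/O realism; extant
  tips are pinned to the present. Fossil tips are point occurrences, not
  ranges, keeping the recovery tests internally consistent.
- The default configuration mirrors a combined-matrix shape at desk scale:
  12 extant + 8 fossil taxa, 60 morphology + 400 molecular columns.

Everything is bit-reproducible from `SimConfig.seed`.

**What passing tests do and do not show.** The generator produces cleanly
Markov-evolving characters on a correct tree with well-separated internal
edges and unbiased fossil sampling. Real matrices violate all of this —
correlated characters, ascertainment toward variable characters, rate
heterogeneity, biased fossil recovery — so the recovery rates measured here
(≈ 95% true-topology recovery at 200 characters on 12 taxa; GER of the true
tree beating a random topology in ≈ 100% of draws) are upper bounds on what
comparable empirical data could deliver, not predictions. What the tests do
establish is the correctness of the machinery: the heuristic search finds
exhaustively verified optima, supports match constrained-enumeration oracles,
and the stratigraphic statistics equal their closed forms.

## Numerical and design choices

- Optimal-tree sets are deduplicated by canonical split sets (integer
  bitmasks); plateau caps avoid unbounded most-parsimonious tree sets.
- Converse constraints are implemented by rejecting trees containing the
  tested split during search (a filter), not by penalties — exact on small
  instances, and it matches the semantics of the decay-index literature.
- ddBS enforces backbone-plus-converse-clade. An alternative reading enforces
  the converse clade only; with a fully resolved backbone the two differ only
  in how far non-tested extant relationships may rearrange. The enforced
  reading is the stricter and the one the module documents; sensitivity to it
  can be probed by passing a less resolved backbone.
- The pipeline runner executes stages in dependency order from one YAML
  config with an explicit seed, writes standard formats (Newick, TSV, JSON),
  and records config/input digests and per-stage scores in a manifest; a rerun
  with identical inputs reproduces identical numbers.
- Problem sizes in the test suite and acceptance script (5–8 extant taxa,
  2–12 fossils, 100–200 characters, 100 seeds for recovery, 999 permutations)
  are chosen so exhaustive oracles are feasible and the full suite runs on a
  single CPU in a few minutes.

## Known limitations

- Heuristic search is RAS + SPR/TBR with strict-improvement acceptance; no
  ratchet, sectorial, or genetic-algorithm strategies, so very large or very
  flat landscapes may need more replicates.
- The signed-rank normal approximation (n > 20) is asymptotic; exact mode is
  the reference.
- `min_length` ignores partial polymorphisms (documented lower bound).
- The generator's molecular block is generic unordered characters, not a
  nucleotide substitution model — sufficient for parsimony pipeline testing,
  not for likelihood benchmarking.
- NEXUS writing covers DATA + ASSUMPTIONS (ord/unord, weights); irreversible
  user-types are constructed in memory (the stratigraphic character) and not
  serialized.
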